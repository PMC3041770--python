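"""Compound-covariate predictive index, overlap-signature extraction, and
two-cluster patient stratification.

The predictive index for a patient is the weighted linear combination of log
signal values over the signature genes,

    index_s = sum_g  t_g * x_{g,s},

with weights t_g frozen from the training class comparison (the paired
pre/post moderated t) and x the log2 expression of the scored cohort.  The
index is never re-fit on the cohort it scores.  Hazard ratios between index
values follow from a per-unit Cox hazard ratio by exponentiation:
HR(index vs reference) = hr_per_unit ** (index - reference).

Patient stratification uses agglomerative clustering of samples (centred
Pearson correlation distance, average linkage) on the signature genes, cut
at the top split into two clusters; the cluster with the higher mean
expression of the signature's up-regulated genes is labelled high risk.

Also shipped here: the published 72-probe-set acquired-chemoresistance
signature for cisplatin/fluorouracil-treated gastric cancer (72 unique gene
symbols, each upregulated at the chemoresistant state, with its paired
moderated t as weight), loadable via :func:`load_resistance72`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import ExpressionMatrix, GeneSetCollection, GeneSignature

__all__ = [
    "PredictiveIndex",
    "ClusterStratification",
    "extract_overlap_signature",
    "compound_covariate_index",
    "hr_for_index",
    "cluster_two_groups",
    "load_resistance72",
]


@dataclass
class PredictiveIndex:
    """Per-patient compound covariate index with its frozen gene weights."""

    values: pd.Series  # index: sample/patient id
    weights: pd.DataFrame  # columns: probe, weight (and gene when known)
    log_base: float

    @property
    def range(self) -> tuple[float, float, float]:
        """(min, median, max) over the scored cohort."""
        v = self.values.to_numpy(dtype=float)
        return float(v.min()), float(np.median(v)), float(v.max())

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClusterStratification:
    """Two-group stratification of a cohort from hierarchical clustering."""

    labels: pd.Series  # "high" / "low" per sample
    linkage: np.ndarray
    genes: list[str]
    orientation_rule: str

    def __post_init__(self):
        groups = set(self.labels)
        if groups != {"high", "low"}:
            raise ValueError("stratification must contain both risk groups")

    def group(self, which: str) -> list[str]:
        return list(self.labels.index[self.labels == which])


def load_resistance72() -> GeneSignature:
    """The published 72-gene acquired-resistance signature.

    Returns a :class:`GeneSignature` with one row per probe set (72 rows, 72
    unique gene symbols), all up-regulated at the chemoresistant state, the
    published paired moderated t-value as the weight, and no p-values (the
    source table reports only t).
    """
    with resources.files("resistsig.data").joinpath(
            "resistance72_signature.tsv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    table = pd.DataFrame({
        "probe": df["probeset"],
        "gene": df["gene"],
        "t": df["t_value"].astype(float),
        "p": np.nan,
        "direction": "up",
        "mean_log_ratio": np.nan,
    })
    return GeneSignature(table, alpha=0.01, classes=("pre", "post"))


def extract_overlap_signature(up_sig: GeneSignature, es_sets: GeneSetCollection,
                              collapse: str | None = "unique-gene") -> GeneSignature:
    """Signature genes that belong to at least one of the supplied sets.

    ``up_sig`` must contain only up-direction genes (the chemoresistant-state
    upregulated arm at the chosen cutoff).  Membership is tested against the
    union of the sets, matching either the probe id or the gene symbol.
    With ``collapse='unique-gene'`` each gene symbol is represented by its
    largest-|t| probe; the collapse rule and the unique-gene count are
    recorded on the result.
    """
    if (up_sig.table["direction"] == "down").any():
        raise ValueError("up_sig must be restricted to up-direction genes")
    union = es_sets.union()
    tab = up_sig.table
    has_gene = "gene" in tab.columns
    in_union = tab["probe"].isin(union)
    if has_gene:
        in_union = in_union | tab["gene"].isin(union)
    overlap = tab[in_union].copy()
    if overlap.empty:
        raise ValueError("no overlap between the signature and the gene sets")
    if collapse == "unique-gene":
        key = (overlap["gene"] if has_gene else overlap["probe"]).to_numpy()
        best_rows = overlap["t"].abs().groupby(key).idxmax()
        overlap = overlap.loc[best_rows].sort_values("t", ascending=False)
    elif collapse is not None:
        raise ValueError(f"unknown collapse rule: {collapse!r}")
    out = GeneSignature(overlap.reset_index(drop=True), alpha=up_sig.alpha,
                        classes=up_sig.classes)
    out.collapse_rule = collapse
    out.n_unique_genes = (overlap["gene"].nunique() if has_gene
                          else overlap["probe"].nunique())
    return out


def compound_covariate_index(m: ExpressionMatrix,
                             sig: GeneSignature) -> PredictiveIndex:
    """Per-sample weighted sum of log signal values over the signature genes.

    Weights are the signature's t statistics, frozen from the training
    comparison.  Every signature probe must be present in the matrix.
    """
    missing = [p for p in sig.probes if p not in m.values.index]
    if missing:
        raise KeyError(f"signature probes absent from matrix: {missing[:10]}")
    sub = m.values.loc[sig.probes]
    if sub.isna().to_numpy().any():
        raise ValueError("compound covariate index requires complete expression")
    w = sig.table.set_index("probe")["t"].loc[sig.probes].to_numpy(dtype=float)
    idx = pd.Series(w @ sub.to_numpy(), index=sub.columns, name="predictive_index")
    cols = ["probe", "t"] + (["gene"] if "gene" in sig.table.columns else [])
    weights = sig.table[cols].rename(columns={"t": "weight"}).copy()
    return PredictiveIndex(values=idx, weights=weights, log_base=m.log_base)


def hr_for_index(hr_per_unit: float, index: float, reference_index: float) -> float:
    """Hazard ratio between two index values given the per-unit hazard ratio."""
    if hr_per_unit <= 0:
        raise ValueError("hr_per_unit must be positive")
    return float(hr_per_unit ** (index - reference_index))


def cluster_two_groups(m: ExpressionMatrix, genes,
                       linkage_method: str = "average",
                       n_clusters: int = 2) -> ClusterStratification:
    """Stratify samples into high/low-risk clusters on the signature genes.

    Genes are median-centred; sample distance is 1 - Pearson correlation
    over the signature genes; agglomeration uses the given linkage (average
    by default) and the dendrogram is cut at its top split (``n_clusters=2``).
    The cluster with the higher mean centred expression of the signature's
    up-regulated genes is labelled ``"high"`` risk.

    ``genes`` may be a :class:`GeneSignature` (its up/down directions drive
    the orientation) or a plain probe list (all treated as up).
    """
    if isinstance(genes, GeneSignature):
        probes = genes.probes
        up_probes = list(genes.up["probe"])
    else:
        probes = list(genes)
        up_probes = probes
    if len(probes) < 2:
        raise ValueError("need at least 2 signature genes")
    sub = m.subset_probes(probes)
    sub.require_complete("cluster_two_groups")
    if sub.shape[1] < 4:
        raise ValueError("need at least 4 samples to stratify")
    X = sub.values
    centred = X.sub(X.median(axis=1), axis=0)
    flat_raw = X.std(axis=0, ddof=0) == 0
    flat_centred = centred.std(axis=0, ddof=0) == 0
    flat = X.columns[flat_raw | flat_centred].tolist()
    if flat:
        raise ValueError(
            f"samples with constant expression over the signature genes "
            f"(correlation undefined): {flat[:10]}"
        )
    D = pdist(centred.to_numpy().T, metric="correlation")
    Z = hierarchy.linkage(D, method=linkage_method)
    assign = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    if len(set(assign)) < 2:
        raise ValueError("top split did not produce two nonempty clusters")
    up = centred.loc[[p for p in up_probes if p in centred.index]]
    if up.empty:
        up = centred
    cluster_means = {c: float(up.loc[:, assign == c].to_numpy().mean())
                     for c in sorted(set(assign))}
    high_cluster = max(cluster_means, key=lambda c: cluster_means[c])
    labels = pd.Series(np.where(assign == high_cluster, "high", "low"),
                       index=X.columns, name="risk_group")
    return ClusterStratification(
        labels=labels, linkage=Z, genes=probes,
        orientation_rule="high = cluster with greater mean centred expression "
                         "of up-regulated signature genes",
    )
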