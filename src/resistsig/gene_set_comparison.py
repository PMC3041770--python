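"""LS gene-set statistic over per-gene association p-values, with a
resampling null.

For a set of N genes the LS statistic is the mean of -ln(p) over the set,
where p comes from a per-gene univariate association test (class comparison
or a proportional-hazards fit against survival time).  Its significance is
the proportion of random N-gene subsets of the tested universe whose LS
statistic is at least as large as the observed one.

Direction convention: large LS (small member p-values) means enrichment, and
the reported resampling p-value is the probability that a random set is at
least as enriched (resampled LS >= observed).  A set is flagged significant
at p < 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _cox
from .data_model import ClinicalTable, ExpressionMatrix, GeneSetCollection, GeneSignature

__all__ = [
    "GeneRanking",
    "LsResult",
    "gene_ranking_from_survival",
    "gene_ranking_from_signature",
    "ls_statistic",
    "ls_resampling_p",
]

LS_SIGNIFICANCE = 0.005


@dataclass
class GeneRanking:
    """Per-probe association p-values over a probe universe.

    ``table`` has columns ``probe``, ``p`` and optionally
    ``hr_per_doubling`` (hazard ratio for a one log2-unit, i.e. two-fold,
    expression change) and ``converged``.
    """

    table: pd.DataFrame
    phenotype: str

    def __post_init__(self):
        if "probe" not in self.table.columns or "p" not in self.table.columns:
            raise ValueError("ranking table needs 'probe' and 'p' columns")
        if self.table["probe"].duplicated().any():
            raise ValueError("duplicate probes in ranking")
        p = self.table["p"].to_numpy(dtype=float)
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        self.table = self.table.reset_index(drop=True)

    @property
    def universe(self) -> list[str]:
        return list(self.table["probe"])

    @property
    def universe_size(self) -> int:
        return len(self.table)

    def neglogp(self) -> pd.Series:
        return pd.Series(-np.log(self.table["p"].to_numpy(dtype=float)),
                         index=self.table["probe"].to_numpy())


@dataclass
class LsResult:
    """LS statistic and resampling p for one gene set."""

    set_name: str
    n_genes: int
    ls_statistic: float
    ls_p: float
    n_resamples: int
    seed: int | None
    significant: bool
    direction_note: str = "ls_p = P(random-set LS >= observed); large LS = enriched"

    def __post_init__(self):
        if self.ls_statistic < 0:
            raise ValueError("LS statistic is nonnegative")
        if not (0 < self.ls_p <= 1):
            raise ValueError("LS p must lie in (0, 1]")


def gene_ranking_from_survival(m: ExpressionMatrix, clin: ClinicalTable,
                               endpoint: str = "ttp") -> GeneRanking:
    """Univariate proportional-hazards p-value per gene.

    Each gene's log2 expression is regressed on the chosen endpoint
    (``ttp`` or ``os``) with a univariate Cox model; the two-sided Wald
    p-value and the hazard ratio per two-fold expression change are
    recorded.  Genes whose fit does not converge are kept with p = 1 and
    ``converged = False``, never dropped.
    """
    if endpoint not in ("ttp", "os"):
        raise ValueError("endpoint must be 'ttp' or 'os'")
    m.require_complete("gene_ranking_from_survival")
    cdf = clin.aligned_to(m.sample_ids)
    time = cdf[f"{endpoint}_months"].to_numpy(dtype=float)
    event = cdf[f"{endpoint}_event"].to_numpy(dtype=bool)
    if not event.any():
        raise ValueError("no events observed for endpoint; ranking undefined")
    X = m.values.to_numpy().T  # samples x genes
    fit = _cox.univariate_cox(X, time, event)
    table = pd.DataFrame({
        "probe": m.probe_ids,
        "p": fit["p"],
        "hr_per_doubling": np.exp(fit["beta"]),
        "converged": fit["converged"],
    })
    return GeneRanking(table, phenotype=f"proportional-hazards-vs-{endpoint}")


def gene_ranking_from_signature(sig: GeneSignature) -> GeneRanking:
    """Ranking from a class-comparison signature (paired or two-class)."""
    kind = "paired-class" if sig.classes == ("pre", "post") else "two-class"
    table = sig.table[["probe", "p"]].copy()
    return GeneRanking(table, phenotype=kind)


def ls_statistic(r: GeneRanking, set_probes) -> float:
    """Mean of -ln(p) over the set members."""
    probes = list(set_probes)
    if not probes:
        raise ValueError("gene set is empty")
    nlp = r.neglogp()
    missing = [p for p in probes if p not in nlp.index]
    if missing:
        raise KeyError(f"set members absent from the ranked universe: {missing[:10]}")
    return float(nlp.loc[probes].mean())


def ls_resampling_p(r: GeneRanking, sets: GeneSetCollection,
                    n_resamples: int = 100_000,
                    seed: int | None = 0) -> list[LsResult]:
    """Resampling p-value for each set's LS statistic.

    For a set of size N, ``n_resamples`` random N-subsets of the universe
    are drawn without replacement (independently per resample) and
    ``ls_p = (1 + #{resampled LS >= observed}) / (n_resamples + 1)``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    nlp = r.neglogp().to_numpy()
    U = len(nlp)
    results = []
    for name in sets.names:
        probes = sets[name]
        N = len(probes)
        if N > U:
            raise ValueError(
                f"set {name!r} has {N} members but the universe has only {U}"
            )
        observed = ls_statistic(r, probes)
        exceed = 0
        chunk = max(1, min(n_resamples, int(2e7) // max(U, 1)))
        done = 0
        while done < n_resamples:
            nb = min(chunk, n_resamples - done)
            # N smallest of U random keys per row = a uniform N-subset
            keys = rng.random((nb, U))
            idx = np.argpartition(keys, N - 1, axis=1)[:, :N]
            sums = nlp[idx].sum(axis=1)
            exceed += int((sums / N >= observed - 1e-12).sum())
            done += nb
        ls_p = (1.0 + exceed) / (n_resamples + 1.0)
        results.append(LsResult(
            set_name=name, n_genes=N, ls_statistic=observed, ls_p=ls_p,
            n_resamples=n_resamples, seed=seed,
            significant=ls_p < LS_SIGNIFICANCE,
        ))
    return results
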