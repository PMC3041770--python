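"""Domain containers and file I/O for expression, clinical, and gene-set data.

The central object is :class:`ExpressionMatrix`, a probes-by-samples table of
log-scale intensities (log2 by default, as produced by RMA summarisation of
Affymetrix arrays).  Expression is assumed to be log-scale on input and is
never re-logged here.  Missing values are tracked with a mask and are only
expected on the external-cohort path (two-colour platforms with dropouts);
the core Affymetrix-style analyses require a complete matrix.

Also defined here: the pre/post pairing design for rebiopsied responders
(:class:`PairedDesign`), per-patient clinical endpoints
(:class:`ClinicalTable`), named gene sets (:class:`GeneSetCollection`),
and the result container for per-gene class comparisons
(:class:`GeneSignature`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PairedDesign",
    "ClinicalTable",
    "GeneSetCollection",
    "GeneSignature",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "read_gmt",
    "map_to_universe",
    "mean_center_probes",
    "knn_impute",
]

_MISSING_TOKENS = ("", "NA")

CLINICAL_COLUMNS = [
    "patient_id",
    "ttp_months",
    "ttp_event",
    "os_months",
    "os_event",
    "age_years",
    "sex",
    "ecog_binary",
    "histology",
    "response_category",
]

RESPONSE_LEVELS = ["PR", "SD", "PD"]  # ordered best -> worst


class ExpressionMatrix:
    """Log-scale expression values, probes x samples, with a missing mask.

    Parameters
    ----------
    values
        2-D float array or DataFrame, one row per probe, one column per
        sample.  ``NaN`` marks missing entries.
    probe_ids, sample_ids
        Identifier lists; required when ``values`` is a bare array.
    log_base
        Base of the logarithm the intensities are on (2 for RMA output).
    """

    def __init__(self, values, probe_ids=None, sample_ids=None, log_base: float = 2.0):
        if isinstance(values, pd.DataFrame):
            df = values.astype(float)
        else:
            df = pd.DataFrame(np.asarray(values, dtype=float),
                              index=list(probe_ids), columns=list(sample_ids))
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        with np.errstate(invalid="ignore"):
            if np.isinf(df.to_numpy()).any():
                raise ValueError("expression values must be finite where observed")
        self.values = df
        self.log_base = float(log_base)

    # -- basic accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the value is missing."""
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_complete(self) -> bool:
        return not self.values.isna().to_numpy().any()

    def require_complete(self, context: str = "this operation") -> None:
        if not self.is_complete():
            n = int(self.values.isna().to_numpy().sum())
            raise ValueError(
                f"{context} requires a complete matrix; {n} missing entries "
                "present (impute or subset first)"
            )

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(probes)], log_base=self.log_base)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[list(samples)], log_base=self.log_base)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, n = self.shape
        return f"ExpressionMatrix({g} probes x {n} samples, log{self.log_base:g})"


@dataclass
class PairedDesign:
    """Pre/post sample pairing for rebiopsied patients.

    ``pairs`` is a list of ``(pre_sample_id, post_sample_id)``; patient ids
    parallel the pairs (generated ``P1..Pn`` when not supplied).
    """

    pairs: list[tuple[str, str]]
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.patient_ids:
            self.patient_ids = [f"P{i + 1}" for i in range(len(self.pairs))]
        if len(self.patient_ids) != len(self.pairs):
            raise ValueError("patient_ids length must match pairs")
        seen: set[str] = set()
        for pre, post in self.pairs:
            if pre == post:
                raise ValueError(f"pre and post samples identical: {pre}")
            for s in (pre, post):
                if s in seen:
                    raise ValueError(f"sample id occurs in more than one pair: {s}")
                seen.add(s)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def validate_against(self, m: ExpressionMatrix) -> None:
        cols = set(m.sample_ids)
        for pre, post in self.pairs:
            for s in (pre, post):
                if s not in cols:
                    raise KeyError(f"paired sample {s!r} not present in matrix")


class ClinicalTable:
    """Per-patient survival endpoints and covariates.

    Wraps a DataFrame with the columns in :data:`CLINICAL_COLUMNS`.
    ``response_category`` is the ordered WHO radiographic response
    (PR best, then SD, then PD) and may be missing for patients without
    measurable disease.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if df["patient_id"].duplicated().any():
            dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise ValueError(f"duplicate patient ids: {dups}")
        for col in ("ttp_months", "os_months"):
            if (df[col].dropna() < 0).any():
                raise ValueError(f"{col} must be nonnegative")
        for col in ("ttp_event", "os_event"):
            df[col] = df[col].astype(bool)
        bad = df["response_category"].dropna()[
            ~df["response_category"].dropna().isin(RESPONSE_LEVELS)
        ]
        if len(bad):
            raise ValueError(f"invalid response categories: {sorted(set(bad))}")
        self.table = df.reset_index(drop=True)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient_id"])

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Rows reordered to a sample-id list (patient id == sample id)."""
        df = self.table.set_index("patient_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise KeyError(f"samples without clinical rows: {missing[:10]}")
        return df.loc[list(sample_ids)].reset_index()

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with per-set provenance notes."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    mapping_report: pd.DataFrame | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def union(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


class GeneSignature:
    """Per-probe result of a class comparison.

    Holds one row per probe with the moderated t statistic, two-sided
    p-value, direction (``"up"`` means higher in the second/resistant
    class), and the mean log-ratio.  Rows are kept sorted by p ascending.
    A ``gene`` column (symbol) is optional but required for unique-gene
    collapsing.
    """

    REQUIRED = ["probe", "t", "p", "direction", "mean_log_ratio"]

    def __init__(self, table: pd.DataFrame, alpha: float | None = None,
                 classes: tuple[str, str] | None = None):
        df = table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"signature table missing columns: {missing}")
        if df["probe"].duplicated().any():
            raise ValueError("duplicate probes in signature")
        p = df["p"].to_numpy(dtype=float)
        finite = np.isfinite(p)
        if ((p[finite] <= 0) | (p[finite] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        t = df["t"].to_numpy(dtype=float)
        expect = np.where(t > 0, "up", "down")
        mismatch = finite & (df["direction"].to_numpy() != expect) & (t != 0)
        if mismatch.any():
            raise ValueError("direction must equal the sign of t")
        order = np.argsort(p, kind="stable")
        self.table = df.iloc[order].reset_index(drop=True)
        self.alpha = alpha
        self.classes = classes

    @property
    def probes(self) -> list[str]:
        return list(self.table["probe"])

    @property
    def up(self) -> pd.DataFrame:
        return self.table[self.table["direction"] == "up"]

    @property
    def down(self) -> pd.DataFrame:
        return self.table[self.table["direction"] == "down"]

    def select(self, alpha: float) -> "GeneSignature":
        if not 0 < alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        sub = self.table[self.table["p"] < alpha] if alpha < 1 else self.table
        return GeneSignature(sub, alpha=alpha, classes=self.classes)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path, fmt: str = "tsv", log_base: float = 2.0) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First header field is ignored (corner label), remaining header fields are
    sample ids; each data row starts with the probe id.  Empty fields and
    ``NA`` are parsed as missing.  Duplicated ids and ragged rows are hard
    errors.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format: {fmt!r}")
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    ncol = len(header)
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != ncol:
            raise ValueError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {ncol}"
            )
        probe_ids.append(fields[0])
        rows.append([np.nan if f in _MISSING_TOKENS else float(f) for f in fields[1:]])
    return ExpressionMatrix(np.asarray(rows, dtype=float), probe_ids, sample_ids,
                            log_base=log_base)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write the matrix as UTF-8, LF-terminated TSV; missing cells as ``NA``."""
    df = m.values
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe\t" + "\t".join(map(str, df.columns)) + "\n")
        for probe, row in zip(df.index, df.to_numpy()):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(probe) + "\t" + "\t".join(cells) + "\n")


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path)
    return ClinicalTable(df)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member TAB member..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n").rstrip("\r")
            if not ln:
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs name, "
                                 "description and at least one member")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            members = [f for f in fields[2:] if f]
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(c: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in c.sets.items():
            desc = c.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def map_to_universe(c: GeneSetCollection, m: ExpressionMatrix,
                    id_map: Mapping[str, Sequence[str]] | pd.DataFrame | None = None
                    ) -> GeneSetCollection:
    """Restrict gene sets to the probes present on the array.

    ``id_map`` optionally maps gene identifiers to probe ids (one gene may
    map to several probes; all are kept).  Without a map, members are taken
    to be probe ids already.  Sets that are empty after mapping are excluded
    with a warning and listed in the attached mapping report.
    """
    if isinstance(id_map, pd.DataFrame):
        pairs = id_map.iloc[:, :2].to_numpy()
        table: dict[str, list[str]] = {}
        for gene, probe in pairs:
            table.setdefault(str(gene), []).append(str(probe))
        id_map = table
    universe = set(m.probe_ids)
    mapped: dict[str, list[str]] = {}
    report_rows = []
    dropped_sets = []
    for name, members in c.sets.items():
        probes: list[str] = []
        dropped = 0
        for g in members:
            cands = list(id_map.get(g, [])) if id_map is not None else [g]
            hits = [p for p in cands if p in universe]
            if hits:
                probes.extend(hits)
            else:
                dropped += 1
        probes = list(dict.fromkeys(probes))  # dedupe, keep order
        report_rows.append({"set": name, "members_in": len(members),
                            "probes_mapped": len(probes), "members_dropped": dropped})
        if probes:
            mapped[name] = probes
        else:
            dropped_sets.append(name)
    if dropped_sets:
        warnings.warn(f"sets empty after mapping to the array, excluded: {dropped_sets}")
    report = pd.DataFrame(report_rows)
    report["excluded"] = report["set"].isin(dropped_sets)
    out = GeneSetCollection(mapped, {k: c.descriptions.get(k, "") for k in mapped})
    out.mapping_report = report
    return out


# ---------------------------------------------------------------------------
# Preprocessing for external validation data
# ---------------------------------------------------------------------------

def mean_center_probes(m: ExpressionMatrix,
                       groups: Sequence | None = None) -> ExpressionMatrix:
    """Probe-wise mean centering, optionally within sample batches.

    Subtracts, within each batch, each probe's mean over its unmasked values.
    Used to remove batch effects before combining external cohorts.
    """
    df = m.values.copy()
    if groups is None:
        groups = ["_all"] * df.shape[1]
    groups = np.asarray(groups)
    if len(groups) != df.shape[1]:
        raise ValueError("one batch label per sample required")
    for g in pd.unique(groups):
        cols = df.columns[groups == g]
        block = df[cols]
        n_obs = block.notna().sum(axis=1)
        empty = block.index[n_obs == 0].tolist()
        if empty:
            raise ValueError(
                f"probes with no observed value in batch {g!r}: {empty[:10]}"
            )
        df[cols] = block.sub(block.mean(axis=1), axis=0)
    return ExpressionMatrix(df, log_base=m.log_base)


def knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Nearest-neighbour-averaging imputation of missing entries.

    For each probe with missing values, the k nearest probes (root mean
    squared difference over co-observed samples) that are observed in the
    target sample are averaged, unweighted, to fill the hole.  If fewer than
    k candidates exist, all are used with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = m.values
    X = df.to_numpy()
    obs = ~np.isnan(X)
    never = np.where(~obs.any(axis=1))[0]
    if never.size:
        names = df.index[never].tolist()
        raise ValueError(f"probes missing in every sample: {names[:10]}")
    if obs.all():
        return ExpressionMatrix(df.copy(), log_base=m.log_base)
    out = X.copy()
    G = X.shape[0]
    warned = False
    for i in np.where(~obs.all(axis=1))[0]:
        # mean squared difference over co-observed columns, all probes at once
        diff = X - X[i]
        co = obs & obs[i]
        with np.errstate(invalid="ignore"):
            d2 = np.where(co, diff**2, 0.0).sum(axis=1) / co.sum(axis=1)
        d2[i] = np.inf
        d2[co.sum(axis=1) == 0] = np.inf
        for j in np.where(~obs[i])[0]:
            cand = np.where(obs[:, j] & np.isfinite(d2))[0]
            if cand.size == 0:
                raise ValueError(
                    f"no imputation candidates for probe {df.index[i]!r} "
                    f"in sample {df.columns[j]!r}"
                )
            kk = min(k, cand.size)
            if kk < k and not warned:
                warnings.warn("fewer candidate neighbours than k; using all")
                warned = True
            nearest = cand[np.argsort(d2[cand], kind="stable")[:kk]]
            out[i, j] = X[nearest, j].mean()
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns),
                            log_base=m.log_base)
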