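"""Moderated t-tests with a random variance model, and permutation global tests.

The random variance model (RVM) is the empirical-Bayes variance shrinkage of
Wright and Simon: per-gene reciprocal variances are assumed to share a
Gamma(a, b) prior (equivalently, variances are inverse-gamma), which makes
each scaled sample variance marginally F-distributed,

    s_g^2 * a * b  ~  F(m, 2a),      m = residual degrees of freedom.

The hyperparameters (a, b) are fitted by maximum likelihood across genes.
The moderated test then replaces the per-gene variance by the posterior
estimate

    s~_g^2 = (m * s_g^2 + 2/b) / (m + 2a)

and refers the t statistic to m + 2a degrees of freedom.  Under the model
this reference distribution is exact, so moderated p-values stay calibrated
while small-sample variance estimates are stabilised.

Global significance of a class comparison is assessed by permutation:
the proportion of label permutations (within-pair pre/post flips for the
paired design, label shuffles for two-class) that produce at least as many
genes significant at the chosen cutoff as the true labels do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import ExpressionMatrix, GeneSignature, PairedDesign

__all__ = [
    "RvmPrior",
    "PermutationResult",
    "fit_rvm_prior",
    "paired_moderated_t",
    "two_class_moderated_t",
    "extract_signature",
    "permutation_global_test",
]

MIN_GENES_FOR_FIT = 50


@dataclass
class RvmPrior:
    """Inverse-gamma variance-prior hyperparameters (precision ~ Gamma(a, b))."""

    a: float
    b: float
    fitted: bool = False
    log_likelihood: float = float("nan")
    n_genes: int = 0

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("RVM hyperparameters must be positive")

    def shrink(self, s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
        """Return (moderated variances, augmented degrees of freedom)."""
        s2 = np.asarray(s2, dtype=float)
        return (df * s2 + 2.0 / self.b) / (df + 2.0 * self.a), df + 2.0 * self.a


@dataclass
class PermutationResult:
    """Global permutation test outcome for a class comparison."""

    observed_count: int
    null_counts: np.ndarray
    permutation_p: float
    B: int
    seed: int | None
    alpha: float
    mode: str

    def __post_init__(self):
        if len(self.null_counts) != self.B:
            raise ValueError("null_counts length must equal B")
        if not (0 < self.permutation_p <= 1):
            raise ValueError("permutation p must lie in (0, 1]")


def _neg_loglik(theta: np.ndarray, s2: np.ndarray, m: float) -> float:
    log_a, log_c = theta  # c = a*b
    a, c = np.exp(log_a), np.exp(log_c)
    if not np.isfinite(a) or not np.isfinite(c) or a > 1e6:
        return np.inf
    ll = np.log(c) + stats.f.logpdf(c * s2, m, 2.0 * a)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(ll.sum())


def fit_rvm_prior(residual_variances, df: float) -> RvmPrior:
    """Maximum-likelihood fit of the variance-prior hyperparameters.

    ``residual_variances`` are per-gene variance estimates, each on ``df``
    residual degrees of freedom.  At least 50 genes with positive variance
    are required; a degenerate (all-equal) variance vector is rejected.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < MIN_GENES_FOR_FIT:
        raise ValueError(
            f"need at least {MIN_GENES_FOR_FIT} genes with positive variance, "
            f"got {len(s2)}"
        )
    if np.allclose(s2, s2[0]):
        raise ValueError("all variances (numerically) equal; prior fit degenerate")
    med = float(np.median(s2))
    starts = []
    for a0 in (0.5, 1.0, 2.0, 4.0, 8.0):
        c0 = stats.f.ppf(0.5, df, 2 * a0) / med  # match medians
        starts.append((np.log(a0), np.log(c0)))
    best = None
    for x0 in starts:
        res = optimize.minimize(_neg_loglik, x0, args=(s2, float(df)),
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("RVM hyperparameter fit failed: no finite likelihood")
    if not best.success:
        raise RuntimeError(
            f"RVM hyperparameter fit did not converge: {best.message} "
            f"(nit={best.nit}, fun={best.fun:.4g})"
        )
    a = float(np.exp(best.x[0]))
    c = float(np.exp(best.x[1]))
    return RvmPrior(a=a, b=c / a, fitted=True,
                    log_likelihood=-float(best.fun), n_genes=len(s2))


def _resolve_prior(prior, s2: np.ndarray, df: float):
    """Return (RvmPrior | None) from a prior spec ('fit' | 'off' | RvmPrior)."""
    if prior == "off" or prior is None:
        return None
    if prior == "fit":
        return fit_rvm_prior(s2, df)
    if isinstance(prior, RvmPrior):
        return prior
    raise ValueError(f"prior must be 'fit', 'off', or an RvmPrior; got {prior!r}")


def _t_to_signature(probes, t, p, mean_lr, classes, genes=None) -> GeneSignature:
    direction = np.where(t > 0, "up", "down")
    table = pd.DataFrame({
        "probe": probes, "t": t, "p": p,
        "direction": direction, "mean_log_ratio": mean_lr,
    })
    if genes is not None:
        table.insert(1, "gene", list(genes))
    return GeneSignature(table, classes=classes)


def _moderated_stats(mean, s2, df, n_eff, prior):
    """Shared t/p computation.  ``n_eff`` is the effective 1/SE^2 scale
    (n for paired means, 1/(1/n0+1/n1) for two-class differences)."""
    if prior is not None:
        var, dof = prior.shrink(s2, df)
    else:
        var, dof = np.asarray(s2, dtype=float), float(df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n_eff)
    t = np.where(mean == 0, 0.0, t)  # 0/0 -> 0 by convention
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, p, dof


def paired_moderated_t(m: ExpressionMatrix, d: PairedDesign,
                       prior="fit") -> GeneSignature:
    """Paired (pre vs post) moderated t-test per gene.

    Positive t (direction ``"up"``) means higher expression at the
    post/resistant state.  ``prior='off'`` gives the classical paired t.
    """
    if d.n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    m.require_complete("paired_moderated_t")
    d.validate_against(m)
    pre = m.values[[p for p, _ in d.pairs]].to_numpy()
    post = m.values[[q for _, q in d.pairs]].to_numpy()
    D = post - pre  # (G, n)
    n = d.n_pairs
    mean = D.mean(axis=1)
    s2 = D.var(axis=1, ddof=1)
    rvm = _resolve_prior(prior, s2, n - 1)
    t, p, dof = _moderated_stats(mean, s2, n - 1, n, rvm)
    sig = _t_to_signature(m.probe_ids, t, p, mean, classes=("pre", "post"))
    sig.rvm_prior = rvm
    sig.df = dof
    return sig


def two_class_moderated_t(m: ExpressionMatrix, labels: Sequence,
                          prior="fit",
                          classes: tuple | None = None) -> GeneSignature:
    """Unpaired two-class moderated t-test per gene.

    Positive t (``"up"``) means higher in the second class of ``classes``
    (sorted label order when not given).
    """
    m.require_complete("two_class_moderated_t")
    labels = np.asarray(labels)
    if len(labels) != m.shape[1]:
        raise ValueError("one label per sample required")
    levels = list(classes) if classes is not None else sorted(set(labels.tolist()))
    if len(levels) != 2 or set(labels.tolist()) - set(levels):
        raise ValueError(f"labels must take exactly the two values {levels}")
    g0 = labels == levels[0]
    g1 = labels == levels[1]
    n0, n1 = int(g0.sum()), int(g1.sum())
    if min(n0, n1) < 2:
        raise ValueError("each class needs at least 2 samples")
    X = m.values.to_numpy()
    m0 = X[:, g0].mean(axis=1)
    m1 = X[:, g1].mean(axis=1)
    ss = X[:, g0].var(axis=1, ddof=0) * n0 + X[:, g1].var(axis=1, ddof=0) * n1
    df = n0 + n1 - 2
    s2 = ss / df
    rvm = _resolve_prior(prior, s2, df)
    n_eff = 1.0 / (1.0 / n0 + 1.0 / n1)
    t, p, dof = _moderated_stats(m1 - m0, s2, df, n_eff, rvm)
    sig = _t_to_signature(m.probe_ids, t, p, m1 - m0,
                          classes=(str(levels[0]), str(levels[1])))
    sig.rvm_prior = rvm
    sig.df = dof
    return sig


def extract_signature(sig: GeneSignature, alpha: float) -> GeneSignature:
    """Genes with p < alpha, partitioned into up/down by the sign of t."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    out = sig.select(alpha)
    out.n_up = int((out.table["direction"] == "up").sum())
    out.n_down = int((out.table["direction"] == "down").sum())
    return out


# ---------------------------------------------------------------------------
# Permutation global test
# ---------------------------------------------------------------------------

def _paired_null_counts(D: np.ndarray, S: np.ndarray, alpha: float, rvm) -> np.ndarray:
    """Significant-gene count per sign-flip column of S (n x B)."""
    G, n = D.shape
    SS = (D * D).sum(axis=1)[:, None]
    means = (D @ S) / n  # (G, B)
    s2 = (SS - n * means**2) / (n - 1)
    s2 = np.maximum(s2, 0.0)
    if rvm is not None:
        var, dof = rvm.shrink(s2, n - 1)
    else:
        var, dof = s2, n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t = np.where(means == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return (p < alpha).sum(axis=0)


def _two_class_null_counts(X: np.ndarray, Z: np.ndarray, n0: int, n1: int,
                           alpha: float, rvm) -> np.ndarray:
    """Counts per permutation column of the class-1 indicator Z (n x B)."""
    G, n = X.shape
    tot = X.sum(axis=1)[:, None]
    sstot = (X * X).sum(axis=1)[:, None]
    s1 = X @ Z  # (G, B) class-1 sums
    m1 = s1 / n1
    m0 = (tot - s1) / n0
    ss = sstot - n1 * m1**2 - n0 * m0**2
    df = n - 2
    s2 = np.maximum(ss / df, 0.0)
    if rvm is not None:
        var, dof = rvm.shrink(s2, df)
    else:
        var, dof = s2, df
    n_eff = 1.0 / (1.0 / n0 + 1.0 / n1)
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(var / n_eff)
    t = np.where(diff == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return (p < alpha).sum(axis=0)


EXHAUSTIVE_MAX_PAIRS = 12


def permutation_global_test(m: ExpressionMatrix, design, alpha: float,
                            B: int = 1000, seed: int | None = 0,
                            prior="fit", mode: str = "auto") -> PermutationResult:
    """Global permutation p for the number of significant genes at ``alpha``.

    ``design`` is a :class:`PairedDesign` (within-pair pre/post flips) or a
    two-class label sequence (label shuffles).  The permutation p-value is
    the proportion of permutations producing at least as many significant
    genes as the observed labels, using the add-one convention
    ``(1 + #{null >= observed}) / (B + 1)`` so it is never zero.  For paired
    designs with n <= 12 pairs, ``mode='auto'`` switches to exhaustive
    enumeration of all 2^n sign patterns (the identity pattern included),
    where the p-value is the exact proportion ``#{>= observed} / 2^n``.

    The RVM prior, when used, is fitted once to the observed residual
    variances and held fixed across permutations.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)

    if isinstance(design, PairedDesign):
        m.require_complete("permutation_global_test")
        design.validate_against(m)
        pre = m.values[[p for p, _ in design.pairs]].to_numpy()
        post = m.values[[q for _, q in design.pairs]].to_numpy()
        D = post - pre
        n = design.n_pairs
        s2 = D.var(axis=1, ddof=1)
        rvm = _resolve_prior(prior, s2, n - 1)
        observed = int(_paired_null_counts(D, np.ones((n, 1)), alpha, rvm)[0])
        exhaustive = (mode == "exhaustive"
                      or (mode == "auto" and n <= EXHAUSTIVE_MAX_PAIRS))
        if exhaustive:
            bits = np.arange(2**n)[None, :] >> np.arange(n)[:, None] & 1
            S = np.where(bits.astype(bool), -1.0, 1.0)  # (n, 2^n)
            null_counts = _paired_null_counts(D, S, alpha, rvm)
            perm_p = float((null_counts >= observed).sum()) / (2**n)
            return PermutationResult(observed, null_counts, perm_p, 2**n,
                                     seed, alpha, "exhaustive")
        S = rng.choice([-1.0, 1.0], size=(n, B))
        null_counts = _paired_null_counts(D, S, alpha, rvm)
        perm_p = (1.0 + float((null_counts >= observed).sum())) / (B + 1)
        return PermutationResult(observed, null_counts, perm_p, B, seed,
                                 alpha, "sampled")

    # two-class design: label shuffles
    labels = np.asarray(design)
    m.require_complete("permutation_global_test")
    if len(labels) != m.shape[1]:
        raise ValueError("one label per sample required")
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError("two-class permutation test needs exactly 2 labels")
    z = (labels == levels[1])
    n1, n0 = int(z.sum()), int((~z).sum())
    X = m.values.to_numpy()
    df = n0 + n1 - 2
    m0 = X[:, ~z].mean(axis=1)
    m1 = X[:, z].mean(axis=1)
    ss = X[:, ~z].var(axis=1, ddof=0) * n0 + X[:, z].var(axis=1, ddof=0) * n1
    rvm = _resolve_prior(prior, ss / df, df)
    observed = int(_two_class_null_counts(X, z.astype(float)[:, None],
                                          n0, n1, alpha, rvm)[0])
    n = n0 + n1
    Z = np.zeros((n, B))
    for b in range(B):
        idx = rng.permutation(n)[:n1]
        Z[idx, b] = 1.0
    null_counts = _two_class_null_counts(X, Z, n0, n1, alpha, rvm)
    perm_p = (1.0 + float((null_counts >= observed).sum())) / (B + 1)
    return PermutationResult(observed, null_counts, perm_p, B, seed,
                             alpha, "sampled")
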