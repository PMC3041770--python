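"""Kaplan–Meier/log-rank comparison, Cox and ordinal-logistic regression,
and permutation-tested cross-validated survival risk prediction.

The risk-prediction procedure follows the supervised-principal-components
lineage: within each cross-validation fold, genes are ranked on the training
patients by their univariate Cox score statistic, the top genes form a small
number of principal components, a Cox model on those components yields a
prognostic index, and left-out patients are assigned to the high- or
low-risk group according to whether their index exceeds the training median.
The log-rank statistic between the two cross-validated groups is then
referred to a null distribution obtained by shuffling the (time, event)
pairs across patients and repeating the entire cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from . import _cox
from .data_model import ClinicalTable, ExpressionMatrix

__all__ = [
    "KmCurve",
    "RiskPredictionResult",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "ordinal_logistic_fit",
    "survival_risk_prediction",
    "design_frame",
]


@dataclass
class KmCurve:
    """Product-limit survival curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # NaN when the curve never reaches 0.5

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if len(s) and (np.diff(s) > 1e-12).any():
            raise ValueError("survival must be nonincreasing")


@dataclass
class RiskPredictionResult:
    """Cross-validated risk grouping and its permutation significance."""

    risk_groups: pd.Series  # "high"/"low" per patient
    cv_index: pd.Series  # cross-validated prognostic index
    observed_logrank: float
    null_logrank: np.ndarray
    permutation_p: float
    n_folds: int
    n_components: int
    n_perms: int
    seed: int | None

    def __post_init__(self):
        if not (0 < self.permutation_p <= 1):
            raise ValueError("permutation p must lie in (0, 1]")


def km_curve(times, events) -> KmCurve:
    """Kaplan–Meier estimate with numbers at risk and the median time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    med = kmf.median_survival_time_
    return KmCurve(
        times=tab.index.to_numpy(dtype=float),
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        at_risk=tab["at_risk"].to_numpy(),
        median=float(med) if np.isfinite(med) else float("nan"),
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("logrank_test compares exactly two groups")
    g = groups == levels[1]
    if events[g].sum() == 0 or events[~g].sum() == 0:
        warnings.warn("a group has zero observed events; log-rank statistic "
                      "computed but poorly determined")
    res = _ll_logrank(times[~g], times[g], events[~g], events[g])
    return float(res.test_statistic), float(res.p_value)


def _clin_frame(clin) -> pd.DataFrame:
    return clin.table if isinstance(clin, ClinicalTable) else clin


def design_frame(clin, index: pd.Series | None = None) -> pd.DataFrame:
    """Covariate frame for the multivariable models: predictive index (when
    given), poor performance status (ECOG 2–3), age in years, female sex."""
    df = _clin_frame(clin)
    out = pd.DataFrame({"patient_id": df["patient_id"]})
    if index is not None:
        out["predictive_index"] = index.reindex(df["patient_id"]).to_numpy()
    out["ecog_2_3"] = df["ecog_binary"].astype(float).to_numpy()
    out["age_years"] = df["age_years"].astype(float).to_numpy()
    sex = df["sex"].astype(str).str.upper()
    out["female"] = sex.isin(["F", "FEMALE", "1"]).astype(float).to_numpy()
    for extra in ("ttp_months", "ttp_event", "os_months", "os_event",
                  "response_category"):
        out[extra] = df[extra].to_numpy()
    return out


def cox_fit(data, covariates, endpoint: str = "ttp") -> pd.DataFrame:
    """Multivariable Cox proportional-hazards fit (Efron ties, lifelines).

    ``data`` is a ClinicalTable or a DataFrame carrying the covariate
    columns plus ``{endpoint}_months`` / ``{endpoint}_event``.  Returns one
    row per covariate with the hazard ratio per unit, its 95% CI, and the
    two-sided Wald p-value.
    """
    df = _clin_frame(data)
    dur, ev = f"{endpoint}_months", f"{endpoint}_event"
    for col in [dur, ev, *covariates]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} missing from data")
    sub = df[[dur, ev, *covariates]].dropna()
    if sub[ev].sum() == 0:
        raise ValueError("no events observed; Cox model undefined")
    Xm = sub[list(covariates)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm - Xm.mean(axis=0)) < len(covariates):
        raise ValueError("covariates are collinear (rank-deficient design)")
    cph = CoxPHFitter()
    cph.fit(sub.astype({ev: int}), duration_col=dur, event_col=ev)
    summ = cph.summary
    return pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "ci_lower": summ["exp(coef) lower 95%"],
        "ci_upper": summ["exp(coef) upper 95%"],
        "p": summ["p"],
    })


def ordinal_logistic_fit(data, covariates,
                         response: str = "response_category") -> pd.DataFrame:
    """Proportional-odds ordinal logistic fit of radiographic response.

    Patients with a missing response (nonmeasurable disease) are excluded.
    The response is ordered PR < SD < PD (best to worst), so an odds ratio
    above 1 means a shift toward worse response per unit of the covariate.
    Levels with zero observations are collapsed away with a warning.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    from .data_model import RESPONSE_LEVELS

    df = _clin_frame(data)
    sub = df.dropna(subset=[response, *covariates])
    if sub.empty:
        raise ValueError("no patients with an observed response")
    observed_levels = [lv for lv in RESPONSE_LEVELS
                       if (sub[response] == lv).any()]
    if len(observed_levels) < 2:
        raise ValueError("need at least 2 observed response levels")
    if len(observed_levels) < len(RESPONSE_LEVELS):
        dropped = sorted(set(RESPONSE_LEVELS) - set(observed_levels))
        warnings.warn(f"response levels with zero observations collapsed "
                      f"away: {dropped}")
    endog = pd.Series(pd.Categorical(sub[response], categories=observed_levels,
                                     ordered=True), index=sub.index)
    exog = sub[list(covariates)].astype(float)
    model = OrderedModel(endog, exog, distr="logit")
    fit = model.fit(method="bfgs", disp=0)
    k = len(covariates)
    params = fit.params[:k]
    bse = fit.bse[:k]
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "coef": params.to_numpy(),
        "or": np.exp(params.to_numpy()),
        "ci_lower": np.exp(params.to_numpy() - 1.96 * bse.to_numpy()),
        "ci_upper": np.exp(params.to_numpy() + 1.96 * bse.to_numpy()),
        "p": p,
    }, index=list(covariates))


# ---------------------------------------------------------------------------
# Cross-validated survival risk prediction
# ---------------------------------------------------------------------------

def _make_folds(n: int, n_folds: int, event: np.ndarray,
                rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into folds such that every training set has events."""
    for attempt in range(20):
        folds = np.array_split(rng.permutation(n), n_folds)
        ok = all(event[np.setdiff1d(np.arange(n), f)].sum() > 0 for f in folds)
        if ok:
            if attempt > 0:
                warnings.warn("refolded to avoid an event-free training set")
            return folds
    raise ValueError("could not build folds with events in every training set")


def _logrank_stat(times, events, high: np.ndarray) -> float:
    if high.all() or (~high).all():
        return 0.0  # no separation proposed
    res = _ll_logrank(times[~high], times[high], events[~high], events[high])
    return float(res.test_statistic)


def _cv_risk_groups(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                    folds, n_components: int, gene_alpha: float,
                    min_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """One full cross-validation pass; returns (high-risk mask, cv index)."""
    n = len(time)
    cv_index = np.zeros(n)
    high = np.zeros(n, dtype=bool)
    chi2_cut = stats.chi2.isf(gene_alpha, 1)
    for test_idx in folds:
        tr = np.setdiff1d(np.arange(n), test_idx)
        chi2 = _cox.univariate_score(X[tr], time[tr], event[tr])
        sel = np.where(chi2 >= chi2_cut)[0]
        if len(sel) < max(n_components, min_genes):
            sel = np.argsort(chi2)[::-1][:max(n_components, min_genes)]
        Xtr = X[np.ix_(tr, sel)]
        mu = Xtr.mean(axis=0)
        ncomp = min(n_components, len(sel), len(tr) - 1)
        _, _, Vt = np.linalg.svd(Xtr - mu, full_matrices=False)
        load = Vt[:ncomp].T
        s_tr = (Xtr - mu) @ load
        try:
            beta, _ = _cox.cox_newton(s_tr, time[tr], event[tr])
        except (RuntimeError, np.linalg.LinAlgError):
            # fall back to the first component with its univariate sign
            fit1 = _cox.univariate_cox(s_tr[:, :1], time[tr], event[tr])
            beta = np.zeros(ncomp)
            beta[0] = fit1["beta"][0]
        idx_tr = s_tr @ beta
        thresh = np.median(idx_tr)
        s_te = (X[np.ix_(test_idx, sel)] - mu) @ load
        idx_te = s_te @ beta
        cv_index[test_idx] = idx_te
        high[test_idx] = idx_te > thresh
    return high, cv_index


def survival_risk_prediction(m: ExpressionMatrix, clin: ClinicalTable, genes,
                             endpoint: str = "ttp", n_folds: int = 10,
                             n_components: int = 2, n_perms: int = 100,
                             seed: int | None = 0, gene_alpha: float = 0.001,
                             min_genes: int = 10) -> RiskPredictionResult:
    """Permutation-tested cross-validated survival risk prediction.

    See the module docstring for the procedure.  The permutation p-value is
    ``(1 + #{shuffled log-rank >= observed}) / (n_perms + 1)``; the observed
    statistic is never counted as one of the permutations.  Folds are drawn
    once from ``seed`` and reused across permutations.
    """
    sub = m.subset_probes(list(genes))
    sub.require_complete("survival_risk_prediction")
    cdf = clin.aligned_to(sub.sample_ids)
    time = cdf[f"{endpoint}_months"].to_numpy(dtype=float)
    event = cdf[f"{endpoint}_event"].to_numpy(dtype=bool)
    n = len(time)
    if n_folds > n:
        raise ValueError("more folds than patients")
    rng = np.random.default_rng(seed)
    folds = _make_folds(n, n_folds, event, rng)
    X = sub.values.to_numpy().T  # samples x genes
    high, cv_index = _cv_risk_groups(X, time, event, folds, n_components,
                                     gene_alpha, min_genes)
    observed = _logrank_stat(time, event, high)
    null = np.zeros(n_perms)
    for b in range(n_perms):
        perm = rng.permutation(n)
        h_b, _ = _cv_risk_groups(X, time[perm], event[perm], folds,
                                 n_components, gene_alpha, min_genes)
        null[b] = _logrank_stat(time[perm], event[perm], h_b)
    perm_p = (1.0 + float((null >= observed - 1e-12).sum())) / (n_perms + 1)
    return RiskPredictionResult(
        risk_groups=pd.Series(np.where(high, "high", "low"),
                              index=sub.sample_ids, name="risk_group"),
        cv_index=pd.Series(cv_index, index=sub.sample_ids,
                           name="cv_prognostic_index"),
        observed_logrank=observed, null_logrank=null, permutation_p=perm_p,
        n_folds=n_folds, n_components=n_components, n_perms=n_perms,
        seed=seed,
    )
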