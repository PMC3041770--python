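import numpy as np
import pandas as pd
import pytest
from scipy import stats

import resistsig as rs
from resistsig import _cox


def _clin_frame(n, time, event, rng=None, response=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "patient_id": [f"s{i}" for i in range(n)],
        "ttp_months": time, "ttp_event": event,
        "os_months": time, "os_event": event,
        "age_years": rng.integers(40, 75, n),
        "sex": rng.choice(["M", "F"], n),
        "ecog_binary": rng.integers(0, 2, n),
        "histology": "diffuse",
        "response_category": response if response is not None else "SD",
    })


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

def test_km_median_without_censoring():
    km = rs.km_curve([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
    assert km.median == 3
    assert km.survival[-1] == pytest.approx(0.0)


def test_km_median_undefined_when_curve_stays_high():
    km = rs.km_curve([1, 2, 3, 4], [1, 0, 0, 0])
    assert np.isnan(km.median)


def test_logrank_identical_groups_is_null():
    t = [1, 2, 3, 4, 2, 3]
    e = [1, 1, 1, 1, 1, 0]
    stat, p = rs.logrank_test(t + t, e + e, ["a"] * 6 + ["b"] * 6)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_computed_oe():
    # group A events at 1, 2; group B events at 3, 4; no censoring.
    # Risk sets: t=1: (2A,2B) E_A=0.5; t=2: (1A,2B) E_A=1/3;
    # t=3: (0A,2B) E_A=0; t=4: (0A,1B) E_A=0.  O_A=2, E_A=5/6.
    # V = sum of hypergeometric variances = 0.25 + 2/9 = 17/36.
    stat, p = rs.logrank_test([1, 2, 3, 4], [1, 1, 1, 1],
                              ["A", "A", "B", "B"])
    expected = (2 - 5 / 6) ** 2 / (17 / 36)
    assert stat == pytest.approx(expected, rel=1e-9)
    assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)


def test_logrank_zero_event_group_warns():
    with pytest.warns(UserWarning, match="zero observed events"):
        rs.logrank_test([1, 2, 3, 4], [1, 1, 0, 0], ["a", "a", "b", "b"])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def test_cox_fit_recovers_planted_coefficient():
    rng = np.random.default_rng(1)
    n, beta = 300, 0.6
    x = rng.normal(0, 1, n)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    cens = rng.exponential(30, n)
    clin = _clin_frame(n, np.minimum(t, cens), t <= cens, rng)
    clin["marker"] = x
    out = rs.cox_fit(clin, ["marker"], "ttp")
    assert abs(out.loc["marker", "hr"] - np.exp(beta)) / np.exp(beta) < 0.15
    assert out.loc["marker", "p"] < 1e-6


def test_cox_fit_null_covariate_wald_p_uniform():
    rng = np.random.default_rng(2)
    ps = []
    for _ in range(120):
        n = 60
        t = rng.exponential(5, n)
        clin = _clin_frame(n, t, np.ones(n, bool), rng)
        clin["marker"] = rng.normal(0, 1, n)
        ps.append(rs.cox_fit(clin, ["marker"], "ttp").loc["marker", "p"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_cox_fit_rejects_collinear_covariates():
    rng = np.random.default_rng(3)
    clin = _clin_frame(50, rng.exponential(5, 50), np.ones(50, bool), rng)
    clin["a"] = rng.normal(0, 1, 50)
    clin["b"] = 2.0 * clin["a"]
    with pytest.raises(ValueError, match="collinear"):
        rs.cox_fit(clin, ["a", "b"], "ttp")


def test_internal_cox_kernels_match_lifelines():
    rng = np.random.default_rng(4)
    n = 120
    X = rng.normal(0, 1, (n, 3))
    t = rng.exponential(1.0 / (0.2 * np.exp(0.5 * X[:, 0])))
    e = t <= rng.exponential(12, n)
    tt = np.minimum(t, rng.exponential(12, n))
    # continuous times: no ties, Breslow == Efron
    clin = _clin_frame(n, tt, e, rng)
    for j in range(3):
        clin[f"x{j}"] = X[:, j]
    ref = rs.cox_fit(clin, ["x0", "x1", "x2"], "ttp")
    beta, cov = _cox.cox_newton(X, tt, e)
    assert np.allclose(beta, ref["coef"].to_numpy(), atol=1e-5)
    uni = _cox.univariate_cox(X[:, :1], tt, e)
    ref1 = rs.cox_fit(clin, ["x0"], "ttp")
    assert uni["beta"][0] == pytest.approx(ref1.loc["x0", "coef"], abs=1e-5)


# ---------------------------------------------------------------------------
# Ordinal logistic regression
# ---------------------------------------------------------------------------

def test_two_level_ordinal_reduces_to_binary_logistic():
    import statsmodels.api as sm
    rng = np.random.default_rng(5)
    n = 150
    x = rng.normal(0, 1, n)
    py = 1 / (1 + np.exp(-(0.8 * x)))
    resp = np.where(rng.random(n) < py, "PD", "PR")
    clin = _clin_frame(n, rng.exponential(5, n), np.ones(n, bool), rng,
                       response=resp)
    clin["marker"] = x
    with pytest.warns(UserWarning, match="collapsed"):
        out = rs.ordinal_logistic_fit(clin, ["marker"])
    logit = sm.Logit((resp == "PD").astype(int),
                     sm.add_constant(x)).fit(disp=0)
    assert out.loc["marker", "coef"] == pytest.approx(logit.params[1],
                                                      abs=1e-5)


def test_ordinal_ci_covers_null_or():
    rng = np.random.default_rng(6)
    covered = 0
    n_sims = 250
    for _ in range(n_sims):
        n = 120
        x = rng.normal(0, 1, n)
        latent = rng.logistic(0, 1, n)  # independent of x
        resp = np.where(latent < -0.5, "PR", np.where(latent < 0.6, "SD", "PD"))
        clin = _clin_frame(n, rng.exponential(5, n), np.ones(n, bool), rng,
                           response=resp)
        clin["marker"] = x
        out = rs.ordinal_logistic_fit(clin, ["marker"])
        if out.loc["marker", "ci_lower"] <= 1.0 <= out.loc["marker", "ci_upper"]:
            covered += 1
    # ~95% nominal coverage; allow 3 binomial SE
    se = np.sqrt(0.95 * 0.05 / n_sims)
    assert abs(covered / n_sims - 0.95) < 3 * se + 0.005


def test_ordinal_requires_observed_responses():
    clin = _clin_frame(20, np.ones(20), np.ones(20, bool),
                       response=np.full(20, np.nan, dtype=object))
    clin["marker"] = 1.0
    with pytest.raises(ValueError, match="observed response"):
        rs.ordinal_logistic_fit(clin, ["marker"])


# ---------------------------------------------------------------------------
# Cross-validated survival risk prediction
# ---------------------------------------------------------------------------

def test_risk_prediction_deterministic_given_seed(cohort_small,
                                                  signature_small):
    m, clin = cohort_small
    genes = signature_small.probes
    a = rs.survival_risk_prediction(m, clin, genes, n_perms=5, seed=3)
    b = rs.survival_risk_prediction(m, clin, genes, n_perms=5, seed=3)
    assert a.risk_groups.equals(b.risk_groups)
    assert a.permutation_p == b.permutation_p
    assert np.array_equal(a.null_logrank, b.null_logrank)


def test_risk_prediction_power_with_planted_link():
    hits = 0
    for rep in range(10):
        cfg = rs.SimulationConfig(n_genes=250, n_true=40, n_cancer_genes=10,
                                  hazard_coefficient=1.2, seed=300 + rep)
        m, d, truth = rs.simulate_paired(cfg)
        mc, clin = rs.simulate_cohort(cfg, truth)
        genes = truth.loc[truth["planted_resistance"], "probe"]
        res = rs.survival_risk_prediction(mc, clin, genes, n_perms=19,
                                          seed=rep)
        if res.permutation_p == pytest.approx(1.0 / 20.0):
            hits += 1
    assert hits >= 9


def test_risk_prediction_p_never_zero(cohort_small, signature_small):
    m, clin = cohort_small
    res = rs.survival_risk_prediction(m, clin, signature_small.probes,
                                      n_perms=10, seed=1)
    assert res.permutation_p >= 1.0 / 11.0
    assert set(res.risk_groups.unique()) <= {"high", "low"}
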