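import itertools

import numpy as np
import pytest
from scipy import stats

import resistsig as rs


def _variances_from_prior(a, b, df, G, seed):
    rng = np.random.default_rng(seed)
    precision = rng.gamma(shape=a, scale=b, size=G)
    return rng.chisquare(df, size=G) / df / precision


# ---------------------------------------------------------------------------
# Random variance model hyperparameter fit
# ---------------------------------------------------------------------------

def test_rvm_fit_recovers_known_hyperparameters():
    a, b, df = 3.0, 2.0, 21
    s2 = _variances_from_prior(a, b, df, G=10_000, seed=3)
    prior = rs.fit_rvm_prior(s2, df)
    assert prior.fitted and prior.n_genes == 10_000
    assert abs(prior.a - a) / a < 0.10
    assert abs(prior.b - b) / b < 0.10


def test_rvm_fit_scale_equivariance():
    s2 = _variances_from_prior(2.5, 1.5, 15, G=4000, seed=4)
    p1 = rs.fit_rvm_prior(s2, 15)
    p2 = rs.fit_rvm_prior(2.0 * s2, 15)
    # doubling variances doubles the prior's variance scale 1/(ab), shape fixed
    assert p2.a == pytest.approx(p1.a, rel=0.02)
    assert 1.0 / (p2.a * p2.b) == pytest.approx(2.0 / (p1.a * p1.b), rel=0.02)


def test_rvm_fit_preconditions():
    with pytest.raises(ValueError, match="at least 50"):
        rs.fit_rvm_prior(np.ones(10) + np.arange(10) * 0.1, 5)
    with pytest.raises(ValueError, match="equal"):
        rs.fit_rvm_prior(np.full(100, 2.0), 5)


# ---------------------------------------------------------------------------
# Moderated t-tests
# ---------------------------------------------------------------------------

def test_paired_zero_differences_give_t0_p1(toy_matrix):
    rng = np.random.default_rng(0)
    pre = rng.normal(size=(100, 4))
    m = toy_matrix(np.hstack([pre, pre]),
                   samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
    d = rs.PairedDesign(pairs=[(f"a{i}", f"b{i}") for i in range(4)])
    # variance across genes is nonzero even though every diff is zero; the
    # RVM shrink target is degenerate here, so run the classical test
    sig = rs.paired_moderated_t(m, d, prior="off")
    assert (sig.table["t"] == 0).all()
    assert (sig.table["p"] == 1).all()


def test_paired_prior_off_equals_classical_t(paired_small):
    m, d, _ = paired_small
    sig = rs.paired_moderated_t(m, d, prior="off")
    D = (m.values[[q for _, q in d.pairs]].to_numpy()
         - m.values[[p for p, _ in d.pairs]].to_numpy())
    ref = stats.ttest_1samp(D, 0.0, axis=1)
    got = sig.table.set_index("probe").loc[m.probe_ids]
    assert np.abs(got["t"].to_numpy() - ref.statistic).max() < 1e-12
    assert np.abs(got["p"].to_numpy() - ref.pvalue).max() < 1e-12


def test_moderated_t_classical_limit_as_shape_vanishes(paired_small):
    # a -> 0 with the prior precision ab held fixed removes the shrinkage
    m, d, _ = paired_small
    weak = rs.RvmPrior(a=1e-8, b=1.0 / 1e-8)
    sig_mod = rs.paired_moderated_t(m, d, prior=weak)
    sig_cls = rs.paired_moderated_t(m, d, prior="off")
    assert np.abs(sig_mod.table.set_index("probe")["t"]
                  - sig_cls.table.set_index("probe")["t"]).max() < 1e-6


def test_two_class_prior_off_equals_pooled_t(toy_matrix):
    m = toy_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
    sig = rs.two_class_moderated_t(m, ["x", "x", "x", "y", "y", "y"],
                                   prior="off")
    ref = stats.ttest_ind([4.0, 5.0, 6.0], [1.0, 2.0, 3.0], equal_var=True)
    assert sig.table.loc[0, "t"] == pytest.approx(ref.statistic, abs=1e-12)
    assert sig.table.loc[0, "p"] == pytest.approx(ref.pvalue, abs=1e-12)


def test_two_class_label_swap_negates_t(paired_small):
    m, _, _ = paired_small
    n = m.shape[1]
    labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    s1 = rs.two_class_moderated_t(m, labels, prior="fit", classes=("a", "b"))
    s2 = rs.two_class_moderated_t(m, labels, prior="fit", classes=("b", "a"))
    a = s1.table.set_index("probe").loc[m.probe_ids]
    b = s2.table.set_index("probe").loc[m.probe_ids]
    assert np.allclose(a["t"].to_numpy(), -b["t"].to_numpy(), atol=1e-12)
    assert np.allclose(a["p"].to_numpy(), b["p"].to_numpy(), atol=1e-12)


def test_two_class_requires_two_per_class(toy_matrix):
    m = toy_matrix(np.zeros((3, 3)))
    with pytest.raises(ValueError, match="at least 2"):
        rs.two_class_moderated_t(m, ["a", "b", "b"], prior="off")


def test_p_invariant_to_per_gene_constant_shift(paired_small):
    m, d, _ = paired_small
    shifted = rs.ExpressionMatrix(m.values + 5.0)
    s1 = rs.paired_moderated_t(m, d, prior="fit")
    s2 = rs.paired_moderated_t(shifted, d, prior="fit")
    assert np.allclose(s1.table.set_index("probe")["p"],
                       s2.table.set_index("probe")["p"], atol=1e-12)


def test_moderated_p_calibrated_under_model_null():
    # data generated from the RVM's own model: p < alpha fraction ~= alpha
    rng = np.random.default_rng(8)
    G, n = 5000, 8
    precision = rng.gamma(3.0, 2.0, size=G)
    sigma = 1.0 / np.sqrt(precision)
    pre = 7.0 + rng.normal(0, 1, (G, n)) * sigma[:, None]
    post = 7.0 + rng.normal(0, 1, (G, n)) * sigma[:, None]
    m = rs.ExpressionMatrix(np.hstack([pre, post]),
                            [f"g{i}" for i in range(G)],
                            [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)])
    d = rs.PairedDesign(pairs=[(f"a{i}", f"b{i}") for i in range(n)])
    sig = rs.paired_moderated_t(m, d, prior="fit")
    for alpha in (0.01, 0.05):
        frac = (sig.table["p"] < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / G)
        assert abs(frac - alpha) < 3 * se


# ---------------------------------------------------------------------------
# Signature extraction
# ---------------------------------------------------------------------------

def test_extract_signature_threshold_and_partition(paired_small):
    m, d, _ = paired_small
    sig = rs.paired_moderated_t(m, d)
    sel = rs.extract_signature(sig, 0.01)
    assert (sel.table["p"] < 0.01).all()
    assert sel.n_up + sel.n_down == len(sel)
    assert len(rs.extract_signature(sig, 1.0)) == len(sig)
    with pytest.raises(ValueError):
        rs.extract_signature(sig, 0.0)


# ---------------------------------------------------------------------------
# Permutation global test
# ---------------------------------------------------------------------------

def test_exhaustive_sign_flips_match_enumeration_oracle(toy_matrix):
    rng = np.random.default_rng(12)
    G, n = 40, 3
    vals = np.hstack([rng.normal(size=(G, n)), rng.normal(size=(G, n))])
    m = toy_matrix(vals, samples=[f"a{i}" for i in range(n)]
                   + [f"b{i}" for i in range(n)])
    d = rs.PairedDesign(pairs=[(f"a{i}", f"b{i}") for i in range(n)])
    alpha = 0.2
    res = rs.permutation_global_test(m, d, alpha=alpha, prior="off",
                                     mode="exhaustive")
    D = vals[:, n:] - vals[:, :n]
    counts = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        p = stats.ttest_1samp(D * np.array(signs), 0.0, axis=1).pvalue
        counts.append(int((p < alpha).sum()))
    observed = counts[0]  # identity flip
    expected_p = sum(c >= observed for c in counts) / 2**n
    assert res.B == 2**n
    assert sorted(res.null_counts.tolist()) == sorted(counts)
    assert res.permutation_p == pytest.approx(expected_p)


def test_strong_signal_saturates_permutation_null():
    cfg = rs.SimulationConfig(n_genes=300, n_true=50, n_cancer_genes=10,
                              n_pairs=10, effect_mu=2.0, seed=21)
    m, d, _ = rs.simulate_paired(cfg)
    res = rs.permutation_global_test(m, d, alpha=0.01, B=199, seed=1,
                                     mode="sampled")
    assert res.permutation_p == pytest.approx(1.0 / 200.0)


def test_sampled_and_exhaustive_null_distributions_agree():
    # chi-square goodness of fit of sampled null counts against the
    # exhaustive distribution, n = 8 pairs
    cfg = rs.SimulationConfig(n_genes=120, n_true=10, n_cancer_genes=10,
                              n_pairs=8, effect_mu=0.0, seed=22)
    m, d, _ = rs.simulate_paired(cfg)
    ex = rs.permutation_global_test(m, d, alpha=0.05, prior="off",
                                    mode="exhaustive")
    sa = rs.permutation_global_test(m, d, alpha=0.05, prior="off",
                                    mode="sampled", B=4000, seed=5)
    edges = np.quantile(ex.null_counts, [0.0, 0.25, 0.5, 0.75]).tolist()
    edges = sorted(set(edges)) + [np.inf]
    exp_prob = np.histogram(ex.null_counts, bins=edges)[0] / len(ex.null_counts)
    obs = np.histogram(sa.null_counts, bins=edges)[0]
    keep = exp_prob > 0
    chi2 = ((obs[keep] - 4000 * exp_prob[keep]) ** 2
            / (4000 * exp_prob[keep])).sum()
    crit = stats.chi2.isf(0.01, keep.sum() - 1)
    assert chi2 < crit


def test_permutation_alpha_bounds(paired_small):
    m, d, _ = paired_small
    with pytest.raises(ValueError, match="alpha"):
        rs.permutation_global_test(m, d, alpha=1.5, B=10)
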