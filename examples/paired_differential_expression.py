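"""Identify an acquired-resistance signature from matched pre/post profiles.

Simulates a reduced-scale paired study (22 rebiopsied responders, 1,200
genes, 120 of them truly shifted at the chemoresistant state), runs the
moderated paired t-test with the random variance model, thresholds the
signature, and checks global significance by within-pair permutation.
"""

import resistsig as rs

cfg = rs.SimulationConfig(n_genes=1200, n_true=120, n_cancer_genes=60, seed=7)
matrix, design, truth = rs.simulate_paired(cfg)

sig = rs.paired_moderated_t(matrix, design, prior="fit")
print(f"RVM prior: a={sig.rvm_prior.a:.2f}, b={sig.rvm_prior.b:.2f} "
      f"(augmented df = {sig.df:.1f})")

for alpha in (0.05, 0.01):
    sel = rs.extract_signature(sig, alpha)
    perm = rs.permutation_global_test(matrix, design, alpha=alpha, B=999,
                                      seed=1, mode="sampled")
    print(f"P<{alpha}: {len(sel)} genes ({sel.n_up} up, {sel.n_down} down), "
          f"global permutation p = {perm.permutation_p:.4f}")

planted = set(truth.loc[truth["planted_resistance"], "probe"])
sel01 = rs.extract_signature(sig, 0.01)
rec = len(planted & set(sel01.probes)) / len(planted)
print(f"planted-gene recovery at P<0.01: {rec:.0%}")
# The permutation p near 1/1000 says the signature is far larger than
# chance; the recovery fraction says most truly shifted genes were found.
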