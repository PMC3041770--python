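# Methods

This note records the statistical models `resistsig` implements, the
defaults and tolerances it chooses where the workflow leaves them open, what
the synthetic generators do and do not emulate, and the package's known
limitations.

## Moderated tests and the random variance model

Expression is assumed log2-scale on input (RMA-style summaries); the
package never re-logs. The paired comparison forms per-gene post − pre
differences `d_g` over n pairs and tests their mean; the two-class
comparison uses the pooled-variance unpaired t. Both can moderate the
variance with the random variance model: reciprocal gene variances share a
Gamma(a, b) prior, equivalently variances are inverse-gamma, which makes
each sample variance marginally satisfy `s²·a·b ~ F(m, 2a)` with m the
residual degrees of freedom. The hyperparameters are fitted by maximising
this F likelihood over all genes with positive variance (Nelder–Mead on
(log a, log ab), five starts with median-matched scale; at least 50 genes
required; an all-equal variance vector is rejected as degenerate). The
moderated statistic replaces `s²` with the posterior variance
`(m·s² + 2/b)/(m + 2a)` and uses `m + 2a` degrees of freedom — under the
model this reference distribution is exact, which is what the null-
calibration tests exercise. With the prior off, the tests reduce to the
textbook paired/pooled t to machine precision (oracle suite). All p-values
are two-sided; direction is carried separately as the sign of t, with "up"
meaning higher at the post/resistant (or second) class.

## Permutation global significance

The global test counts genes significant at the feature-selection cutoff
and compares that count with label permutations: within-pair pre/post flips
for the paired design (the exchangeability unit is the within-patient
label), full label shuffles for two classes. Sampled mode uses the add-one
convention `(1 + #{null ≥ observed})/(B + 1)` so p is never zero; default
B = 1,000 with the seed recorded in the result. For ≤ 12 pairs an
exhaustive mode enumerates all 2^n sign patterns and reports the exact
proportion (the identity pattern included, so p ≥ 2^−n). The RVM prior is
fitted once to the observed residual variances and held fixed across
permutations; refitting per permutation would be closer to a full
re-analysis but changes the null counts only through the (stable)
hyperparameters, and holding it fixed keeps the permutation distribution a
function of a single fitted model.

## LS gene-set comparison

For a mapped set of N probes, `LS = mean(−ln p)` over the per-gene
univariate association p-values. The null is resampling-based: random
N-subsets of the ranked universe, drawn without replacement independently
per resample, with `ls_p = (1 + #{LS_resample ≥ LS_observed})/(R + 1)` and
R = 100,000 by default (reducible). Enrichment is one-sided in the
direction of small member p-values: a resampled set counts against the
observed one when its LS is at least as large. The workflow's prose
convention for this tail can be read either way; the implementation fixes
the direction as above and says so in the result metadata
(`direction_note`). Significance is flagged below 0.005. Per-gene survival
association uses a univariate Cox fit of the endpoint on each gene's log2
expression (vectorised Newton–Raphson, Breslow ties, two-sided Wald p);
non-convergent genes are kept with p = 1 and flagged, never dropped, and
the hazard ratio per two-fold change (one log2 unit) is retained.

## Compound covariate index and stratification

The index is exactly linear: `Σ_g t_g·x_{g,s}` with weights frozen from the
training comparison and the same log base as the input (log2 default,
recorded on the result). Unique-gene collapsing — needed when several
probes map to one symbol — keeps the probe with the largest |t| and records
the rule. Hazard-ratio conversion between index values is pure
exponentiation of the per-unit Cox hazard ratio.

Stratification clusters samples on the signature genes after per-gene
median centring, using 1 − Pearson correlation as the sample distance and
average linkage, cut at the top split into two clusters. Distance and
linkage are not dictated by the workflow; centred correlation with average
linkage matches the Cluster/heatmap lineage this analysis style descends
from, and both are arguments. The cluster with the higher mean centred
expression of the up-regulated arm is labelled high risk. Correlation is
undefined for a sample constant over the signature genes; that is a hard
error naming the sample.

## Survival models

Kaplan–Meier curves, log-rank tests and multivariable Cox fits go through
lifelines (Efron tie handling — endpoint times at monthly resolution
produce ties); ordinal response models are statsmodels' proportional-odds
logistic (`OrderedModel`, logit link) with the response ordered PR < SD <
PD and nonmeasurable patients excluded. The internal per-gene and
cross-validation Cox kernels use Breslow ties for speed; they are
cross-checked against lifelines on tie-free data, where the two tie rules
coincide.

Survival risk prediction uses supervised principal components: per fold,
genes with univariate Cox score p below 0.001 (falling back to the top 10
genes when fewer qualify) are centred and decomposed; 2 components are kept
(both thresholds are arguments); a Cox fit on the training scores gives the
prognostic index; left-out patients are classed by the training-median
threshold. The component count and within-fold selection level are choices,
not workflow facts. Folds are drawn once from the seed and reused across
permutations, which shuffles only the (time, event) pairs; the observed
labelling is never counted as a permutation (add-one convention). The
default of 100 permutations makes p resolvable to ~0.01.

## Synthetic data

The generators are the package's study-scale test bed, not a model of any
real accession. Defaults: 5,000 genes, 22 pairs, 101-patient cohort, 21
controls, 200 planted resistance genes with an up:down split matching the
468:165 asymmetry of the motivating signature, mean |shift| of 1.0 log2
units (SD one third of that) — a size at which the paired design recovers
≳ 90% of planted genes at P < 0.01, comfortably above the 70% the
acceptance suite requires. Gene variances come from the inverse-gamma prior
with a = 3, b = 2 (log2 residual SD mostly 0.3–0.6, typical of array
data); pre and post share a per-patient-per-gene baseline, so paired
differences have variance 2σ² and a prior fit to them recovers shape a and
scale b/2. The cohort carries a latent standard-normal resistance score:
planted genes load on it at half their acquired shift, TTP is exponential
with log-hazard 0.8 per score unit (baseline median 4 months), overall
survival uses a 0.6-attenuated coefficient (baseline median 8 months),
censoring is independent exponential (rate 0.02/month, capped at 36
months), and the ordered response follows a proportional-odds model on the
score with cutpoints set by a normal approximation to give roughly the
32/32/36 PR/SD/PD mix among measurable patients (13% nonmeasurable).
Healthy controls share the tumour baselines except for a disjoint planted
cancer set, so the resistance signature is non-enriched in the
cancer-vs-normal contrast by construction.

Not emulated: probe-level artefacts, batch effects, heavy-tailed noise,
gene–gene correlation beyond the single latent score, and non-proportional
hazards. Passing tests therefore demonstrate correctness of the statistics
under their own assumptions and end-to-end recoverability of planted
structure — not robustness to real-array pathologies.

## Numerical choices and scale of the checks

Sampled-vs-exact agreement is asserted within binomial error; LS and
permutation comparisons use a 1e−12 tolerance when testing `≥` between
floating-point statistics. Newton solvers cap steps (±2 per iteration for
per-gene fits, norm 5 for multivariate) and flag non-convergence rather
than silently reporting. Calibration checks run at reduced replicate
counts (400 repetitions for permutation and LS p-values at B = 79 and
R = 99; 60 repetitions of the full risk-prediction procedure at 50
patients and 19 permutations; 200 cohort simulations for the cluster-TTP
power property at 400 genes), sizes chosen so each Kolmogorov–Smirnov or
proportion bound still has resolving power while the suite stays quick.
The acceptance script runs the full default-scale study with B = 999
permutations and 20,000 LS resamples.

## Known limitations

* The LS resampling null treats genes as exchangeable; correlated genes
  make it anti-conservative on real arrays (as with any random-set null).
* The RVM fit assumes a single variance prior across all genes.
* Breslow ties in the internal Cox kernels differ slightly from Efron at
  heavy tie loads; the public `cox_fit` (lifelines, Efron) is the one to
  report.
* `knn_impute` is O(missing-probes × genes) and meant for external
  validation matrices, not for matrices that are mostly missing; the
  distance is root-mean-square over co-observed samples, and k = 10 by
  default (a common nearest-neighbour-averaging choice; the workflow does
  not fix one).
* Two-cluster stratification always returns two groups; it does not test
  whether two clusters are an appropriate description of the cohort.
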