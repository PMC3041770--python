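"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a matched pre/post chemotherapy expression study:

* ``simulate_paired`` — n matched pre/post tumour profiles in which a
  planted subset of "resistance" genes shifts at the post (chemoresistant)
  state; per-gene variances are drawn from the inverse-gamma prior of the
  random variance model, so the moderated tests see data from their own
  model.
* ``simulate_cohort`` — an independent pretreatment cohort whose
  progression hazard rises with a per-patient latent resistance score; the
  planted genes' expression correlates with that score, and an ordered
  radiographic response (PR/SD/PD) follows a proportional-odds model on it.
* ``simulate_normals`` — healthy-control profiles sharing the tumour gene
  baselines except for a disjoint planted cancer-vs-normal gene set, so the
  resistance and cancer-specific signatures are separable by construction.

All generators are deterministic functions of ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (CLINICAL_COLUMNS, ClinicalTable, ExpressionMatrix,
                         GeneSetCollection, PairedDesign)

__all__ = ["SimulationConfig", "simulate_paired", "simulate_cohort",
           "simulate_normals", "planted_gene_sets", "write_study"]


@dataclass
class SimulationConfig:
    """Study-scale and effect-size parameters for the synthetic generators.

    Defaults mirror the design of the motivating study: 22 rebiopsied
    pre/post pairs, an independent 101-patient cohort, 21 healthy controls,
    and a planted resistance signature whose up/down split follows the
    468:165 asymmetry of the discovered signature.
    """

    n_genes: int = 5000
    n_pairs: int = 22
    n_cohort: int = 101
    n_normals: int = 21
    n_true: int = 200          # planted resistance genes
    effect_mu: float = 1.0     # mean |post - pre| log2 shift of planted genes
    up_fraction: float = 468.0 / 633.0
    rvm_a: float = 3.0         # variance-prior shape (precision ~ Gamma(a, b))
    rvm_b: float = 2.0         # variance-prior scale
    baseline_mean: float = 7.0  # log2 RMA-like intensity level
    baseline_sd: float = 1.0
    patient_effect_scale: float = 1.0  # patient-gene baseline SD, x gene SD
    cohort_loading: float = 0.5  # shift fraction expressed per unit latent score
    hazard_coefficient: float = 0.8  # log-hazard of progression per unit score
    ttp_baseline_rate: float = float(np.log(2) / 4.0)  # median TTP ~ 4 months
    os_coefficient_factor: float = 0.6
    os_baseline_rate: float = float(np.log(2) / 8.0)   # median OS ~ 8 months
    censor_rate: float = 0.02  # per month, independent of outcome
    followup_cap_months: float = 36.0
    response_beta: float = 0.8  # proportional-odds slope on the latent score
    nonmeasurable_prob: float = 13.0 / 101.0
    n_cancer_genes: int = 200  # disjoint cancer-vs-normal planted set
    cancer_effect: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_pairs", "n_cohort", "n_normals", "n_true",
                     "n_cancer_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true + self.n_cancer_genes > self.n_genes:
            raise ValueError("planted sets exceed the number of genes")
        for name in ("up_fraction", "nonmeasurable_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rvm_a <= 0 or self.rvm_b <= 0:
            raise ValueError("variance-prior hyperparameters must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be nonnegative")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _gene_params(cfg: SimulationConfig) -> dict:
    """Gene-level parameters shared by all three generators (stream 0)."""
    rng = _rng(cfg, 0)
    G = cfg.n_genes
    probes = [f"g{i + 1:05d}" for i in range(G)]
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)
    precision = rng.gamma(shape=cfg.rvm_a, scale=cfg.rvm_b, size=G)
    sigma = 1.0 / np.sqrt(precision)
    planted = rng.choice(G, size=cfg.n_true + cfg.n_cancer_genes, replace=False)
    resist = planted[:cfg.n_true]
    cancer = planted[cfg.n_true:]
    n_up = int(round(cfg.up_fraction * cfg.n_true))
    direction = np.zeros(G)
    direction[resist[:n_up]] = 1.0
    direction[resist[n_up:]] = -1.0
    shift = np.zeros(G)
    shift[resist] = np.abs(rng.normal(cfg.effect_mu, cfg.effect_mu / 3.0,
                                      size=cfg.n_true)) if cfg.effect_mu > 0 \
        else 0.0
    cancer_dir = np.zeros(G)
    cancer_dir[cancer] = np.where(rng.random(cfg.n_cancer_genes) < 0.7, 1.0, -1.0)
    cancer_shift = np.zeros(G)
    cancer_shift[cancer] = np.abs(
        rng.normal(cfg.cancer_effect, cfg.cancer_effect / 3.0,
                   size=cfg.n_cancer_genes))
    return {
        "probes": probes, "mu": mu, "sigma": sigma,
        "resist_idx": resist, "direction": direction, "shift": shift,
        "cancer_idx": cancer, "cancer_direction": cancer_dir,
        "cancer_shift": cancer_shift,
    }


def _truth_table(gp: dict) -> pd.DataFrame:
    G = len(gp["probes"])
    planted = np.zeros(G, dtype=bool)
    planted[gp["resist_idx"]] = True
    cancer = np.zeros(G, dtype=bool)
    cancer[gp["cancer_idx"]] = True
    dirn = np.where(gp["direction"] > 0, "up",
                    np.where(gp["direction"] < 0, "down", ""))
    cdirn = np.where(gp["cancer_direction"] > 0, "up",
                     np.where(gp["cancer_direction"] < 0, "down", ""))
    return pd.DataFrame({
        "probe": gp["probes"],
        "planted_resistance": planted,
        "direction": dirn,
        "shift": gp["shift"],
        "planted_cancer": cancer,
        "cancer_direction": cdirn,
        "cancer_shift": gp["cancer_shift"],
        "sigma2": gp["sigma"] ** 2,
        "baseline_mean": gp["mu"],
    })


def simulate_paired(cfg: SimulationConfig
                    ) -> tuple[ExpressionMatrix, PairedDesign, pd.DataFrame]:
    """Matched pre/post profiles with a planted resistance signature.

    Pre and post values share a per-patient-per-gene baseline; planted genes
    additionally shift at the post state by ``~|Normal(effect_mu,
    effect_mu/3)|`` in their planted direction.  The returned truth table
    lists every gene's planted status, direction and shift.
    """
    gp = _gene_params(cfg)
    rng = _rng(cfg, 1)
    G, n = cfg.n_genes, cfg.n_pairs
    sigma = gp["sigma"][:, None]
    base = gp["mu"][:, None] + rng.normal(0.0, 1.0, (G, n)) * sigma \
        * cfg.patient_effect_scale
    pre = base + rng.normal(0.0, 1.0, (G, n)) * sigma
    post = base + rng.normal(0.0, 1.0, (G, n)) * sigma \
        + (gp["direction"] * gp["shift"])[:, None]
    pre_ids = [f"P{i + 1:02d}_pre" for i in range(n)]
    post_ids = [f"P{i + 1:02d}_post" for i in range(n)]
    values = np.concatenate([pre, post], axis=1)
    m = ExpressionMatrix(values, gp["probes"], pre_ids + post_ids)
    design = PairedDesign(pairs=list(zip(pre_ids, post_ids)),
                          patient_ids=[f"P{i + 1:02d}" for i in range(n)])
    return m, design, _truth_table(gp)


def simulate_cohort(cfg: SimulationConfig, truth: pd.DataFrame | None = None
                    ) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Independent pretreatment cohort with score-dependent progression.

    Each patient carries a latent resistance score ``s ~ N(0, 1)``; planted
    genes express ``direction * shift * cohort_loading * s`` on top of their
    baseline, time to progression is exponential with log-hazard
    ``hazard_coefficient * s``, overall survival uses the attenuated
    coefficient, and the ordered response follows a proportional-odds model
    on ``s``.  Censoring is independent (exponential, capped at the
    follow-up horizon).  The clinical table records ``latent_score`` and the
    realised signature score (standardised mean planted-up minus planted-
    down expression) for truth-recovery checks.
    """
    gp = _gene_params(cfg)
    if truth is not None and list(truth["probe"]) != gp["probes"]:
        raise ValueError("truth table does not match this configuration")
    rng = _rng(cfg, 2)
    G, n = cfg.n_genes, cfg.n_cohort
    s = rng.normal(0.0, 1.0, n)
    sigma = gp["sigma"][:, None]
    loading = (gp["direction"] * gp["shift"] * cfg.cohort_loading)[:, None]
    X = gp["mu"][:, None] + loading * s[None, :] \
        + rng.normal(0.0, 1.0, (G, n)) * sigma
    ids = [f"C{i + 1:03d}" for i in range(n)]
    m = ExpressionMatrix(X, gp["probes"], ids)

    def _endpoint(rate0: float, coef: float) -> tuple[np.ndarray, np.ndarray]:
        rate = rate0 * np.exp(coef * s)
        t_event = rng.exponential(1.0 / rate)
        if cfg.censor_rate > 0:
            t_cens = np.minimum(rng.exponential(1.0 / cfg.censor_rate, n),
                                cfg.followup_cap_months)
        else:
            t_cens = np.full(n, cfg.followup_cap_months)
        event = t_event <= t_cens
        return np.minimum(t_event, t_cens), event

    ttp, ttp_event = _endpoint(cfg.ttp_baseline_rate, cfg.hazard_coefficient)
    os_t, os_event = _endpoint(cfg.os_baseline_rate,
                               cfg.hazard_coefficient * cfg.os_coefficient_factor)

    # ordered response (PR best .. PD worst), proportional odds on s;
    # cutpoints from a normal approximation to the latent marginal so the
    # category mix resembles a ~32/32/36 split among measurable patients
    latent = cfg.response_beta * s + rng.logistic(0.0, 1.0, n)
    latent_sd = np.sqrt(cfg.response_beta**2 + np.pi**2 / 3.0)
    c1 = stats.norm.ppf(0.318) * latent_sd
    c2 = stats.norm.ppf(0.636) * latent_sd
    response = np.where(latent <= c1, "PR", np.where(latent <= c2, "SD", "PD"))
    response = response.astype(object)
    response[rng.random(n) < cfg.nonmeasurable_prob] = np.nan

    up = gp["direction"] > 0
    down = gp["direction"] < 0
    realized = X[up].mean(axis=0) - (X[down].mean(axis=0) if down.any() else 0.0)
    realized = (realized - realized.mean()) / realized.std(ddof=0)

    clin = pd.DataFrame({
        "patient_id": ids,
        "ttp_months": ttp, "ttp_event": ttp_event,
        "os_months": os_t, "os_event": os_event,
        "age_years": np.round(rng.normal(58.0, 8.0, n)).astype(int),
        "sex": np.where(rng.random(n) < 0.72, "M", "F"),
        "ecog_binary": (rng.random(n) < 0.07).astype(int),
        "histology": np.where(rng.random(n) < 0.6, "diffuse", "intestinal"),
        "response_category": response,
        "latent_score": s,
        "realized_score": realized,
    })
    return m, ClinicalTable(clin)


def simulate_normals(cfg: SimulationConfig) -> ExpressionMatrix:
    """Healthy-control profiles: shared baselines, minus the planted
    cancer-vs-normal shifts (tumours sit at baseline, so cancer-set genes
    with direction "up" are higher in tumours than in these controls)."""
    gp = _gene_params(cfg)
    rng = _rng(cfg, 3)
    G, n = cfg.n_genes, cfg.n_normals
    sigma = gp["sigma"][:, None]
    offset = (gp["cancer_direction"] * gp["cancer_shift"])[:, None]
    X = gp["mu"][:, None] - offset + rng.normal(0.0, 1.0, (G, n)) * sigma
    ids = [f"N{i + 1:02d}" for i in range(n)]
    return ExpressionMatrix(X, gp["probes"], ids)


def planted_gene_sets(truth: pd.DataFrame) -> GeneSetCollection:
    """GMT-style collection of the planted resistance (all/up/down) and
    cancer-specific sets, for enrichment checks against the truth."""
    sets = {}
    res = truth[truth["planted_resistance"]]
    sets["planted_resistance"] = list(res["probe"])
    up = list(res.loc[res["direction"] == "up", "probe"])
    down = list(res.loc[res["direction"] == "down", "probe"])
    if up:
        sets["planted_resistance_up"] = up
    if down:
        sets["planted_resistance_down"] = down
    cancer = truth[truth["planted_cancer"]]
    sets["planted_cancer"] = list(cancer["probe"])
    desc = {k: "planted by the synthetic generator" for k in sets}
    return GeneSetCollection(sets, desc)


def write_study(cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Generate the full synthetic study and write it as plain-text files.

    Emits the paired and cohort expression TSVs, the pairs CSV, the
    clinical CSV, a GMT of the planted sets, and the truth table TSV.
    Returns the mapping of artefact name to path.
    """
    import os

    from .data_model import write_expression_matrix, write_gmt

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    m_paired, design, truth = simulate_paired(cfg)
    m_cohort, clin = simulate_cohort(cfg, truth)
    m_norm = simulate_normals(cfg)

    paths["paired_matrix"] = p = os.path.join(outdir, "paired_expression.tsv")
    write_expression_matrix(m_paired, p)
    paths["cohort_matrix"] = p = os.path.join(outdir, "cohort_expression.tsv")
    write_expression_matrix(m_cohort, p)
    paths["normals_matrix"] = p = os.path.join(outdir, "normal_expression.tsv")
    write_expression_matrix(m_norm, p)
    paths["pairs"] = p = os.path.join(outdir, "pairs.csv")
    pd.DataFrame(design.pairs, columns=["pre_sample_id", "post_sample_id"]) \
        .assign(patient_id=design.patient_ids).to_csv(p, index=False)
    paths["clinical"] = p = os.path.join(outdir, "clinical.csv")
    clin.write_csv(p)
    paths["gene_sets"] = p = os.path.join(outdir, "planted_sets.gmt")
    write_gmt(planted_gene_sets(truth), p)
    paths["truth"] = p = os.path.join(outdir, "truth.tsv")
    truth.to_csv(p, sep="\t", index=False, lineterminator="\n")
    return paths
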