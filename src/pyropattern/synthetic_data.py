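"""Multi-cohort synthetic study generator with planted pattern structure.

Expression carries K planted sample patterns: a regulator panel whose
per-pattern means follow a shared ordered-level design (so the latent
score has pattern-level separation), signature genes loaded with
per-gene random permutations of the same centered levels (so every
pairwise pattern contrast is differential), and pure noise genes.
Survival hazard is log-linear (or step) in the latent score, and the
per-sample mutation burden is Poisson with a log-linear link on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from .data_io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .genomic_landscape import CNVCalls, MutationTable, NONSILENT_CLASSES


@dataclass
class SimulationConfig:
    seed: int = 0
    n_patterns: int = 3
    samples_per_pattern: int = 50
    n_regulators: int = 33
    n_signature_genes: int = 100
    n_noise_genes: int = 500
    delta: float = 2.0  # per-gene between-pattern shift, log2 units
    sigma: float = 1.0  # residual sd
    n_cohorts: int = 2
    batch_shift_sd: float = 1.0  # additive per (gene, cohort) offset sd
    batch_scale_range: tuple[float, float] = (0.7, 1.4)
    baseline_hazard: float = 0.002  # per day
    beta: float = -0.8  # log-hazard coefficient on the latent score
    censoring_fraction: float = 0.3
    latent_noise_sd: float = 0.5
    step_hazard: bool = False  # hazard jumps at latent score 0 instead
    step_log_hr: float = 1.5
    tmb_intercept: float = 1.0
    tmb_slope: float = 0.5
    silent_rate: float = 0.5  # extra Silent calls per sample (Poisson mean)
    cnv_rate: float = 0.1  # fraction of (panel gene, sample) pairs altered

    def __post_init__(self) -> None:
        if min(
            self.n_patterns,
            self.samples_per_pattern,
            self.n_regulators,
            self.n_signature_genes,
            self.n_noise_genes,
            self.n_cohorts,
        ) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring fraction must lie in [0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class SimulationTruth:
    pattern: pd.Series  # sample -> 1..K
    latent: pd.Series  # sample -> latent score L
    gene_roles: pd.Series  # gene -> regulator | signature | noise
    effects: pd.DataFrame  # gene x pattern true mean shift
    true_cutpoint: float | None = None


def _centered_levels(k: int) -> np.ndarray:
    return np.arange(k, dtype=float) - (k - 1) / 2.0


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[
    ExpressionMatrix,
    ClinicalTable,
    MutationTable,
    CNVCalls,
    GeneSetCollection,
    SimulationTruth,
]:
    """Generate one fully reproducible synthetic study from the config."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_patterns
    n = k * cfg.samples_per_pattern
    sample_ids = [f"S{i:04d}" for i in range(n)]
    pattern = np.repeat(np.arange(1, k + 1), cfg.samples_per_pattern)

    reg = [f"REG{i:03d}" for i in range(cfg.n_regulators)]
    sig = [f"SIG{i:04d}" for i in range(cfg.n_signature_genes)]
    noise = [f"NOISE{i:04d}" for i in range(cfg.n_noise_genes)]
    genes = reg + sig + noise
    g = len(genes)

    levels = _centered_levels(k)
    effects = np.zeros((g, k))
    # regulators share the level ordering: the pattern-level mean regulator
    # effect equals delta * level, which defines the latent score below
    for i in range(cfg.n_regulators):
        effects[i, :] = cfg.delta * levels
    # signature genes follow the same ordered levels up to a random sign,
    # so they track the latent score (and every pattern pair differs)
    sig_signs = rng.choice([-1.0, 1.0], size=cfg.n_signature_genes)
    for i in range(cfg.n_signature_genes):
        effects[cfg.n_regulators + i, :] = sig_signs[i] * cfg.delta * levels

    # latent score: pattern-level mean regulator effect plus a sample-level
    # deviation.  The deviation is a real latent factor expressed in the
    # downstream signature genes (not pure annotation noise); otherwise a
    # score built from expression could never track the within-pattern
    # variation that drives the hazard.  Regulators stay free of it so the
    # planted cluster structure is exactly the pattern labels.
    pattern_mean_effect = effects[: cfg.n_regulators, :].mean(axis=0)
    eta = rng.normal(0.0, cfg.latent_noise_sd, size=n)
    latent = pattern_mean_effect[pattern - 1] + eta

    baseline = rng.normal(6.0, 1.0, size=g)
    x = (
        baseline[:, None]
        + effects[:, pattern - 1]
        + rng.normal(0.0, cfg.sigma, size=(g, n))
    )
    sig_rows = slice(cfg.n_regulators, cfg.n_regulators + cfg.n_signature_genes)
    x[sig_rows, :] += sig_signs[:, None] * eta[None, :]

    # cohort assignment and additive + scale batch effects per (gene, cohort)
    cohort_idx = rng.integers(0, cfg.n_cohorts, size=n)
    cohorts = np.array([f"cohort{j}" for j in cohort_idx], dtype=object)
    shifts = rng.normal(0.0, cfg.batch_shift_sd, size=(g, cfg.n_cohorts))
    scales = rng.uniform(*cfg.batch_scale_range, size=(g, cfg.n_cohorts))
    x = x * scales[:, cohort_idx] + shifts[:, cohort_idx]

    expr = ExpressionMatrix(
        gene_ids=genes, sample_ids=sample_ids, values=x, scale="log2", cohort=cohorts
    )

    # survival: exponential with log-linear (or step) hazard in the latent
    if cfg.step_hazard:
        log_hr = cfg.step_log_hr * (latent > 0.0)
        true_cut = 0.0
    else:
        log_hr = cfg.beta * latent
        true_cut = None
    hazard = cfg.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_fraction > 0:
        # calibrate uniform censoring on (0, cmax] to the target fraction:
        # E[frac censored] = mean(min(T, cmax) / cmax)
        def frac(cmax: float) -> float:
            return float(np.mean(np.minimum(t_event, cmax) / cmax))

        lo, hi = 1e-6, float(t_event.max()) * 1e3
        target = cfg.censoring_fraction
        if frac(hi) > target or frac(lo) < target:
            raise ValueError("infeasible censoring target for these event times")
        cmax = brentq(lambda c: frac(c) - target, lo, hi, xtol=1e-9)
        c_time = rng.uniform(0.0, cmax, size=n)
        obs_time = np.minimum(t_event, c_time)
        event = (t_event <= c_time).astype(int)
    else:
        obs_time = t_event
        event = np.ones(n, dtype=int)
    obs_time = np.maximum(obs_time, 1e-3)  # keep times strictly positive

    clinical = pd.DataFrame(
        {
            "time": obs_time,
            "event": event,
            "age": np.round(rng.normal(62, 10, size=n)).astype(int),
            "pattern_truth": pattern,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # mutations: nonsilent burden ~ Poisson(exp(a + b * latent))
    mut_rate = np.exp(cfg.tmb_intercept + cfg.tmb_slope * latent)
    n_nonsilent = rng.poisson(mut_rate)
    n_silent = rng.poisson(cfg.silent_rate, size=n)
    mut_universe = reg + sig[: max(1, len(sig) // 2)]
    nonsilent_classes = sorted(NONSILENT_CLASSES)
    records = []
    for j, sid in enumerate(sample_ids):
        for _ in range(int(n_nonsilent[j])):
            records.append(
                (
                    sid,
                    mut_universe[rng.integers(len(mut_universe))],
                    nonsilent_classes[rng.integers(len(nonsilent_classes))],
                )
            )
        for _ in range(int(n_silent[j])):
            records.append(
                (sid, mut_universe[rng.integers(len(mut_universe))], "Silent")
            )
    mutations = MutationTable(
        pd.DataFrame(records, columns=["sample_id", "gene", "variant_classification"])
    )

    # CNV calls: sparse random states over the regulator panel
    cnv_records = []
    for gene in reg:
        hit = rng.random(n) < cfg.cnv_rate
        states = rng.choice([-2, -1, 1, 2], size=int(hit.sum()))
        for sid, st in zip(np.array(sample_ids)[hit], states):
            cnv_records.append((sid, gene, int(st)))
    cnv = CNVCalls(
        pd.DataFrame(cnv_records, columns=["sample_id", "gene", "state"])
        if cnv_records
        else pd.DataFrame({"sample_id": [], "gene": [], "state": []}).astype(
            {"state": int}
        )
    )

    gene_sets = GeneSetCollection({"REGULATOR_PANEL": reg})
    roles = ["regulator"] * len(reg) + ["signature"] * len(sig) + ["noise"] * len(noise)
    truth = SimulationTruth(
        pattern=pd.Series(pattern, index=sample_ids, name="pattern"),
        latent=pd.Series(latent, index=sample_ids, name="latent"),
        gene_roles=pd.Series(roles, index=genes, name="role"),
        effects=pd.DataFrame(effects, index=genes, columns=list(range(1, k + 1))),
        true_cutpoint=true_cut,
    )
    return expr, ClinicalTable(clinical), mutations, cnv, gene_sets, truth


def truth_metrics(
    truth: SimulationTruth,
    assignments: pd.Series | np.ndarray | None = None,
    ps: pd.Series | None = None,
    deg_set=None,
) -> dict[str, float]:
    """Compare pipeline outputs against generator truth.

    Returns whichever of ari, spearman_L_ps, de_recall, de_false_inclusion
    can be computed from the supplied arguments.
    """
    out: dict[str, float] = {}
    if assignments is not None:
        if isinstance(assignments, pd.Series):
            if not assignments.index.equals(truth.pattern.index):
                if set(assignments.index) != set(truth.pattern.index):
                    raise ValueError("assignment sample ids do not match truth")
                assignments = assignments.loc[truth.pattern.index]
            labels = assignments.to_numpy()
        else:
            labels = np.asarray(assignments)
            if labels.size != truth.pattern.size:
                raise ValueError("assignment length does not match truth")
        out["ari"] = float(adjusted_rand_score(truth.pattern.to_numpy(), labels))
    if ps is not None:
        if not set(ps.index) == set(truth.latent.index):
            raise ValueError("score sample ids do not match truth")
        aligned = ps.loc[truth.latent.index]
        rho = spearmanr(aligned.to_numpy(), truth.latent.to_numpy()).statistic
        out["spearman_L_ps"] = float(rho)
    if deg_set is not None:
        true_sig = set(truth.gene_roles.index[truth.gene_roles == "signature"])
        null_genes = set(truth.gene_roles.index[truth.gene_roles == "noise"])
        found = set(deg_set.genes)
        out["de_recall"] = len(found & true_sig) / len(true_sig) if true_sig else 0.0
        # regulators also carry the pattern, so only noise genes count as false
        out["de_false_inclusion"] = (
            len(found & null_genes) / len(found) if found else 0.0
        )
    return out
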