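"""Per-sample pattern quantification: univariate Cox screening of the
overlap signature genes, a centered two-component PCA signature, the
per-sample score (PC1 coordinate + PC2 coordinate), and survival
stratification at a maximally selected log-rank cutpoint."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_io import ClinicalTable, ExpressionMatrix
from .differential_expression import OverlapDEGSet
from .survival_stats import cox_fit, logrank_z_scan


@dataclass
class PSModel:
    genes: list[str]
    centers: np.ndarray  # per-gene means on the training data (log2 units)
    w1: np.ndarray  # first component loadings, unit norm
    w2: np.ndarray  # second component loadings, unit norm
    variance_explained: tuple[float, float]
    sign_rule: str = "largest-loading-positive"
    orientation_flipped: bool = False


@dataclass
class PSResult:
    ps: pd.Series  # per-sample score
    cutpoint: float
    group: pd.Series  # 'high' / 'low'
    minprop: float
    max_abs_z: float
    p_value: float | None = None


def screen_prognostic(
    m: ExpressionMatrix,
    c: ClinicalTable,
    genes: OverlapDEGSet | list[str],
    alpha: float = 0.05,
) -> list[str]:
    """Genes whose univariate Cox Wald p < alpha; input order preserved."""
    gene_list = genes.genes if isinstance(genes, OverlapDEGSet) else list(genes)
    common = [s for s in m.sample_ids if s in set(c.sample_ids)]
    if len(common) < 3:
        raise ValueError("too few samples shared by expression and clinical data")
    sub = m.subset_samples(common)
    clin = c.subset(common)
    if clin.event.sum() < 10:
        raise ValueError("fewer than 10 events: screening would be unreliable")
    idx = sub.gene_index()
    selected = []
    for g in gene_list:
        if g not in idx:
            warnings.warn(f"gene {g!r} not in expression matrix; skipped")
            continue
        x = sub.values[idx[g]]
        if np.ptp(x) == 0:
            warnings.warn(f"gene {g!r} constant across samples; skipped")
            continue
        try:
            fit = cox_fit(x, clin.time, clin.event, names=[g])
        except ValueError as exc:
            warnings.warn(f"gene {g!r} skipped: {exc}")
            continue
        if fit.p[0] < alpha:
            selected.append(g)
    if not selected:
        raise ValueError(
            "no gene passed the prognostic screen; consider raising alpha"
        )
    return selected


def _apply_sign_rule(w: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(w)))
    return -w if w[i] < 0 else w


def fit_ps_model(m: ExpressionMatrix) -> PSModel:
    """Centered (unscaled) PCA of the prognostic-gene expression.

    Loadings are the first two principal directions over genes; each is
    sign-fixed so its largest-|entry| coefficient is positive.
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes for a two-component model")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    x = m.values.astype(float)
    centers = x.mean(axis=1)
    xc = x - centers[:, None]
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    tol = max(xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if (s > tol).sum() < 2:
        raise ValueError("centered expression has rank < 2")
    w1 = _apply_sign_rule(u[:, 0])
    w2 = _apply_sign_rule(u[:, 1])
    total = float((s**2).sum())
    ve = (float(s[0] ** 2) / total, float(s[1] ** 2) / total)
    return PSModel(
        genes=list(m.gene_ids), centers=centers, w1=w1, w2=w2, variance_explained=ve
    )


def compute_ps(model: PSModel, m: ExpressionMatrix) -> pd.Series:
    """Score = <x - centers, w1> + <x - centers, w2> per sample."""
    idx = m.gene_index()
    missing = [g for g in model.genes if g not in idx]
    if missing:
        raise ValueError(f"model genes missing from matrix: {missing[:10]}")
    rows = [idx[g] for g in model.genes]
    xc = m.values[rows, :] - model.centers[:, None]
    ps = (model.w1 + model.w2) @ xc
    return pd.Series(ps, index=m.sample_ids, name="ps")


def orient_protective(
    model: PSModel, m: ExpressionMatrix, c: ClinicalTable
) -> tuple[PSModel, pd.Series]:
    """Flip the model's components (recorded, never silent) so that a higher
    score associates with lower hazard on the given training data.

    Returns the (possibly flipped) model and the oriented scores.
    """
    ps = compute_ps(model, m)
    clin = c.subset(list(ps.index))
    fit = cox_fit(ps.to_numpy(), clin.time, clin.event, names=["ps"])
    if fit.beta[0] > 0:
        model = replace(
            model, w1=-model.w1, w2=-model.w2, orientation_flipped=True
        )
        ps = -ps
        warnings.warn("score orientation flipped so that high score is protective")
    return model, ps


def find_cutpoint(
    ps,
    c: ClinicalTable,
    minprop: float = 0.1,
    n_perm: int = 0,
    seed: int = 0,
) -> PSResult:
    """Maximally selected log-rank cutpoint on the score.

    Candidates are midpoints of consecutive sorted unique score values
    whose split leaves at least ``minprop`` of samples on each side; the
    cut maximizing |standardized log-rank statistic| wins, ties to the
    lower cutpoint.  ``n_perm > 0`` adds a permutation p-value in which
    the scan is re-maximized per permutation.
    """
    if isinstance(ps, pd.Series):
        ids = list(ps.index)
        values = ps.to_numpy(dtype=float)
    else:
        values = np.asarray(ps, dtype=float)
        ids = list(c.sample_ids)
        if values.size != len(ids):
            raise ValueError("score vector does not align with clinical table")
    clin = c.subset(ids)
    times, events = clin.time, clin.event
    if events.sum() == 0:
        raise ValueError("no events: cannot select a cutpoint")

    n = values.size
    min_count = int(np.ceil(minprop * n))
    uniq = np.unique(values)
    candidates = []
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        n_high = int((values > cut).sum())
        if n_high >= min_count and (n - n_high) >= min_count:
            candidates.append(cut)
    if not candidates:
        raise ValueError("no admissible cutpoint under the minprop constraint")

    cand_arr = np.asarray(candidates, dtype=float)

    def scan(ev_times, ev_events, vals) -> tuple[float, float]:
        z = np.abs(logrank_z_scan(ev_times, ev_events, vals, cand_arr))
        best = int(np.argmax(z))  # argmax returns the first (lowest) maximizer
        return float(cand_arr[best]), float(z[best])

    cutpoint, max_abs_z = scan(times, events, values)
    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            _, stat = scan(times[perm], events[perm], values)
            if stat >= max_abs_z - 1e-12:
                exceed += 1
        p_value = (1 + exceed) / (n_perm + 1)

    group = pd.Series(
        np.where(values > cutpoint, "high", "low"), index=ids, name="group"
    )
    return PSResult(
        ps=pd.Series(values, index=ids, name="ps"),
        cutpoint=float(cutpoint),
        group=group,
        minprop=minprop,
        max_abs_z=float(max_abs_z),
        p_value=p_value,
    )
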