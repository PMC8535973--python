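"""Moderated group-contrast statistics on log2 expression.

A one-way layout pools residual variance across all groups per gene;
empirical-Bayes hyperparameters (prior df d0, prior variance s0sq) are
fitted by moment matching on log sample variances, and the per-gene
posterior variance shrinks the observed variance toward the prior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class ContrastTable:
    contrast: tuple    # (group_a, group_b); difference is a - b
    table: pd.DataFrame  # index gene: diff, t, p, fdr, flagged
    d0: float
    s0sq: float
    residual_df: int


@dataclass
class OverlapDEGSet:
    genes: list[str]
    qualification: pd.DataFrame  # genes x contrasts, boolean
    fdr_threshold: float


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (position-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by safeguarded Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y  # standard starting value
    lo, hi = 1e-12, 1e12
    for _ in range(max_iter):
        f = float(special.polygamma(1, x)) - y
        if f > 0:  # trigamma decreasing: f>0 means x too small
            lo = max(lo, x)
        else:
            hi = min(hi, x)
        fprime = float(special.polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) < tol * (1 + abs(x)):
            return x_new
        x = x_new
    raise RuntimeError("trigamma_inverse did not converge")


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0sq) from per-gene sample variances.

    Matches mean and variance of log(s2) against the scaled-F model.
    Degenerate spread (all variances equal, or less dispersed than the
    chi-square alone implies) yields d0 = +inf with s0sq the geometric
    mean of the variances.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        warnings.warn("too few positive variances to fit a prior; using d0=inf")
        s0 = float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 1.0
        return math.inf, s0
    z = np.log(s2[ok])
    zbar = float(z.mean())
    evar = float(z.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, float(np.exp(zbar))
    try:
        d0 = 2.0 * trigamma_inverse(evar)
    except RuntimeError:
        warnings.warn("prior-df solve did not converge; falling back to d0=inf")
        return math.inf, float(np.exp(zbar))
    log_s0 = (
        zbar
        - (float(special.digamma(df / 2.0)) - math.log(df / 2.0))
        + (float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    )
    return d0, float(np.exp(log_s0))


def moderated_de(
    m,
    groups: dict[str, object],
    contrasts: list[tuple] | None = None,
    d0: float | None = None,
) -> list[ContrastTable]:
    """Moderated two-group statistics for each requested contrast.

    ``m`` is a log2-scale ExpressionMatrix; ``groups`` maps sample id to
    cluster label.  ``contrasts`` defaults to all label pairs.  ``d0``
    forces the prior degrees of freedom (0 = ordinary t, inf = fully
    pooled); by default it is fitted from the data.
    """
    if m.scale != "log2":
        raise ValueError("moderated_de expects log2 expression")
    missing = [s for s in m.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:10]}")
    labels = np.array([groups[s] for s in m.sample_ids], dtype=object)
    uniq = sorted(set(labels), key=str)
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
    for a, b in contrasts:
        for g in (a, b):
            if (labels == g).sum() < 2:
                raise ValueError(f"contrast group {g!r} has fewer than 2 samples")

    x = m.values
    n = x.shape[1]
    k = len(uniq)
    df_resid = n - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    group_masks = {g: labels == g for g in uniq}
    means = {g: x[:, msk].mean(axis=1) for g, msk in group_masks.items()}
    rss = np.zeros(x.shape[0])
    for g, msk in group_masks.items():
        rss += ((x[:, msk] - means[g][:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid
    zero_var = s2 <= 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} genes with zero residual variance")

    if d0 is None:
        d0_fit, s0sq = fit_variance_prior(s2[~zero_var], df_resid)
    else:
        d0_fit = float(d0)
        _, s0sq = fit_variance_prior(s2[~zero_var], df_resid)
    if math.isinf(d0_fit):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0_fit == 0:
        s2_post = s2.copy()
        df_total = df_resid
    else:
        s2_post = (d0_fit * s0sq + df_resid * s2) / (d0_fit + df_resid)
        df_total = d0_fit + df_resid

    out = []
    for a, b in contrasts:
        na = group_masks[a].sum()
        nb = group_masks[b].sum()
        diff = means[a] - means[b]
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
        if math.isinf(df_total):
            p = 2 * stats.norm.sf(np.abs(t))
        else:
            p = 2 * stats.t.sf(np.abs(t), df=df_total)
        # a gene with no residual variance anywhere carries no evidence
        p = np.where(zero_var, 1.0, p)
        t = np.where(zero_var, 0.0, t)
        table = pd.DataFrame(
            {
                "diff": diff,
                "t": t,
                "p": p,
                "fdr": bh_fdr(p),
                "flagged": zero_var,
            },
            index=m.gene_ids,
        )
        out.append(
            ContrastTable(
                contrast=(a, b),
                table=table,
                d0=d0_fit,
                s0sq=float(s0sq),
                residual_df=df_resid,
            )
        )
    return out


def overlap_degs(
    tables: list[ContrastTable], fdr_threshold: float = 0.01
) -> OverlapDEGSet:
    """Genes significant (fdr < threshold) in EVERY contrast."""
    if not tables:
        raise ValueError("no contrast tables supplied")
    universe = list(tables[0].table.index)
    for ct in tables[1:]:
        if list(ct.table.index) != universe:
            raise ValueError("contrast tables cover different gene universes")
    qual = pd.DataFrame(
        {
            f"{ct.contrast[0]}_vs_{ct.contrast[1]}": ct.table["fdr"] < fdr_threshold
            for ct in tables
        },
        index=universe,
    )
    members = [g for g in universe if bool(qual.loc[g].all())]
    return OverlapDEGSet(genes=members, qualification=qual, fdr_threshold=fdr_threshold)
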