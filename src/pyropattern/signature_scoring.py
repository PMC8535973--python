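"""Per-sample gene-set enrichment (rank-based running sum), combined
immune/stromal scoring with a purity transform, and hypergeometric
over-representation analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, GeneSetCollection
from .differential_expression import bh_fdr

# Purity transform constants: cos(a + b * combined_score).  Overridable
# per call; defaults follow the published expression-based purity fit.
PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


@dataclass
class SsgseaProfile:
    sample_ids: list[str]
    signatures: list[str]
    scores: np.ndarray  # signatures x samples
    alpha: float
    normalized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.signatures, columns=self.sample_ids)


@dataclass
class EstimateResult:
    sample_ids: list[str]
    immune_score: np.ndarray
    stromal_score: np.ndarray
    estimate_score: np.ndarray
    purity: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "immune_score": self.immune_score,
                "stromal_score": self.stromal_score,
                "estimate_score": self.estimate_score,
                "purity": self.purity,
            },
            index=self.sample_ids,
        )


def _sample_scores(expr_col: np.ndarray, hit_mask: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment score for one sample.

    Genes are walked in decreasing expression order.  In-set steps are
    weighted by rank^alpha where rank is the average ascending rank
    (highest expression = N); out-of-set steps are uniform.
    """
    n = expr_col.size
    order = np.argsort(-expr_col, kind="stable")
    asc_rank = stats.rankdata(expr_col)  # ties -> average; N = top
    weights = np.abs(asc_rank) ** alpha
    hits = hit_mask[order]
    w_o = weights[order]
    n_hits = int(hits.sum())
    p_in = np.cumsum(np.where(hits, w_o, 0.0))
    denom_in = p_in[-1]
    p_in = p_in / denom_in
    p_out = np.cumsum(~hits) / (n - n_hits)
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> SsgseaProfile:
    """Single-sample enrichment scores for every set in the collection.

    Scores depend only on within-sample expression ranks.  With
    ``normalize`` each signature is min-max rescaled across samples.
    """
    gene_pos = m.gene_index()
    n = m.n_genes
    masks: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        matched = [g for g in members if g in gene_pos]
        dropped = len(members) - len(matched)
        if dropped:
            warnings.warn(f"set {name!r}: {dropped} members not in matrix")
        if not matched:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if len(matched) == n:
            raise ValueError(f"gene set {name!r} covers every gene in the matrix")
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in matched]] = True
        masks[name] = mask

    names = list(masks)
    scores = np.empty((len(names), m.n_samples))
    for j in range(m.n_samples):
        col = m.values[:, j]
        for i, name in enumerate(names):
            scores[i, j] = _sample_scores(col, masks[name], alpha)
    if normalize:
        lo = scores.min(axis=1, keepdims=True)
        hi = scores.max(axis=1, keepdims=True)
        rng = np.where(hi > lo, hi - lo, 1.0)
        scores = (scores - lo) / rng
    return SsgseaProfile(
        sample_ids=list(m.sample_ids),
        signatures=names,
        scores=scores,
        alpha=alpha,
        normalized=normalize,
    )


def estimate_scores(
    m: ExpressionMatrix,
    stromal_set: list[str],
    immune_set: list[str],
    alpha: float = 0.25,
    purity_intercept: float = PURITY_INTERCEPT,
    purity_slope: float = PURITY_SLOPE,
) -> EstimateResult:
    """Immune/stromal enrichment, their sum, and a cosine purity estimate."""
    sets = GeneSetCollection({"stromal": stromal_set, "immune": immune_set})
    profile = ssgsea_score(m, sets, alpha=alpha, normalize=False)
    frame = profile.to_frame()
    stromal = frame.loc["stromal"].to_numpy()
    immune = frame.loc["immune"].to_numpy()
    combined = stromal + immune
    arg = purity_intercept + purity_slope * combined
    outside = (arg <= 0) | (arg >= np.pi / 2)
    if outside.any():
        warnings.warn(
            f"purity argument outside (0, pi/2) for {int(outside.sum())} samples; clamped"
        )
    purity = np.cos(arg)
    purity = np.clip(purity, np.finfo(float).tiny, 1.0)
    return EstimateResult(
        sample_ids=list(m.sample_ids),
        immune_score=immune,
        stromal_score=stromal,
        estimate_score=combined,
        purity=purity,
    )


def ora_enrich(
    query: list[str], universe: list[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against gene sets.

    Returns a frame (set, set_size, overlap, p, fdr) sorted by p ascending.
    """
    if not query:
        raise ValueError("empty query gene list")
    universe_list = list(dict.fromkeys(universe))
    if len(universe_list) != len(universe):
        raise ValueError("universe contains duplicates")
    uni = set(universe_list)
    offenders = [g for g in query if g not in uni]
    if offenders:
        raise ValueError(f"query genes outside universe: {offenders[:10]}")
    q = set(query)
    rows = []
    for name, members in sets.items():
        in_uni = uni & set(members)
        overlap = len(in_uni & q)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(in_uni), len(q)))
        rows.append(
            {"set": name, "set_size": len(in_uni), "overlap": overlap, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p", kind="stable", ignore_index=True)
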