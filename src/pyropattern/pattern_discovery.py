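"""Subsampled consensus clustering over a curated gene panel.

Samples are repeatedly subsampled (items only; the panel is too small
for gene subsampling to be stable), clustered with a base method, and
the co-clustering frequency among co-sampled pairs forms the consensus
matrix.  Model selection uses the proportion of ambiguous clustering
(PAC) of the consensus CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .data_io import ExpressionMatrix


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]  # k -> n x n consensus matrix
    assignments: dict[int, np.ndarray]  # k -> per-sample labels in 1..k
    pac: dict[int, float]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # k -> (grid, CDF values)
    delta_area: dict[int, float]
    reps: int
    p_item: float
    sample_ids: list[str] = field(default_factory=list)
    pac_bounds: tuple[float, float] = (0.1, 0.9)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).all():
        raise ValueError("constant expression panel: degenerate distance")
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _base_cluster(data: np.ndarray, k: int, method: str, seed: int) -> np.ndarray:
    """Cluster rows of ``data`` (samples x genes) into k groups."""
    if method == "kmeans":
        # one random restart per repetition: local-optimum variability is
        # part of the consensus sampling (a deterministic best-of-many fit
        # can make a wrong k look perfectly stable)
        km = KMeans(n_clusters=k, n_init=1, random_state=seed)
        return km.fit_predict(data)
    if method == "hierarchical":
        # 1 - Spearman correlation between samples
        ranks = np.apply_along_axis(rankdata, 1, data)
        corr = np.corrcoef(ranks)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        z = linkage(squareform(dist, checks=False), method="average")
        return fcluster(z, t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown base method {method!r}")


def assign_clusters(
    consensus_matrix: np.ndarray, k: int, sample_ids: list[str] | None = None
) -> np.ndarray:
    """Average-linkage cut of 1 - consensus into k groups.

    Labels are 1..k, renumbered by descending group size; ties broken by
    the smallest member sample id (index order when ids are absent).
    """
    c = np.asarray(consensus_matrix, dtype=float)
    n = c.shape[0]
    if c.shape != (n, n):
        raise ValueError("consensus matrix must be square")
    if not np.allclose(c, c.T, atol=1e-12):
        raise ValueError("consensus matrix must be symmetric")
    if c.min() < -1e-12 or c.max() > 1 + 1e-12:
        raise ValueError("consensus entries must lie in [0, 1]")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    if k == 1:
        return np.ones(n, dtype=int)
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    return _renumber_by_size(raw, sample_ids)


def _renumber_by_size(raw: np.ndarray, sample_ids: list[str] | None) -> np.ndarray:
    ids = sample_ids if sample_ids is not None else [f"{i:09d}" for i in range(len(raw))]
    labels = np.unique(raw)
    keyed = []
    for lab in labels:
        members = [ids[i] for i in np.flatnonzero(raw == lab)]
        keyed.append((-len(members), min(members), lab))
    keyed.sort()
    mapping = {old: new + 1 for new, (_, _, old) in enumerate(keyed)}
    return np.array([mapping[v] for v in raw], dtype=int)


def consensus_cluster(
    m: ExpressionMatrix,
    k_range,
    reps: int = 1000,
    p_item: float = 0.8,
    base_method: str = "kmeans",
    seed: int = 0,
    pac_bounds: tuple[float, float] = (0.1, 0.9),
    subsample_indices: list[np.ndarray] | None = None,
) -> ConsensusResult:
    """Consensus clustering of samples over the matrix's gene panel.

    ``subsample_indices`` optionally fixes the per-repetition subsamples
    (used for equivariance testing); otherwise per-rep seeds are derived
    from the master seed by a counter, independent of execution order.
    """
    k_range = sorted(int(k) for k in k_range)
    if any(k < 2 for k in k_range):
        raise ValueError("k_range entries must be >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0 < p_item <= 1):
        raise ValueError("p_item must lie in (0, 1]")
    n = m.n_samples
    if max(k_range) >= n:
        raise ValueError(f"max k {max(k_range)} must be < n samples {n}")
    x = _standardize_rows(m.values.astype(float))
    data = x.T  # samples x genes

    n_sub = max(int(round(p_item * n)), max(k_range) + 1)
    if subsample_indices is None:
        master = np.random.SeedSequence(seed)
        rep_seeds = master.generate_state(reps)
        subsample_indices = []
        for r in range(reps):
            rng = np.random.default_rng(rep_seeds[r])
            subsample_indices.append(np.sort(rng.choice(n, size=n_sub, replace=False)))
    else:
        if len(subsample_indices) != reps:
            raise ValueError("subsample_indices must supply one index set per rep")
        rep_seeds = np.random.SeedSequence(seed).generate_state(reps)

    # co-sampling counts are k-independent
    co_sampled = np.zeros((n, n))
    for idx in subsample_indices:
        co_sampled[np.ix_(idx, idx)] += 1

    consensus: dict[int, np.ndarray] = {}
    assignments: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    cdfs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    areas: dict[int, float] = {}
    u1, u2 = pac_bounds

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pairs never co-subsampled; "
            "their consensus is defined as 0"
        )

    for k in k_range:
        co_clustered = np.zeros((n, n))
        for r, idx in enumerate(subsample_indices):
            labels = _base_cluster(data[idx], k, base_method, int(rep_seeds[r]))
            for lab in np.unique(labels):
                members = idx[labels == lab]
                co_clustered[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(co_sampled > 0, co_clustered / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2
        consensus[k] = cons
        assignments[k] = assign_clusters(cons, k, m.sample_ids)
        tri = cons[np.triu_indices(n, k=1)]
        grid = np.concatenate([[0.0], np.sort(tri), [1.0]])
        cdf_vals = np.searchsorted(np.sort(tri), grid, side="right") / tri.size
        cdfs[k] = (grid, cdf_vals)
        pac[k] = float((tri <= u2).mean() - (tri <= u1).mean())
        areas[k] = float(np.trapezoid(cdf_vals, grid))

    delta_area: dict[int, float] = {}
    prev = None
    for k in k_range:
        if prev is None:
            delta_area[k] = areas[k]
        else:
            delta_area[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] else 0.0
        prev = k

    return ConsensusResult(
        k_range=list(k_range),
        consensus=consensus,
        assignments=assignments,
        pac=pac,
        cdf=cdfs,
        delta_area=delta_area,
        reps=reps,
        p_item=p_item,
        sample_ids=list(m.sample_ids),
        pac_bounds=(u1, u2),
    )


def select_k(r: ConsensusResult, method: str = "pac", forced_k: int | None = None) -> int:
    """Pick the number of clusters: minimum PAC, ties to the smaller k."""
    if forced_k is not None:
        if forced_k not in r.k_range:
            raise ValueError(f"forced_k={forced_k} outside k_range {r.k_range}")
        return int(forced_k)
    if method != "pac":
        raise ValueError(f"unknown selection method {method!r}")
    best = min(r.k_range, key=lambda k: (r.pac[k], k))
    return int(best)
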