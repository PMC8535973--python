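"""Independent brute-force reference implementations used by the tests.

Everything here is written in plain Python (loops, enumeration, grids)
and deliberately shares no code with the package implementation.
"""

from __future__ import annotations

import math
from itertools import combinations


# ---------------------------------------------------------------------------
# single-sample enrichment running sum
# ---------------------------------------------------------------------------


def ssgsea_oracle(values, gene_names, set_members, alpha):
    """Plain-loop running-sum enrichment score for one sample."""
    n = len(values)
    # average ascending ranks with ties (1 = lowest, n = highest)
    by_value = sorted(range(n), key=lambda i: values[i])
    asc = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[by_value[j + 1]] == values[by_value[i]]:
            j += 1
        avg_rank = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            asc[by_value[t]] = avg_rank
        i = j + 1
    # walk order: decreasing value, original index breaks ties
    order = sorted(range(n), key=lambda i: (-values[i], i))
    hits = set(set_members)
    is_hit = [gene_names[i] in hits for i in order]
    weights = [abs(asc[i]) ** alpha for i in order]
    total_in = sum(w for w, h in zip(weights, is_hit) if h)
    n_out = sum(1 for h in is_hit if not h)
    p_in = 0.0
    p_out = 0.0
    score = 0.0
    for w, h in zip(weights, is_hit):
        if h:
            p_in += w / total_in
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


def ssgsea_alpha0_oracle(values, gene_names, set_members):
    """Unweighted variant: P_in is the hit-count fraction."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    hits = set(set_members)
    n_in = sum(1 for i in order if gene_names[i] in hits)
    n_out = n - n_in
    p_in = 0.0
    p_out = 0.0
    score = 0.0
    for i in order:
        if gene_names[i] in hits:
            p_in += 1.0 / n_in
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_oracle(pvals):
    """Benjamini-Hochberg by explicit sort and reverse cumulative minimum."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    scaled = [pvals[idx] * m / (rank + 1) for rank, idx in enumerate(indexed)]
    running = float("inf")
    adjusted_sorted = [0.0] * m
    for rank in range(m - 1, -1, -1):
        running = min(running, scaled[rank])
        adjusted_sorted[rank] = min(running, 1.0)
    out = [0.0] * m
    for rank, idx in enumerate(indexed):
        out[idx] = adjusted_sorted[rank]
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def cox_loglik_oracle(beta, x, times, events):
    """Breslow partial log-likelihood, direct risk-set enumeration (1 covar)."""
    n = len(times)
    ll = 0.0
    for i in range(n):
        if events[i]:
            denom = sum(
                math.exp(beta * x[j]) for j in range(n) if times[j] >= times[i]
            )
            ll += beta * x[i] - math.log(denom)
    return ll


def cox_beta_grid_oracle(x, times, events, lo=-5.0, hi=5.0):
    """Maximize the Breslow partial likelihood by iterated grid refinement."""
    for _ in range(8):
        grid = [lo + (hi - lo) * i / 200.0 for i in range(201)]
        best = max(grid, key=lambda b: cox_loglik_oracle(b, x, times, events))
        width = (hi - lo) / 200.0
        lo, hi = best - 2 * width, best + 2 * width
    return best


# ---------------------------------------------------------------------------
# counting / enumeration tests
# ---------------------------------------------------------------------------


def hypergeom_upper_tail_oracle(overlap, population, successes, draws):
    """P(X >= overlap) by summing hypergeometric point masses."""
    total = math.comb(population, draws)
    p = 0.0
    for x in range(overlap, min(successes, draws) + 1):
        if draws - x <= population - successes:
            p += math.comb(successes, x) * math.comb(population - successes, draws - x) / total
    return p


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher exact p by enumerating tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point_prob(x):
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(n, c1)
        )

    observed = point_prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(
        point_prob(x) for x in range(lo, hi + 1) if point_prob(x) <= observed * (1 + 1e-7)
    )


def average_linkage_oracle(dist, k):
    """Naive agglomerative average linkage; returns a partition (frozensets).

    ``dist`` is a full symmetric matrix (list of lists).
    """
    clusters = [frozenset([i]) for i in range(len(dist))]
    while len(clusters) > k:
        best = None
        best_d = float("inf")
        for i, j in combinations(range(len(clusters)), 2):
            d = sum(dist[a][b] for a in clusters[i] for b in clusters[j]) / (
                len(clusters[i]) * len(clusters[j])
            )
            if d < best_d - 1e-15:
                best_d = d
                best = (i, j)
        i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [merged]
    return set(clusters)


def mw_auc_oracle(case_markers, control_markers):
    """Mann-Whitney AUC by explicit pair counting (ties 0.5)."""
    num = 0.0
    for mc in case_markers:
        for mk in control_markers:
            if mc > mk:
                num += 1.0
            elif mc == mk:
                num += 0.5
    return num / (len(case_markers) * len(control_markers))
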