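"""Survival estimators and association tests.

Kaplan-Meier, multi-group log-rank, Cox proportional hazards (Newton-
Raphson on the Breslow partial likelihood with step-halving), IPCW
time-dependent ROC AUC, rank/location group comparisons, and Spearman
association with exact small-sample inference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMFit:
    event_times: np.ndarray  # distinct event times, sorted
    survival: np.ndarray  # S(t) at each event time
    variance: np.ndarray  # Greenwood variance of S(t)
    at_risk: np.ndarray  # risk-set size just before each event time

    def survival_at(self, t: float) -> float:
        """Left-continuous product-limit estimate evaluated at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValueError("events must be binary 0/1")
    return times, events.astype(int)


def km_fit(times, events) -> KMFit:
    """Product-limit survival estimate with Greenwood variance."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    distinct = np.unique(t_sorted[e_sorted == 1])
    n = len(times)
    surv, var, risk = [], [], []
    s = 1.0
    greenwood = 0.0
    for t in distinct:
        n_at_risk = int((t_sorted >= t).sum())
        d = int(((t_sorted == t) & (e_sorted == 1)).sum())
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            greenwood += d / (n_at_risk * (n_at_risk - d))
        risk.append(n_at_risk)
        surv.append(s)
        var.append(s * s * greenwood)
    return KMFit(
        event_times=distinct,
        survival=np.array(surv),
        variance=np.array(var),
        at_risk=np.array(risk, dtype=int),
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """K-group log-rank test; returns (chi2, df, p)."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    k = len(labels)
    gidx = np.searchsorted(labels, groups)
    event_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = int(((times == t) & (events == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(times == t) & (events == 1)], minlength=k).astype(float)
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            cov += v
    diff = (observed - expected)[: k - 1]
    vmat = cov[: k - 1, : k - 1]
    chi2 = float(diff @ np.linalg.pinv(vmat) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def logrank_z(times, events, mask) -> float:
    """Standardized two-group log-rank statistic (O-E)/sqrt(V) for the
    group flagged by ``mask``.  Used by cutpoint scanning."""
    times, events = _check_surv(times, events)
    mask = np.asarray(mask, dtype=bool)
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n1 = (at_risk & mask).sum()
        d1 = ((times == t) & (events == 1) & mask).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e / math.sqrt(var))


def logrank_z_scan(times, events, values, cutpoints) -> np.ndarray:
    """Standardized two-group log-rank statistic for every candidate cut.

    For each cut c the "high" group is ``values > c``.  Vectorized over
    cuts; algebraically identical to calling :func:`logrank_z` per cut.
    """
    times, events = _check_surv(times, events)
    values = np.asarray(values, dtype=float)
    cutpoints = np.atleast_1d(np.asarray(cutpoints, dtype=float))
    order = np.argsort(-times, kind="stable")
    t_o = times[order]
    e_o = events[order]
    v_o = values[order]
    risk_end = _tie_closure(t_o)
    ev = np.flatnonzero(e_o == 1)
    if ev.size == 0:
        return np.zeros(cutpoints.size)
    runs = np.unique(risk_end[ev])  # last row of each event tie run
    n_k = runs + 1.0  # at-risk counts
    cum_ev = np.cumsum(e_o)
    d_k = np.diff(np.concatenate([[0.0], cum_ev[runs]]))  # events per run

    high = v_o[None, :] > cutpoints[:, None]  # cuts x samples
    n1 = np.cumsum(high, axis=1)[:, runs].astype(float)  # at-risk in high
    e1_cum = np.cumsum(high & (e_o == 1)[None, :], axis=1)[:, runs].astype(float)
    d1 = np.diff(np.concatenate([np.zeros((len(cutpoints), 1)), e1_cum], axis=1), axis=1)

    frac = n1 / n_k[None, :]
    o_minus_e = (d1 - d_k[None, :] * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = np.where(
            n_k[None, :] > 1,
            d_k[None, :] * frac * (1 - frac) * (n_k - d_k)[None, :] / np.maximum(n_k - 1, 1)[None, :],
            0.0,
        )
    var = var_terms.sum(axis=1)
    z = np.zeros(len(cutpoints))
    ok = var > 0
    z[ok] = o_minus_e[ok] / np.sqrt(var[ok])
    return z


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    ll_path: list[float] = field(default_factory=list)

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            },
            index=self.names,
        )


def _tie_closure(times: np.ndarray) -> np.ndarray:
    """For rows sorted by descending time, the last index of each tie run
    (Breslow: tied event times share the full risk set)."""
    n = times.size
    boundaries = np.flatnonzero(np.diff(times) != 0)
    last = np.empty(n, dtype=int)
    start = 0
    for b in boundaries:
        last[start : b + 1] = b
        start = b + 1
    last[start:] = n - 1
    return last


def _cox_ll_grad_hess(beta, x, events, ev, risk_end):
    """Breslow partial log-likelihood with gradient and Hessian.

    Rows are sorted by descending time; ``ev`` indexes event rows and
    ``risk_end[i]`` is the last row of row i's risk set (tie closure).
    """
    n, p = x.shape
    eta = np.clip(x @ beta, -700, 700)
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)
    r = risk_end[ev]
    ll = float(eta[ev].sum() - np.log(s0[r]).sum())
    mu = s1[r] / s0[r][:, None]  # events x p
    grad = x[ev].sum(axis=0) - mu.sum(axis=0)
    hess = -(s2[r] / s0[r][:, None, None]).sum(axis=0) + mu.T @ mu
    return ll, grad, hess


def cox_fit(
    covariates,
    times,
    events,
    names: list[str] | None = None,
    ties: str = "breslow",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson with step-halving.

    The log partial likelihood is guaranteed non-decreasing across
    iterations; a decrease (or failure to converge) raises.
    """
    if ties != "breslow":
        raise NotImplementedError("only Breslow tie handling is implemented")
    times, events = _check_surv(times, events)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if n != times.size:
        raise ValueError("covariate rows must match number of samples")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    const = np.ptp(x, axis=0) == 0
    if const.any():
        bad = [names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant covariate(s): {bad}")
    if events.sum() < p + 1:
        raise ValueError("too few events for the number of covariates")

    # center/scale for conditioning; back-transform at the end
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    xs = (x - mu) / sd
    order = np.argsort(-times, kind="stable")
    xs_o = xs[order]
    t_o = times[order]
    e_o = events[order]
    risk_end = _tie_closure(t_o)
    ev = np.flatnonzero(e_o == 1)

    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(beta, xs_o, e_o, ev, risk_end)
    ll_path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix: {exc}") from exc
        # step-halving to enforce monotone log-likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _cox_ll_grad_hess(cand, xs_o, e_o, ev, risk_end)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ValueError("cox_fit step-halving failed to increase likelihood")
        beta, grad, hess = cand, grad_new, hess_new
        if ll_new < ll - 1e-10:
            raise AssertionError("log partial likelihood decreased")
        delta = ll_new - ll
        ll = ll_new
        ll_path.append(ll)
        if abs(delta) < tol and np.linalg.norm(grad) < 1e-6:
            converged = True
            break
    if not converged:
        raise ValueError("cox_fit did not converge (possible monotone likelihood)")
    # beta is on the standardized-covariate scale here; a per-SD log hazard
    # ratio beyond ~15 only arises under (near-)monotone likelihood
    if np.abs(beta).max() > 15:
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ValueError(f"diverging coefficient for {worst!r}: possible perfect separation")

    info = -hess
    cov_s = np.linalg.inv(info)
    beta_raw = beta / sd
    se_raw = np.sqrt(np.diag(cov_s)) / sd
    z = beta_raw / se_raw
    pvals = 2 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    return CoxFit(
        names=list(names),
        beta=beta_raw,
        se=se_raw,
        hr=np.exp(beta_raw),
        ci_lower=np.exp(beta_raw - zcrit * se_raw),
        ci_upper=np.exp(beta_raw + zcrit * se_raw),
        p=pvals,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        ll_path=ll_path,
    )


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------


def td_roc_auc(marker, times, events, horizon: float) -> float:
    """Cumulative-case / dynamic-control AUC at ``horizon`` with IPCW.

    Cases: events by the horizon.  Controls: subjects still event-free
    past the horizon.  Case weights are 1/G(T-) where G is the
    Kaplan-Meier estimate of the censoring distribution; marker ties
    count 0.5.  Without censoring this reduces to the Mann-Whitney
    statistic between cases and controls.
    """
    times, events = _check_surv(times, events)
    marker = np.asarray(marker, dtype=float)
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    if cases.sum() == 0:
        raise ValueError("no events by the horizon")
    if controls.sum() == 0:
        raise ValueError("no subjects event-free past the horizon")
    cens_km = km_fit(times, 1 - events)
    # G evaluated just before each case's event time
    g = np.array([cens_km.survival_at(np.nextafter(t, -np.inf)) for t in times[cases]])
    g = np.clip(g, 1e-12, None)
    w = 1.0 / g
    m_case = marker[cases]
    m_ctrl = marker[controls]
    # pairwise comparison, vectorized
    gt = (m_case[:, None] > m_ctrl[None, :]).sum(axis=1)
    eq = (m_case[:, None] == m_ctrl[None, :]).sum(axis=1)
    num = float((w * (gt + 0.5 * eq)).sum())
    den = float(w.sum() * len(m_ctrl))
    return num / den


# ---------------------------------------------------------------------------
# group comparison and correlation
# ---------------------------------------------------------------------------


def compare_groups(values, labels, test: str = "auto") -> tuple[float, float]:
    """Location comparison across groups; returns (statistic, two-sided p).

    Two groups: Wilcoxon rank-sum (exact for combined n <= 20 without
    ties) or Welch t when ``test='parametric'``.  More than two groups:
    Kruskal-Wallis, or one-way ANOVA when parametric.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    parametric = test in ("parametric", "t", "anova")
    if len(uniq) == 2:
        a, b = samples
        if parametric:
            res = stats.ttest_ind(a, b, equal_var=False)
            return float(res.statistic), float(res.pvalue)
        n = len(a) + len(b)
        no_ties = len(np.unique(values)) == n
        method = "exact" if (n <= 20 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if parametric:
        res = stats.f_oneway(*samples)
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def spearman_assoc(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with a permutation-exact p for n <= 8.

    rho is the Pearson correlation of average ranks; for larger n the
    p-value uses the t approximation with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= target:
                count += 1
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)
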