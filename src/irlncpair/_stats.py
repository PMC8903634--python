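"""Small shared statistical primitives used by several modules.

These are internal numerical helpers: a vectorized product-limit evaluator,
the Breslow partial log-likelihood (used for cross-validated deviance and as
an independent oracle in the test suite), and the Wilcoxon rank-sum p-value
with the exact/asymptotic path selection used throughout the package.
"""
from __future__ import annotations

import numpy as np
from scipy import stats


def km_survival_curve(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate: unique event times and S(t) just after each.

    Censored observations reduce the risk set without a survival step.
    Returns ``(event_times, survival)`` with survival evaluated at each unique
    event time (right-continuous step function; S before the first event is 1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    # number at risk just before each unique time
    uniq, first_idx = np.unique(t, return_index=True)
    at_risk = n - first_idx
    d = np.array([e[t == u].sum() for u in uniq])
    keep = d > 0
    ev_times = uniq[keep]
    surv = np.cumprod(1.0 - d[keep] / at_risk[keep])
    return ev_times, surv


def km_survival_at(time: np.ndarray, event: np.ndarray, t0: float) -> float:
    """S(t0) from the product-limit estimator (1.0 before the first event)."""
    ev_times, surv = km_survival_curve(time, event)
    idx = np.searchsorted(ev_times, t0, side="right") - 1
    return 1.0 if idx < 0 else float(surv[idx])


def breslow_partial_loglik(
    lp: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Cox partial log-likelihood with Breslow handling of tied event times.

    ``lp`` is the per-subject linear predictor x'beta.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")  # descending time
    lp_s, t_s, e_s = lp[order], time[order], event[order]
    # running log-sum-exp of risk sets from the largest time downwards
    m = lp.max()
    cum = np.cumsum(np.exp(lp_s - m))
    ll = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # risk set at this time = subjects with time >= t_s[i] = first j entries
        d_idx = [k for k in range(i, j) if e_s[k] == 1]
        if d_idx:
            log_denominator = m + np.log(cum[j - 1])
            ll += lp_s[d_idx].sum() - len(d_idx) * log_denominator
        i = j
    return float(ll)


def ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic U and p-value.

    Exact enumeration when both samples have n <= 12 and the pooled data are
    tie-free; otherwise the normal approximation with tie and continuity
    correction.  Degenerate case (all pooled values identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (x.size <= 12 and y.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
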