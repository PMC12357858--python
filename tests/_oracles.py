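"""Independent reference implementations used only by the test suite.

Each oracle is written from the textbook definition with plain Python
loops, deliberately sharing no code with the package implementations it
checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special


def welch_p_value(a, b) -> float:
    """Two-sided Welch t-test p-value from the written-out formulas."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    # two-sided p from the Student-t CDF (regularized incomplete beta)
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


def logrank_chi2_p(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Mantel-Haenszel log-rank by explicit risk-table enumeration."""
    rows = [(float(t), int(e), 0) for t, e in zip(times_a, events_a)]
    rows += [(float(t), int(e), 1) for t, e in zip(times_b, events_b)]
    event_times = sorted({t for t, e, _ in rows if e == 1})
    o_minus_e = 0.0
    variance = 0.0
    for et in event_times:
        at_risk = [(t, e, g) for t, e, g in rows if t >= et]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for t, e, _ in at_risk if t == et and e == 1)
        d_a = sum(1 for t, e, g in at_risk if t == et and e == 1 and g == 0)
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / variance
    p = float(special.chdtrc(1, chi2))
    return float(chi2), p


def breslow_partial_loglik(beta: float, group, times, events) -> float:
    """Written-out Breslow partial log-likelihood for one binary covariate."""
    rows = list(zip([float(t) for t in times],
                    [int(e) for e in events],
                    [int(g) for g in group]))
    ll = 0.0
    for et in sorted({t for t, e, _ in rows if e == 1}):
        deaths = [(t, e, g) for t, e, g in rows if t == et and e == 1]
        risk = [math.exp(beta * g) for t, e, g in rows if t >= et]
        for _, _, g in deaths:
            ll += beta * g
        ll -= len(deaths) * math.log(sum(risk))
    return ll


def grid_search_beta(group, times, events,
                     lo: float = -10.0, hi: float = 10.0) -> float:
    """Maximize the Breslow partial likelihood by iterated grid refinement."""
    for _ in range(12):
        grid = np.linspace(lo, hi, 201)
        ll = [breslow_partial_loglik(b, group, times, events) for b in grid]
        k = int(np.argmax(ll))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
    return float((lo + hi) / 2)


def brute_force_cutoff(expression, times, events, q_lo, q_hi, min_group,
                       logrank_fn) -> tuple[float, float]:
    """Exhaustive best-cutoff search over every admissible split.

    ``logrank_fn(times_a, events_a, times_b, events_b) -> (chi2, p)`` is
    injected so the oracle can exercise either the package log-rank or
    this module's own.
    """
    expr = np.asarray(expression, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    ok = np.isfinite(expr)
    expr, t, e = expr[ok], t[ok], e[ok]
    lo, hi = np.quantile(expr, [q_lo, q_hi])
    best = None
    for cutoff in sorted(set(expr.tolist())):
        if not (lo <= cutoff <= hi):
            continue
        high = expr > cutoff
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        _, p = logrank_fn(t[high], e[high], t[~high], e[~high])
        if best is None or p < best[1]:
            best = (float(cutoff), p)
    return best


def mean_rank_order(rank_vectors: list[dict[str, float]]) -> list[str]:
    """Borda-style consensus: sort proteins by their mean rank."""
    proteins = set(rank_vectors[0])
    for rv in rank_vectors[1:]:
        proteins &= set(rv)
    means = {p: sum(rv[p] for rv in rank_vectors) / len(rank_vectors)
             for p in proteins}
    return sorted(proteins, key=lambda p: (means[p], p))
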