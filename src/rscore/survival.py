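"""Clinical-association component: KM curves, log-rank, Cox HR, cutoff scan.

For each candidate protein the cohort is dichotomized at the expression
cutoff that minimizes the two-group log-rank (Cox-Mantel) p-value, the
"best cutoff" convention of common survival-plotting services.  The scan
considers every distinct observed expression value inside configurable
quantile bounds whose split leaves both groups at least ``min_group``
patients; "high" means strictly greater than the cutoff.  The selected
split is then summarized by the log-rank p-value and the Cox
proportional-hazards ratio (high vs low) from a single-binary-covariate
partial-likelihood fit with Breslow tie handling.

The scan performs no multiplicity correction, so its p-values are
optimistically biased (anti-conservative); they are used as ranking
statistics, not as calibrated significance tests.  Null calibration is
asserted in the test suite for a fixed median split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ComponentScore, SurvivalCohort
from .errors import NoValidCutoff, ValidationError

logger = logging.getLogger(__name__)

_BETA_BOUND = 20.0  # |ln HR| beyond this is treated as non-estimable


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimates at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (S = 1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class AssociationResult:
    """Best-cutoff survival association for one protein in one cohort."""

    protein: str
    cohort_id: str
    cutoff: float
    p_logrank: float
    hazard_ratio: float  # NaN when the Cox fit is non-estimable
    n_high: int
    n_low: int

    @property
    def direction_consistent(self) -> bool:
        """True iff high expression is adverse (HR > 1)."""
        return bool(np.isfinite(self.hazard_ratio) and self.hazard_ratio > 1.0)


@dataclass(frozen=True)
class ScanConfig:
    """Cutoff-scan settings: quantile bounds and minimum group size.

    ``min_group=None`` resolves to max(5, 10% of the cohort) at run time.
    """

    q_lo: float = 0.10
    q_hi: float = 0.90
    min_group: int | None = None

    def resolve_min_group(self, n: int) -> int:
        if self.min_group is not None:
            return self.min_group
        return max(5, int(np.ceil(0.10 * n)))


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if (t <= 0).any():
        raise ValidationError("all survival times must be > 0")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValidationError("event indicators must be 0 or 1")
    return t, e


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored observations reduce the risk sets only.  With no events the
    curve is identically 1.
    """
    from lifelines import KaplanMeierFitter

    t, e = _as_arrays(times, events)
    if e.sum() == 0:
        return KMCurve(times=np.array([]), survival=np.array([]), at_risk=np.array([]))
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=np.int64)
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def _logrank_sorted(t: np.ndarray, e: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Mantel-Haenszel statistic on time-sorted arrays; g marks group A.

    Uses exact hypergeometric moments per distinct event time.
    """
    n = t.size
    ut_idx = np.flatnonzero(np.diff(t, prepend=np.nan) != 0)
    d = np.add.reduceat(e, ut_idx)  # events at each distinct time
    d1 = np.add.reduceat(e * g, ut_idx)  # events in group A
    at_risk = n - ut_idx
    cg = np.concatenate(([0.0], np.cumsum(g)))
    n1 = g.sum() - cg[ut_idx]  # group-A members at risk

    has_event = d > 0
    d, d1, nr, n1 = d[has_event], d1[has_event], at_risk[has_event], n1[has_event]
    expected = d * n1 / nr
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / nr) * (1 - n1 / nr) * (nr - d) / (nr - 1)
    var = np.where(nr > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = float((d1.sum() - expected.sum()) ** 2 / v)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, max(p, np.finfo(float).tiny)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group Cox-Mantel (log-rank) test.

    Returns (chi2, p) with p from the chi-square distribution with 1 df.
    With zero events overall the test is vacuous: (0, 1) is returned and
    logged.
    """
    ta, ea = _as_arrays(times_a, events_a)
    tb, eb = _as_arrays(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        logger.info("log-rank: zero events overall, returning chi2=0, p=1")
        return 0.0, 1.0
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.ones_like(ta), np.zeros_like(tb)])
    order = np.argsort(t, kind="stable")
    return _logrank_sorted(t[order], e[order], g[order])


def _cox_aggregates(t, e, z):
    """Per-distinct-event-time risk-set aggregates for the binary Cox fit."""
    order = np.argsort(t, kind="stable")
    t, e, z = t[order], e[order], z[order]
    n = t.size
    ut_idx = np.flatnonzero(np.diff(t, prepend=np.nan) != 0)
    d = np.add.reduceat(e, ut_idx)
    s = np.add.reduceat(e * z, ut_idx)  # events among z=1
    at_risk = n - ut_idx
    cz = np.concatenate(([0.0], np.cumsum(z)))
    n1 = z.sum() - cz[ut_idx]
    n0 = at_risk - n1
    keep = d > 0
    return d[keep], s[keep], n0[keep], n1[keep]


def cox_hazard_ratio(group_high, times, events) -> float:
    """Hazard ratio exp(beta) for a single binary covariate (Breslow ties).

    ``beta`` maximizes the Breslow partial likelihood via safeguarded
    Newton iteration (tolerance 1e-8 on beta).  Monotone likelihoods —
    for example when one group's events all precede the other group's
    first event — have no finite maximizer; NaN is returned and the
    caller flags the protein non-estimable.  The same applies when either
    group has no events.
    """
    t, e = _as_arrays(times, events)
    z = np.asarray(group_high, dtype=float)
    if not np.isin(z, (0.0, 1.0)).all():
        raise ValidationError("group_high must be 0/1")
    if e[z == 1].sum() == 0 or e[z == 0].sum() == 0:
        return float("nan")
    d, s, n0, n1 = _cox_aggregates(t, e, z)

    def score_info(beta: float) -> tuple[float, float]:
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        u = float((s - d * n1 * eb / denom).sum())
        info = float((d * n0 * n1 * eb / denom**2).sum())
        return u, info

    beta = 0.0
    for _ in range(200):
        u, info = score_info(beta)
        if info <= 0:
            return float("nan")
        step = u / info
        step = float(np.clip(step, -2.0, 2.0))  # safeguard large Newton steps
        beta += step
        if abs(beta) > _BETA_BOUND:
            return float("nan")
        if abs(step) < 1e-8:
            return float(np.exp(beta))
    return float("nan")


def best_cutoff_scan(
    expression,
    times,
    events,
    q_lo: float = 0.10,
    q_hi: float = 0.90,
    min_group: int | None = None,
    protein: str = "",
    cohort_id: str = "",
) -> AssociationResult:
    """Find the expression cutoff minimizing the log-rank p-value.

    Candidate cutoffs are the distinct observed expression values inside
    the [q_lo, q_hi] expression quantiles whose split (high = strictly
    greater than the cutoff) leaves both groups >= min_group patients.
    Ties on p break toward the smaller cutoff.  Patients with missing
    expression are excluded before scanning.
    """
    expr = np.asarray(expression, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    present = np.isfinite(expr)
    expr, t, e = expr[present], t[present], e[present]
    n = expr.size
    if np.unique(expr).size < 2:
        raise NoValidCutoff(f"{protein}: constant or empty expression")
    mg = ScanConfig(q_lo, q_hi, min_group).resolve_min_group(n)

    lo, hi = np.quantile(expr, [q_lo, q_hi])
    values = np.unique(expr)
    candidates = values[(values >= lo) & (values <= hi)]

    order = np.argsort(t, kind="stable")
    t_s, e_s, expr_s = t[order], e[order], expr[order]

    best: tuple[float, float, int] | None = None  # (p, cutoff, n_high)
    for cutoff in candidates:  # ascending, so strict < keeps the smaller cutoff
        high = expr_s > cutoff
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < mg or n_low < mg:
            continue
        _, p = _logrank_sorted(t_s, e_s, high.astype(float))
        if best is None or p < best[0]:
            best = (p, float(cutoff), n_high)
    if best is None:
        raise NoValidCutoff(
            f"{protein}: no admissible cutoff (min_group={mg}, bounds=[{lo}, {hi}])"
        )
    p, cutoff, n_high = best
    hr = cox_hazard_ratio((expr > cutoff).astype(float), t, e)
    return AssociationResult(
        protein=protein,
        cohort_id=cohort_id,
        cutoff=cutoff,
        p_logrank=p,
        hazard_ratio=hr,
        n_high=n_high,
        n_low=n - n_high,
    )


def cohort_association(
    cohort: SurvivalCohort,
    proteins: list[str] | None = None,
    scan: ScanConfig | None = None,
) -> tuple[list[ComponentScore], list[AssociationResult]]:
    """Best-cutoff association for every protein in a cohort.

    Proteins whose best split has HR <= 1 cannot show the adverse
    (oncogenic) direction; they stay in the results table but receive
    worst-possible metric values (p = 1, HR component value 0) so rank
    vectors stay complete.  Non-estimable proteins (constant expression,
    no admissible cutoff, monotone Cox likelihood) are excluded and
    logged.
    """
    if scan is None:
        scan = ScanConfig()
    if proteins is None:
        proteins = cohort.proteins
    times = cohort.data["time"].to_numpy(dtype=float)
    events = cohort.data["event"].to_numpy(dtype=float)

    results: list[AssociationResult] = []
    p_vals: dict[str, float] = {}
    hr_vals: dict[str, float] = {}
    for symbol in proteins:
        expr = cohort.data[symbol].to_numpy(dtype=float)
        if not np.isfinite(expr).any():
            logger.info("%s/%s: all expression missing, excluded", cohort.cohort_id, symbol)
            continue
        try:
            res = best_cutoff_scan(
                expr, times, events,
                q_lo=scan.q_lo, q_hi=scan.q_hi, min_group=scan.min_group,
                protein=symbol, cohort_id=cohort.cohort_id,
            )
        except NoValidCutoff as exc:
            logger.info("%s: %s", cohort.cohort_id, exc)
            continue
        if not np.isfinite(res.hazard_ratio):
            logger.info(
                "%s/%s: Cox HR non-estimable at best cutoff, excluded",
                cohort.cohort_id, symbol,
            )
            continue
        results.append(res)
        if res.direction_consistent:
            p_vals[symbol] = res.p_logrank
            hr_vals[symbol] = res.hazard_ratio
        else:  # rank-penalize to the bottom of both components
            p_vals[symbol] = 1.0
            hr_vals[symbol] = 0.0

    cid = cohort.cohort_id
    scores = [
        ComponentScore(f"p_logrank:{cid}", cid, "p_logrank", pd.Series(p_vals, dtype=float)),
        ComponentScore(f"hazard_ratio:{cid}", cid, "hazard_ratio", pd.Series(hr_vals, dtype=float)),
    ]
    return scores, results
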