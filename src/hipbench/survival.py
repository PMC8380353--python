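"""Net failure estimation by one minus Kaplan-Meier, with Greenwood errors.

Net failure F(t) = 1 - S(t), where S is the product-limit (Kaplan-Meier)
survival function with revision as the event and death / end of follow-up
as censoring.  This is the cumulative probability of revision in a
hypothetical world without death — the standard registry quantity for
comparing implant performance, distinct from the competing-risks
cumulative incidence.

Variance is Greenwood's estimator,

    Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (r_i (r_i - d_i)),

over distinct event times t_i with d_i events and r_i subjects at risk;
by symmetry SE[F(t)] = SE[S(t)].  Confidence intervals are plain Wald
intervals on the failure scale, clipped to [0, 1].

Ties between events and censorings at the same timestamp follow the
standard convention: events are processed first, i.e. a subject censored
at t is still in the risk set for events at t.  "At risk at t" means
follow-up time >= t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .registry import Construct, HipbenchError, TimeToEvent

__all__ = ["SurvivalEstimate", "KMCurve", "km_failure", "km_curve", "n_at_risk"]


class SurvivalInputError(HipbenchError, ValueError):
    """Empty or invalid input to a survival estimator."""


@dataclass(frozen=True)
class SurvivalEstimate:
    """Net failure of one construct at a fixed horizon.

    Attributes
    ----------
    horizon_years:
        The time point t (years since primary operation).
    failure:
        F(t) = 1 - S(t), the cumulative probability of revision.
    se:
        Greenwood standard error of F(t); 0 when no events occurred by t.
    ci_low, ci_high:
        95% (or ``confidence``) Wald bounds on F(t), clipped to [0, 1].
    n_at_risk:
        Number of subjects with follow-up time >= t.
    n, n_events:
        Total subjects and number of events observed by t.
    beyond_follow_up:
        True when t exceeds the last observed time; the estimate is then
        the value at the last event time, carried forward.
    """

    horizon_years: float
    failure: float
    se: float
    ci_low: float
    ci_high: float
    n_at_risk: int
    n: int
    n_events: int
    construct: Optional[Construct] = None
    beyond_follow_up: bool = False


@dataclass(frozen=True)
class KMCurve:
    """Stepwise Kaplan-Meier curve: right-continuous, S(0) = 1.

    ``event_times`` are the distinct times with at least one event;
    ``survival[i]`` is S(event_times[i]); ``at_risk[i]`` and ``events[i]``
    are r_i and d_i.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) by step-function lookup (1.0 before the first event)."""
        idx = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_arrays(times_events: Iterable[TimeToEvent]) -> Tuple[np.ndarray, np.ndarray]:
    pairs = [(te.time_years, te.event) for te in times_events]
    if not pairs:
        return np.empty(0), np.empty(0, dtype=bool)
    times, events = zip(*pairs)
    return np.asarray(times, dtype=float), np.asarray(events, dtype=bool)


def _km_steps(times: np.ndarray, events: np.ndarray):
    """Distinct event times with (d_i, r_i, S, cumulative Greenwood sum)."""
    order = np.argsort(times, kind="mergesort")
    ts = times[order]
    es = events[order]
    n = ts.size
    evt, d = np.unique(ts[es], return_counts=True)
    r = n - np.searchsorted(ts, evt, side="left")
    frac = d / r
    surv = np.cumprod(1.0 - frac)
    # Greenwood terms; where r == d the curve hits 0 and the variance is
    # taken as 0 from that point on (degenerate estimate).
    safe = r > d
    terms = np.zeros_like(frac)
    terms[safe] = d[safe] / (r[safe] * (r[safe] - d[safe]).astype(float))
    gw = np.cumsum(terms)
    return evt, d, r, surv, gw


def km_failure_from_arrays(
    times: np.ndarray,
    events: np.ndarray,
    horizon: float,
    confidence: float = 0.95,
    construct: Optional[Construct] = None,
) -> SurvivalEstimate:
    """Array fast path behind :func:`km_failure` (same contract)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise SurvivalInputError("km_failure requires at least one subject")
    if horizon <= 0:
        raise SurvivalInputError(f"horizon must be positive, got {horizon!r}")
    if np.any(times < 0):
        raise SurvivalInputError("negative follow-up time")

    evt, d, r, surv, gw = _km_steps(times, events)
    k = int(np.searchsorted(evt, horizon, side="right"))  # event times <= horizon
    if k == 0:
        s, var_sum, hit_zero = 1.0, 0.0, False
        n_events = 0
    else:
        s = float(surv[k - 1])
        var_sum = float(gw[k - 1])
        hit_zero = bool(np.any(r[:k] == d[:k]))
        n_events = int(d[:k].sum())
    if hit_zero:
        s, se = 0.0, 0.0
    else:
        se = s * math.sqrt(var_sum)
    failure = 1.0 - s
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    ci_low = max(0.0, failure - z * se)
    ci_high = min(1.0, failure + z * se)
    return SurvivalEstimate(
        horizon_years=float(horizon),
        failure=failure,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_at_risk=int(np.sum(times >= horizon)),
        n=int(times.size),
        n_events=n_events,
        construct=construct,
        beyond_follow_up=bool(horizon > times.max()),
    )


def km_failure(
    times_events: Iterable[TimeToEvent],
    horizon: float,
    confidence: float = 0.95,
    construct: Optional[Construct] = None,
) -> SurvivalEstimate:
    """Estimate net failure F(t) = 1 - S(t) at ``horizon`` years.

    When ``horizon`` lies beyond the last observed time the product limit
    is carried forward from the last event time, ``n_at_risk`` is 0 and
    ``beyond_follow_up`` is flagged.

    Raises
    ------
    SurvivalInputError
        On empty input or a non-positive horizon.
    """
    times, events = _as_arrays(times_events)
    return km_failure_from_arrays(times, events, horizon, confidence, construct)


def km_curve(times_events: Iterable[TimeToEvent]) -> KMCurve:
    """Full product-limit curve (event times, S, risk sets, event counts)."""
    times, events = _as_arrays(times_events)
    if times.size == 0:
        raise SurvivalInputError("km_curve requires at least one subject")
    evt, d, r, surv, _ = _km_steps(times, events)
    return KMCurve(event_times=evt, survival=surv, at_risk=r, events=d)


def n_at_risk(times_events: Iterable[TimeToEvent], horizon: float) -> int:
    """Number of subjects neither failed nor censored before ``horizon``.

    Boundary convention: a subject with time exactly equal to the horizon
    counts as at risk (time >= t).
    """
    if horizon <= 0:
        raise SurvivalInputError(f"horizon must be positive, got {horizon!r}")
    times, _ = _as_arrays(times_events)
    return int(np.sum(times >= horizon))
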