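"""Reconstruct pseudo individual-patient data from digitized Kaplan-Meier
coordinates.

Published trials rarely release patient-level survival data; what is
available is the KM figure. After the figure is digitized into
(time, survival) coordinates, the product-limit relation

    S(t_j) = S(t_{j-1}) * (1 - d_j / n_j)

can be inverted interval by interval to recover integer event counts d_j
given the number at risk n_j. With a published number-at-risk table the
allocation follows the standard Guyot-style balance (censorings per interval
= at-risk drop minus events); without one, censoring during follow-up cannot
be identified from the curve alone, so all survivors are administratively
censored at the last digitized time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .survival_models import PseudoIPD

__all__ = [
    "DigitizedCurve",
    "CurveValidationError",
    "IntervalAllocation",
    "interval_event_allocation",
    "reconstruct_ipd",
    "read_curve_csv",
    "write_curve_csv",
]

log = logging.getLogger(__name__)


class CurveValidationError(ValueError):
    """A digitized curve violates a Kaplan-Meier invariant."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized KM coordinates for one arm and endpoint.

    ``points`` is a sequence of (time_months, survival) pairs with strictly
    increasing times and non-increasing survival in [0, 1]. The first point
    must sit at time <= 0.5 months with survival >= 0.98 — a curve that does
    not start at (about) (0, 1) was mis-digitized. ``at_risk`` optionally
    carries the published number-at-risk table as (time, count) pairs.
    """

    arm: str
    endpoint: str
    points: tuple[tuple[float, float], ...]
    at_risk: tuple[tuple[float, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.endpoint not in ("OS", "PFS"):
            raise CurveValidationError(f"endpoint must be 'OS' or 'PFS', got {self.endpoint!r}")
        pts = tuple((float(t), float(s)) for t, s in self.points)
        if len(pts) < 2:
            raise CurveValidationError("a digitized curve needs at least two points")
        t0, s0 = pts[0]
        if t0 > 0.5 or not (0.98 <= s0 <= 1.0):
            raise CurveValidationError(
                f"first point (t={t0:g}, S={s0:g}) must have t<=0.5 and S in [0.98, 1]; "
                "the curve appears mis-digitized")
        for i in range(1, len(pts)):
            if pts[i][0] <= pts[i - 1][0]:
                raise CurveValidationError(
                    f"times must be strictly increasing; point {i} at t={pts[i][0]:g} "
                    f"does not exceed t={pts[i - 1][0]:g}")
            if pts[i][1] > pts[i - 1][1] + 1e-12:
                raise CurveValidationError(
                    f"survival must be non-increasing; point {i} rises from "
                    f"{pts[i - 1][1]:g} to {pts[i][1]:g}")
            if not (0.0 <= pts[i][1] <= 1.0):
                raise CurveValidationError(f"survival at point {i} outside [0, 1]")
        object.__setattr__(self, "points", pts)
        if self.at_risk is not None:
            ar = tuple((float(t), int(n)) for t, n in self.at_risk)
            if any(ar[i][0] <= ar[i - 1][0] for i in range(1, len(ar))):
                raise CurveValidationError("at-risk times must be strictly increasing")
            if any(ar[i][1] > ar[i - 1][1] for i in range(1, len(ar))):
                raise CurveValidationError("at-risk counts must be non-increasing")
            object.__setattr__(self, "at_risk", ar)

    @property
    def times(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def survivals(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survivals})


@dataclass(frozen=True)
class IntervalAllocation:
    """Integer events/censorings assigned to one inter-point interval."""

    t_start: float
    t_end: float
    n_at_risk: int       # at risk entering the interval
    events: int
    censorings: int


def _allocation_no_at_risk(times, survs, total_n) -> list[IntervalAllocation]:
    """Greedy inversion of the product-limit relation, no censoring during
    follow-up; everyone still at risk is censored at the final time point."""
    n_cur = total_n
    s_km = 1.0
    out: list[IntervalAllocation] = []
    t_prev = 0.0
    for i, (t, s) in enumerate(zip(times, survs)):
        if s < s_km - 1e-12 and n_cur == 0:
            raise CurveValidationError(
                f"interval {i}: survival drops to {s:g} but nobody remains at risk")
        d = 0
        if n_cur > 0 and s_km > 0:
            d = int(round(n_cur * (1.0 - s / s_km)))
            d = min(max(d, 0), n_cur)
            s_km *= 1.0 - d / n_cur
        cens = 0
        if i == len(times) - 1:
            cens = n_cur - d
        out.append(IntervalAllocation(t_prev, t, n_cur, d, cens))
        n_cur -= d + cens
        t_prev = t
    return out


def _allocation_with_at_risk(curve: DigitizedCurve, total_n: int) -> list[IntervalAllocation]:
    """Two-pass Guyot-style allocation honouring the number-at-risk table.

    Pass 1 estimates events ignoring in-interval censoring; the at-risk
    balance then fixes censorings per at-risk interval, which pass 2 spreads
    evenly over the digitized sub-intervals while recomputing events.
    """
    times, survs = curve.times, curve.survivals
    if times[0] == 0.0:  # the (0, 1) anchor spans no interval
        times, survs = times[1:], survs[1:]
    ar_times = [t for t, _ in curve.at_risk]
    ar_counts = [n for _, n in curve.at_risk]
    if ar_counts[0] != total_n:
        raise CurveValidationError(
            f"at-risk table starts at {ar_counts[0]} but total_n={total_n}")
    # map each digitized point to its at-risk interval k: ar_times[k] < t <= ar_times[k+1]
    n_int = len(ar_times)
    point_interval = np.searchsorted(np.array(ar_times), times, side="left") - 1
    point_interval = np.clip(point_interval, 0, n_int - 1)

    def run_pass(cens_per_interval: list[int]) -> tuple[list[IntervalAllocation], list[int]]:
        n_cur = total_n
        s_km = 1.0
        t_prev = 0.0
        allocs: list[IntervalAllocation] = []
        events_per_interval = [0] * n_int
        used_cens = [0] * n_int
        for i, (t, s) in enumerate(zip(times, survs)):
            k = int(point_interval[i])
            d = 0
            if n_cur > 0 and s_km > 0:
                d = int(round(n_cur * (1.0 - s / s_km)))
                d = min(max(d, 0), n_cur)
                s_km *= 1.0 - d / n_cur
            # share of this at-risk interval's censorings for this sub-interval
            n_sub = int(np.sum(point_interval == k))
            j_sub = int(np.sum(point_interval[: i + 1] == k))  # 1-based position
            target_c = int(round(cens_per_interval[k] * j_sub / n_sub))
            c = min(max(target_c - used_cens[k], 0), n_cur - d)
            is_last = i == len(times) - 1
            if is_last:
                c = n_cur - d
            allocs.append(IntervalAllocation(t_prev, t, n_cur, d, c))
            events_per_interval[k] += d
            used_cens[k] += c
            n_cur -= d + c
            t_prev = t
        return allocs, events_per_interval

    # pass 1: no in-interval censoring
    allocs, ev_per_int = run_pass([0] * n_int)
    cens = []
    for k in range(n_int):
        nxt = ar_counts[k + 1] if k + 1 < n_int else 0
        c = ar_counts[k] - nxt - ev_per_int[k]
        if c < -max(2, int(0.02 * total_n)):
            raise CurveValidationError(
                f"infeasible allocation in at-risk interval {k}: events "
                f"({ev_per_int[k]}) exceed the at-risk drop ({ar_counts[k]}-{nxt})")
        cens.append(max(c, 0))
    # pass 2: spread those censorings within intervals, recompute events
    allocs, _ = run_pass(cens)
    return allocs


def interval_event_allocation(
    curve: DigitizedCurve, total_n: int
) -> list[IntervalAllocation]:
    """Allocate integer events and censorings to each inter-point interval.

    Conservation holds by construction: the allocated events plus censorings
    sum to ``total_n`` and the running at-risk count never goes negative.
    """
    if total_n < 10:
        raise ValueError("total_n must be at least 10")
    if curve.at_risk is not None:
        return _allocation_with_at_risk(curve, total_n)
    times, survs = curve.times, curve.survivals
    if times[0] == 0.0:  # skip the anchor point; no interval precedes it
        times, survs = times[1:], survs[1:]
    return _allocation_no_at_risk(times, survs, total_n)


def reconstruct_ipd(
    curve: DigitizedCurve,
    total_n: int,
    event_placement: str = "midpoint",
) -> PseudoIPD:
    """Turn a digitized KM curve into ``total_n`` pseudo patient records.

    Events within an interval are placed at the interval midpoint by default
    (``event_placement='drop'`` puts them at the drop time instead, i.e. the
    interval's right edge); censorings are spread evenly over the interval,
    except administrative censoring at the final time point.

    The reconstruction is self-consistent: re-estimating the KM curve from
    the returned records reproduces the input survival values to within
    about half a patient's worth of probability mass at each time point.
    """
    if event_placement not in ("midpoint", "drop"):
        raise ValueError("event_placement must be 'midpoint' or 'drop'")
    allocs = interval_event_allocation(curve, total_n)
    t_last = allocs[-1].t_end
    times: list[float] = []
    events: list[int] = []
    for a in allocs:
        if a.events:
            te = a.t_end if event_placement == "drop" else 0.5 * (a.t_start + a.t_end)
            te = max(te, 1e-9)
            times.extend([te] * a.events)
            events.extend([1] * a.events)
        if a.censorings:
            if a.t_end >= t_last - 1e-12 and curve.at_risk is None:
                tc = [a.t_end] * a.censorings
            else:
                # evenly inside the interval, after the events
                tc = list(np.linspace(a.t_start, a.t_end, a.censorings + 2)[1:-1]) \
                    if a.censorings > 1 else [0.5 * (a.t_start + a.t_end)]
                if a.t_end >= t_last - 1e-12:
                    tc = [a.t_end] * a.censorings
            times.extend(max(t, 1e-9) for t in tc)
            events.extend([0] * a.censorings)
    ipd = PseudoIPD(np.array(times), np.array(events))
    assert len(ipd) == total_n, "record conservation violated"
    return ipd


# ---------------------------------------------------------------------------
# CSV dialects


def read_curve_csv(path, arm: str = "", endpoint: str = "OS",
                   at_risk_path=None) -> DigitizedCurve:
    """Read `time_months,survival` coordinates (optional `time_months,n_risk`
    sidecar for the number-at-risk table)."""
    df = pd.read_csv(path)
    pts = tuple(zip(df["time_months"].astype(float), df["survival"].astype(float)))
    at_risk = None
    if at_risk_path is not None:
        ar = pd.read_csv(at_risk_path)
        at_risk = tuple(zip(ar["time_months"].astype(float), ar["n_risk"].astype(int)))
    return DigitizedCurve(arm=arm, endpoint=endpoint, points=pts, at_risk=at_risk)


def write_curve_csv(curve: DigitizedCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)
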