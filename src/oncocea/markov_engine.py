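"""Three-state cohort simulation: progression-free (PFS), progressed disease
(PD), and death, over fixed-length cycles.

Two constructions are offered and cross-checked in the tests:

* ``markov`` (default): state memberships evolve by a per-cycle transition
  matrix. The per-cycle death probability comes from the overall-survival
  curve as the conditional event probability 1 - S(t)/S(t-u) over the cycle
  (t = cycle end, u = cycle width), the probability of leaving PFS likewise
  from the PFS curve; P(PFS->PD) is their difference, floored at zero. The
  same conditional death probability is applied from PFS and from PD, which
  is exactly what deriving transitions from marginal OS and PFS curves can
  identify.
* ``partitioned``: the partitioned-survival construction — PFS membership is
  S_PFS(t), the death compartment 1 - S_OS(t), and PD the difference. Where
  the curves cross (S_PFS > S_OS), PFS is clamped down to S_OS so that mass
  still sums to one; a warning is logged if the clamp fires on more than 5%
  of cycles.

When S_PFS <= S_OS everywhere on the cycle grid the two constructions
coincide (the Markov recursion telescopes to the partitioned formulas), so
disagreement between them is a direct diagnostic of curve-crossing.

Time is internally in months, with 1 month = 30.4375 days; cycle c is
evaluated at t_c = c * cycle_days / 30.4375 months.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival_models import ParametricSurvival

__all__ = [
    "DAYS_PER_MONTH",
    "ModelConfig",
    "CohortTrace",
    "conditional_event_prob",
    "transition_matrix",
    "build_trace",
]

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # 365.25 / 12


@dataclass(frozen=True)
class ModelConfig:
    """Global settings of the decision model.

    Defaults: 28-day cycles over a 10-year horizon (130 cycles), 5% annual
    discount rate, willingness-to-pay 268,200 CNY per QALY (three times 2023
    Chinese per-capita GDP), no half-cycle correction, Markov transitions.
    """

    cycle_days: float = 28.0
    horizon_years: float = 10.0
    annual_discount: float = 0.05
    wtp: float = 268_200.0
    half_cycle_correction: bool = False
    transition_mode: str = "markov"
    allow_extended_discount: bool = False

    def __post_init__(self) -> None:
        if not self.cycle_days > 0:
            raise ValueError("cycle_days must be positive")
        if not self.horizon_years > 0:
            raise ValueError("horizon_years must be positive")
        hi = 1.0 if self.allow_extended_discount else 0.08
        if not (0.0 <= self.annual_discount <= hi):
            raise ValueError(
                f"annual_discount must lie in [0, {hi:g}] "
                "(set allow_extended_discount to widen)")
        if self.transition_mode not in ("markov", "partitioned"):
            raise ValueError("transition_mode must be 'markov' or 'partitioned'")

    @property
    def n_cycles(self) -> int:
        return int(math.floor(self.horizon_years * 365.25 / self.cycle_days))

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    def cycle_times_months(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_months


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state-membership fractions.

    Row c gives the membership at the start of cycle c (t_c months);
    ``new_deaths[c]`` is the death mass that entered during cycle c-1
    (zero at c=0). Mass is conserved to 1e-10 every cycle.
    """

    t_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    new_deaths: np.ndarray

    def __post_init__(self) -> None:
        total = self.pfs + self.pd + self.dead
        if np.any(np.abs(total - 1.0) > 1e-10):
            worst = int(np.argmax(np.abs(total - 1.0)))
            raise ValueError(
                f"state masses at cycle {worst} sum to {total[worst]!r}, not 1")

    def __len__(self) -> int:
        return int(self.t_months.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(len(self)),
            "t_months": self.t_months,
            "pfs": self.pfs,
            "pd": self.pd,
            "dead": self.dead,
            "new_deaths": self.new_deaths,
        })


def conditional_event_prob(model: ParametricSurvival, t: float, u: float) -> float:
    """Probability the event occurs in (t-u, t] given event-free at t-u:
    1 - S(t)/S(t-u).

    If the curve is already exhausted (S(t-u)=0) the cohort there is gone;
    returns 1 with a logged warning.
    """
    if u <= 0:
        raise ValueError("cycle width u must be positive")
    if t < u:
        raise ValueError("t must be at least u")
    s_prev = float(model.survival(t - u))
    if s_prev <= 0.0:
        log.warning("conditional_event_prob: S(%.4g)=0, cohort exhausted; returning 1", t - u)
        return 1.0
    p = 1.0 - float(model.survival(t)) / s_prev
    return min(1.0, max(0.0, p))


def transition_matrix(
    c: int,
    config: ModelConfig,
    os_model: ParametricSurvival,
    pfs_model: ParametricSurvival,
) -> np.ndarray:
    """3x3 row-stochastic matrix for the transition into cycle c (c >= 1),
    states ordered (PFS, PD, dead). Death is absorbing. P(PFS->PD) is the
    excess of the PFS-exit probability over the death probability, floored
    at zero."""
    if c < 1:
        raise ValueError("transitions start at cycle 1")
    u = config.cycle_months
    t = c * u
    p_death = conditional_event_prob(os_model, t, u)
    p_exit = conditional_event_prob(pfs_model, t, u)
    p_pfs_pd = max(0.0, p_exit - p_death)
    m = np.array([
        [1.0 - p_pfs_pd - p_death, p_pfs_pd, p_death],
        [0.0, 1.0 - p_death, p_death],
        [0.0, 0.0, 1.0],
    ])
    if np.any(m < -1e-12) or np.any(m > 1.0 + 1e-12):
        raise RuntimeError(f"transition matrix entries outside [0,1] at cycle {c}: {m}")
    return np.clip(m, 0.0, 1.0)


def build_trace(
    config: ModelConfig,
    os_model: ParametricSurvival,
    pfs_model: ParametricSurvival,
) -> CohortTrace:
    """Simulate the cohort from everyone-in-PFS at cycle 0 to the horizon."""
    n = config.n_cycles
    ts = config.cycle_times_months()
    if config.transition_mode == "partitioned":
        s_os = os_model.survival(ts)
        s_pfs = pfs_model.survival(ts)
        clamped = s_pfs > s_os + 1e-15
        if clamped.sum() > 0.05 * n:
            log.warning(
                "partitioned trace: PFS curve exceeds OS curve on %d of %d cycles; "
                "PFS membership clamped to the OS curve", int(clamped.sum()), n)
        pfs = np.minimum(s_pfs, s_os)
        dead = 1.0 - s_os
        pd_ = 1.0 - pfs - dead
    else:
        pfs = np.empty(n)
        pd_ = np.empty(n)
        dead = np.empty(n)
        state = np.array([1.0, 0.0, 0.0])
        pfs[0], pd_[0], dead[0] = state
        for c in range(1, n):
            state = state @ transition_matrix(c, config, os_model, pfs_model)
            state = state / state.sum()  # remove 1-ulp drift
            pfs[c], pd_[c], dead[c] = state
    new_deaths = np.diff(dead, prepend=dead[0])
    new_deaths[0] = 0.0
    return CohortTrace(t_months=ts, pfs=pfs, pd=np.maximum(pd_, 0.0),
                       dead=dead, new_deaths=new_deaths)
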