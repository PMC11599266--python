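"""Discounted cost and QALY accrual over a cohort trace, incremental
cost-effectiveness comparison, and dose/body-surface-area arithmetic.

Costing conventions (all config-overridable):

* drug acquisition plus follow-up (laboratory + imaging) costs accrue each
  cycle spent progression-free — treatment runs until progression;
* subsequent-line therapy plus supportive care accrue each cycle spent in
  progressed disease;
* a one-time end-of-life cost is charged to the death mass entering each
  cycle, at that cycle's discount factor;
* adverse-event management is a one-time expected lump sum at model entry:
  sum over the arm's event list of incidence x unit cost (trials report
  per-patient incidences, not per-cycle rates).

QALYs per cycle are (pfs*u_pfs + pd*u_pd) * cycle_years. Discounting is
annual-rate, continuous in cycle time: (1+r)^(-cycle_days*c/365.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .markov_engine import CohortTrace, ModelConfig
from .survival_models import ParametricSurvival

__all__ = [
    "AdverseEvent",
    "StrategyInputs",
    "CostInputs",
    "Utilities",
    "StrategyOutcome",
    "CEAResult",
    "DecisionCase",
    "body_surface_area",
    "weighted_patient_profile",
    "discount_factor",
    "discount_factors",
    "accrue",
    "compare",
    "evaluate_case",
]


def body_surface_area(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) from the Chinese-population linear formula
    BSA = 0.0061*height + 0.0124*weight - 0.0099."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.0061 * height_cm + 0.0124 * weight_kg - 0.0099


def weighted_patient_profile(male_val: float, female_val: float,
                             n_male: int, n_female: int) -> float:
    """Sex-weighted average of a patient characteristic."""
    if n_male + n_female <= 0:
        raise ValueError("need at least one patient")
    return (male_val * n_male + female_val * n_female) / (n_male + n_female)


def discount_factor(cycle: int, config: ModelConfig) -> float:
    """(1+r)^(-t_years) at the start of the given cycle."""
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    t_years = cycle * config.cycle_days / 365.25
    return (1.0 + config.annual_discount) ** (-t_years)


def discount_factors(config: ModelConfig) -> np.ndarray:
    t_years = np.arange(config.n_cycles) * config.cycle_days / 365.25
    return (1.0 + config.annual_discount) ** (-t_years)


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    incidence: float
    unit_cost: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.incidence <= 1.0):
            raise ValueError(f"AE {self.name!r}: incidence must lie in [0, 1]")
        if self.unit_cost < 0:
            raise ValueError(f"AE {self.name!r}: unit cost must be non-negative")


@dataclass(frozen=True)
class StrategyInputs:
    """One treatment arm: acquisition cost, adverse-event profile, and the
    fitted OS and PFS extrapolations."""

    name: str
    key: str
    drug_cost_per_cycle: float
    adverse_events: tuple[AdverseEvent, ...]
    os_model: ParametricSurvival
    pfs_model: ParametricSurvival

    def __post_init__(self) -> None:
        if self.drug_cost_per_cycle < 0:
            raise ValueError("drug cost must be non-negative")
        object.__setattr__(self, "adverse_events", tuple(self.adverse_events))

    @property
    def ae_lump_sum(self) -> float:
        return sum(ae.incidence * ae.unit_cost for ae in self.adverse_events)


@dataclass(frozen=True)
class CostInputs:
    """Non-drug unit costs (CNY)."""

    lab_per_visit: float = 317.36
    imaging_per_visit: float = 677.70
    supportive_per_cycle: float = 2_141.20
    end_of_life_once: float = 11_299.00
    subsequent_tx_per_cycle: float = 7_541.10

    def __post_init__(self) -> None:
        for f in ("lab_per_visit", "imaging_per_visit", "supportive_per_cycle",
                  "end_of_life_once", "subsequent_tx_per_cycle"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass(frozen=True)
class Utilities:
    """Health-state utilities; death is anchored at zero."""

    u_pfs: float = 0.84
    u_pd: float = 0.57
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        if self.u_dead != 0.0:
            raise ValueError("the dead-state utility is fixed at 0")
        if not (0.0 <= self.u_pd <= self.u_pfs <= 1.0):
            raise ValueError(
                f"utilities must satisfy 0 <= u_pd ({self.u_pd}) <= "
                f"u_pfs ({self.u_pfs}) <= 1")


@dataclass(frozen=True)
class StrategyOutcome:
    name: str
    discounted_cost: float
    discounted_qalys: float


def _cycle_weights(trace: CohortTrace, config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """State-occupancy arrays used for accrual, optionally half-cycle
    corrected (mean of adjacent cycle-start memberships)."""
    pfs, pd_ = trace.pfs, trace.pd
    if config.half_cycle_correction:
        pfs = np.concatenate([0.5 * (pfs[:-1] + pfs[1:]), pfs[-1:]])
        pd_ = np.concatenate([0.5 * (pd_[:-1] + pd_[1:]), pd_[-1:]])
    return pfs, pd_


def accrue(
    trace: CohortTrace,
    strategy: StrategyInputs,
    costs: CostInputs,
    utilities: Utilities,
    config: ModelConfig,
) -> StrategyOutcome:
    """Discounted total cost and QALYs for one strategy over the trace."""
    if len(trace) != config.n_cycles:
        raise ValueError(
            f"trace has {len(trace)} cycles but the config implies {config.n_cycles}")
    df = discount_factors(config)
    pfs_w, pd_w = _cycle_weights(trace, config)
    pfs_cost = strategy.drug_cost_per_cycle + costs.lab_per_visit + costs.imaging_per_visit
    pd_cost = costs.subsequent_tx_per_cycle + costs.supportive_per_cycle
    cost_per_cycle = (
        pfs_w * pfs_cost + pd_w * pd_cost + trace.new_deaths * costs.end_of_life_once
    )
    total_cost = strategy.ae_lump_sum + float(np.sum(df * cost_per_cycle))
    qaly_per_cycle = (pfs_w * utilities.u_pfs + pd_w * utilities.u_pd) * config.cycle_years
    total_qalys = float(np.sum(df * qaly_per_cycle))
    return StrategyOutcome(strategy.name, total_cost, total_qalys)


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator.

    ``icer`` is None whenever a dominance flag applies (sign disagreement
    makes the ratio meaningless). ``nmb`` is the incremental net monetary
    benefit wtp*dQALY - dCost; for positive QALY gains, nmb >= 0 is
    equivalent to ICER <= WTP.
    """

    intervention: StrategyOutcome
    comparator: StrategyOutcome
    wtp: float
    incremental_cost: float = field(init=False)
    incremental_qalys: float = field(init=False)
    icer: float | None = field(init=False)
    dominance: str | None = field(init=False)
    nmb: float = field(init=False)
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        dc = self.intervention.discounted_cost - self.comparator.discounted_cost
        dq = self.intervention.discounted_qalys - self.comparator.discounted_qalys
        object.__setattr__(self, "incremental_cost", dc)
        object.__setattr__(self, "incremental_qalys", dq)
        nmb = self.wtp * dq - dc
        object.__setattr__(self, "nmb", nmb)
        icer: float | None = None
        dominance: str | None = None
        if dq == 0.0 and dc == 0.0:
            dominance = "equivalent"
        elif dq >= 0.0 and dc <= 0.0 and (dq > 0 or dc < 0):
            dominance = "dominant"       # cheaper and at least as effective
        elif dq <= 0.0 and dc >= 0.0 and (dq < 0 or dc > 0):
            dominance = "dominated"      # costlier and at most as effective
        else:
            icer = dc / dq
        object.__setattr__(self, "icer", icer)
        object.__setattr__(self, "dominance", dominance)
        if dominance == "equivalent":
            verdict = "equivalent"
        else:
            ce = nmb >= 0.0
            verdict = (f"{'' if ce else 'not '}cost-effective at WTP "
                       f"¥{self.wtp:,.2f}/QALY")
        object.__setattr__(self, "verdict", verdict)

    @property
    def cost_effective(self) -> bool:
        return self.dominance != "dominated" and self.nmb >= 0.0

    def to_frame(self) -> pd.DataFrame:
        """Base-case results table: one row per strategy, incremental columns
        on the intervention row."""
        return pd.DataFrame([
            {
                "group": self.intervention.name,
                "cost": round(self.intervention.discounted_cost, 2),
                "incremental_cost": round(self.incremental_cost, 2),
                "qalys": round(self.intervention.discounted_qalys, 2),
                "incremental_qalys": round(self.incremental_qalys, 2),
                "icer": None if self.icer is None else round(self.icer, 2),
                "dominance": self.dominance,
            },
            {
                "group": self.comparator.name,
                "cost": round(self.comparator.discounted_cost, 2),
                "incremental_cost": None,
                "qalys": round(self.comparator.discounted_qalys, 2),
                "incremental_qalys": None,
                "icer": None,
                "dominance": None,
            },
        ])


def compare(intervention: StrategyOutcome, comparator: StrategyOutcome,
            config: ModelConfig) -> CEAResult:
    """Incremental comparison, intervention minus comparator."""
    return CEAResult(intervention=intervention, comparator=comparator, wtp=config.wtp)


# ---------------------------------------------------------------------------
# a full decision case (both arms + shared inputs)


@dataclass(frozen=True)
class DecisionCase:
    """Everything needed to run the deterministic model once."""

    config: ModelConfig
    intervention: StrategyInputs
    comparator: StrategyInputs
    costs: CostInputs
    utilities: Utilities

    @property
    def strategies(self) -> tuple[StrategyInputs, StrategyInputs]:
        return (self.intervention, self.comparator)


def evaluate_case(case: DecisionCase, traces=None) -> CEAResult:
    """Build traces (unless supplied), accrue both arms, and compare.

    ``traces`` may carry pre-built (intervention, comparator) traces: state
    occupancy depends only on the survival models and cycle grid, so
    sensitivity analyses that vary costs, utilities or the discount rate can
    reuse them.
    """
    from .markov_engine import build_trace  # local to avoid import cycles

    if traces is None:
        traces = tuple(
            build_trace(case.config, s.os_model, s.pfs_model) for s in case.strategies
        )
    out_i = accrue(traces[0], case.intervention, case.costs, case.utilities, case.config)
    out_c = accrue(traces[1], case.comparator, case.costs, case.utilities, case.config)
    return compare(out_i, out_c, case.config)
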