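"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis reruns the deterministic model at each parameter's lower
and upper limit with everything else at baseline, ranking parameters by the
ICER spread they induce. Probabilistic analysis draws every non-fixed
parameter jointly (independently) from its assigned distribution — gamma for
costs, beta for utilities and the discount rate — reruns both arms per draw,
and summarises the (dCost, dQALY) cloud as a cost-effectiveness
acceptability curve (CEAC).

Distribution moments follow the usual method-of-moments convention for
decision models: mean = baseline and sd = (high - low) / (2 * 1.96), i.e.
the stated limits are read as a 95% interval. Beta-distributed parameters
are rescaled to their natural support first ([0, 1] for utilities; the
sensitivity range [0, 0.08] for the discount rate).

The fitted survival-curve parameters are deliberately held fixed in the PSA:
no sampling distributions are published for them. (Hooking in multivariate-
normal sampling of the fit would be a natural extension.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import DecisionCase, evaluate_case
from .markov_engine import build_trace

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "PARAM_SD_DIVISOR",
    "valid_param_names",
    "apply_overrides",
    "sample_parameter",
    "one_way",
    "tornado_to_frame",
    "run_psa",
    "ceac",
    "ceac_crossing",
    "default_wtp_grid",
]

log = logging.getLogger(__name__)

PARAM_SD_DIVISOR = 2 * 1.96  # limits read as a 95% interval


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: baseline, range, and sampling distribution.

    ``distribution`` is 'gamma', 'beta' or 'fixed'. Beta specs carry their
    natural ``support``; the parameter is rescaled to [0, 1] on that support
    before moment matching.
    """

    name: str
    baseline: float
    low: float
    high: float
    distribution: str = "fixed"
    support: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.distribution not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if not (self.low <= self.baseline <= self.high):
            raise ValueError(
                f"{self.name}: require low <= baseline <= high, got "
                f"({self.low}, {self.baseline}, {self.high})")
        if self.distribution == "gamma" and self.baseline <= 0 and self.sd > 0:
            raise ValueError(f"{self.name}: gamma needs a positive baseline")
        if self.distribution == "beta":
            a, b = self.support
            if not (a < b and a <= self.low and self.high <= b):
                raise ValueError(
                    f"{self.name}: limits [{self.low}, {self.high}] must lie in "
                    f"the beta support [{a}, {b}]")
            if self.sd > 0:
                self.beta_params()  # fail fast on infeasible moments

    @property
    def sd(self) -> float:
        return (self.high - self.low) / PARAM_SD_DIVISOR

    def gamma_params(self) -> tuple[float, float]:
        """(shape, scale) with mean=baseline, sd per the range rule."""
        shape = (self.baseline / self.sd) ** 2
        return shape, self.sd**2 / self.baseline

    def beta_params(self) -> tuple[float, float]:
        """(alpha, beta) on the rescaled support."""
        a, b = self.support
        m = (self.baseline - a) / (b - a)
        s = self.sd / (b - a)
        if m <= 0.0 or m >= 1.0:
            raise ValueError(f"{self.name}: beta baseline must lie strictly inside its support")
        if s**2 >= m * (1 - m):
            raise ValueError(
                f"{self.name}: sd {self.sd:g} too large for a beta on "
                f"[{a}, {b}] with mean {self.baseline:g}")
        nu = m * (1 - m) / s**2 - 1.0
        return m * nu, (1 - m) * nu


def sample_parameter(spec: ParamSpec, rng: np.random.Generator) -> float:
    """Draw one value; degenerate ranges and 'fixed' return the baseline."""
    if spec.distribution == "fixed" or spec.sd == 0.0:
        return spec.baseline
    if spec.distribution == "gamma":
        shape, scale = spec.gamma_params()
        return float(rng.gamma(shape, scale))
    alpha, beta = spec.beta_params()
    a, b = spec.support
    return a + (b - a) * float(rng.beta(alpha, beta))


# ---------------------------------------------------------------------------
# mapping parameter names onto the decision case


def _registry(case: DecisionCase) -> dict[str, Callable[[DecisionCase, float], DecisionCase]]:
    reg: dict[str, Callable[[DecisionCase, float], DecisionCase]] = {}

    def set_strategy_field(key, fname):
        def setter(c: DecisionCase, v: float) -> DecisionCase:
            if c.intervention.key == key:
                return replace(c, intervention=replace(c.intervention, **{fname: v}))
            return replace(c, comparator=replace(c.comparator, **{fname: v}))
        return setter

    for strat in case.strategies:
        reg[f"drug_cost.{strat.key}"] = set_strategy_field(strat.key, "drug_cost_per_cycle")

    for fname in ("lab_per_visit", "imaging_per_visit", "supportive_per_cycle",
                  "end_of_life_once", "subsequent_tx_per_cycle"):
        def cost_setter(c, v, fname=fname):
            return replace(c, costs=replace(c.costs, **{fname: v}))
        reg[f"cost.{fname}"] = cost_setter

    ae_names = {ae.name for s in case.strategies for ae in s.adverse_events}
    for ae_name in sorted(ae_names):
        def ae_setter(c, v, ae_name=ae_name):
            def patch(s):
                return replace(s, adverse_events=tuple(
                    replace(ae, unit_cost=v) if ae.name == ae_name else ae
                    for ae in s.adverse_events))
            return replace(c, intervention=patch(c.intervention),
                           comparator=patch(c.comparator))
        reg[f"ae_cost.{ae_name}"] = ae_setter

    reg["utility.pfs"] = lambda c, v: replace(c, utilities=replace(c.utilities, u_pfs=v))
    reg["utility.pd"] = lambda c, v: replace(c, utilities=replace(c.utilities, u_pd=v))
    reg["discount_rate"] = lambda c, v: replace(
        c, config=replace(c.config, annual_discount=v))
    return reg


def valid_param_names(case: DecisionCase) -> list[str]:
    return sorted(_registry(case))


def apply_overrides(case: DecisionCase, overrides: Mapping[str, float]) -> DecisionCase:
    """Return a copy of the case with the named parameters replaced."""
    reg = _registry(case)
    out = case
    overrides = dict(overrides)
    # the two utilities are jointly constrained (u_pd <= u_pfs): swap them in
    # atomically so one-at-a-time application cannot trip the invariant early
    u_pfs = overrides.pop("utility.pfs", None)
    u_pd = overrides.pop("utility.pd", None)
    for name, value in overrides.items():
        if name not in reg:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: {sorted(reg)}")
        out = reg[name](out, value)
    if u_pfs is not None or u_pd is not None:
        new_u = replace(
            out.utilities,
            u_pfs=out.utilities.u_pfs if u_pfs is None else u_pfs,
            u_pd=out.utilities.u_pd if u_pd is None else u_pd,
        )
        out = replace(out, utilities=new_u)
    return out


def _case_traces(case: DecisionCase):
    return tuple(build_trace(case.config, s.os_model, s.pfs_model)
                 for s in case.strategies)


# ---------------------------------------------------------------------------
# one-way (tornado)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(case: DecisionCase, specs: Sequence[ParamSpec]) -> list[TornadoEntry]:
    """Rerun the deterministic model at each parameter's low and high limit.

    Returns entries sorted by descending ICER spread. A dominance outcome at
    a limit is recorded as a signed infinity-free sentinel: the NMB-implied
    'equivalent ICER' would be misleading, so dominant results report the
    ICER as 0 (better and cheaper) — with the shipped inputs this does not
    occur and every limit yields a finite ratio.
    """
    traces = _case_traces(case)
    names = valid_param_names(case)
    for spec in specs:
        if spec.name not in names:
            raise KeyError(f"unknown parameter {spec.name!r}; valid names: {names}")

    def icer_at(name: str, value: float) -> float:
        res = evaluate_case(apply_overrides(case, {name: value}), traces=traces)
        if res.icer is not None:
            return res.icer
        return 0.0 if res.dominance == "dominant" else float("inf")

    entries = [
        TornadoEntry(s.name, icer_at(s.name, s.low), icer_at(s.name, s.high))
        for s in specs
    ]
    return sorted(entries, key=lambda e: -e.spread)


def tornado_to_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {"parameter": e.parameter, "icer_low": e.icer_at_low,
         "icer_high": e.icer_at_high, "spread": e.spread}
        for e in entries
    ])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo (dCost, dQALY) samples plus CEAC points."""

    d_cost: np.ndarray
    d_qaly: np.ndarray
    ceac: pd.DataFrame
    seed: int
    n_invalid_resampled: int = 0

    @property
    def n_sims(self) -> int:
        return int(self.d_cost.size)

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n_sims),
            "d_cost": self.d_cost,
            "d_qaly": self.d_qaly,
        })


def default_wtp_grid() -> np.ndarray:
    """0 to 1,000,000 CNY/QALY in 5,000 steps."""
    return np.arange(0.0, 1_000_000.0 + 1.0, 5_000.0)


def run_psa(
    case: DecisionCase,
    specs: Sequence[ParamSpec],
    n_sims: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Joint Monte-Carlo propagation of all non-fixed parameters.

    Draws violating a structural constraint (u_pd > u_pfs, discount outside
    its support) are resampled and counted; if resamples exceed 5% of n_sims
    the parameter specification is considered pathological and the run
    aborts. (With the shipped utility distributions the rejection probability
    is about 1%, so the valve only trips on genuinely broken configs.)
    Survival parameters are fixed, so state occupancy is computed once per
    arm and reused; only accrual is repeated per draw. Reproducible given the
    seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    rng = np.random.default_rng(seed)
    traces = _case_traces(case)
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    names = valid_param_names(case)
    for spec in specs:
        if spec.name not in names:
            raise KeyError(f"unknown parameter {spec.name!r}; valid names: {names}")
        if spec.distribution == "beta" and spec.sd > 0:
            spec.beta_params()  # moment feasibility is a config-load error

    d_cost = np.empty(n_sims)
    d_qaly = np.empty(n_sims)
    max_invalid = max(1, int(0.05 * n_sims))
    n_invalid = 0
    for i in range(n_sims):
        while True:
            values = {s.name: sample_parameter(s, rng) for s in specs}
            try:
                drawn = apply_overrides(case, values)
            except (ValueError, KeyError):
                drawn = None
            if drawn is not None:
                break
            n_invalid += 1
            if n_invalid > max_invalid:
                raise RuntimeError(
                    f"PSA rejected more than {max_invalid} structurally invalid "
                    "draws; check the parameter specifications")
        res = evaluate_case(drawn, traces=traces)
        d_cost[i] = res.incremental_cost
        d_qaly[i] = res.incremental_qalys
    if n_invalid:
        log.info("PSA resampled %d structurally invalid draws", n_invalid)
    ceac_df = ceac_frame(d_cost, d_qaly, wtp_grid)
    return PSAResult(d_cost=d_cost, d_qaly=d_qaly, ceac=ceac_df, seed=seed,
                     n_invalid_resampled=n_invalid)


def ceac_frame(d_cost: np.ndarray, d_qaly: np.ndarray,
               wtp_grid: np.ndarray) -> pd.DataFrame:
    probs = [float(np.mean(w * d_qaly - d_cost > 0.0)) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "p_ce": probs})


def ceac(result: PSAResult, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Probability the intervention is cost-effective (positive incremental
    NMB) at each willingness-to-pay value."""
    if result.n_sims == 0:
        raise ValueError("CEAC requires at least one PSA sample")
    return ceac_frame(result.d_cost, result.d_qaly, np.asarray(wtp_grid, dtype=float))


def ceac_crossing(ceac_df: pd.DataFrame, level: float = 0.5) -> float | None:
    """Smallest WTP on the grid where the acceptability reaches `level`."""
    hit = ceac_df[ceac_df["p_ce"] >= level]
    return None if hit.empty else float(hit["wtp"].iloc[0])
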