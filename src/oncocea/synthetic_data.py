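"""Synthetic trial data with known ground truth.

No patient-level data from the source trial is public; the pipeline's only
real-world inputs are digitized Kaplan-Meier coordinates. This module
manufactures those inputs end to end — simulated event records, KM step
curves, noisily "digitized" coordinate files, and complete runnable
workspaces — so every downstream stage can be tested against a known truth.

The ``sunlight_like`` preset mirrors the study conditions this package was
built around: 246 patients per arm, log-normal OS and PFS truths taken from
the published best-fit parameter table, and administrative censoring at 12
months of follow-up (so extrapolation beyond the observed window is
genuinely exercised). What the generator does **not** emulate: pixel-level
digitization artefacts, informative censoring, and covariate structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from lifelines import KaplanMeierFitter

from .km_reconstruction import DigitizedCurve, write_curve_csv
from .survival_models import ParametricSurvival, PseudoIPD

__all__ = [
    "FOLLOWUP_MONTHS",
    "Scenario",
    "simulate_ipd",
    "km_step",
    "digitize",
    "make_scenario",
    "PRESETS",
]

#: Observed follow-up window (months) for administrative censoring.
FOLLOWUP_MONTHS = 12.0

#: Published best-fit log-normal (meanlog, sdlog) truths per arm and endpoint.
_TABLE_TRUTH = {
    ("combo", "PFS"): ("lognormal", 1.660, 0.850),
    ("combo", "OS"): ("lognormal", 2.398, 0.808),
    ("mono", "PFS"): ("lognormal", 1.110, 0.644),
    ("mono", "OS"): ("lognormal", 2.030, 0.793),
}


@dataclass(frozen=True)
class Scenario:
    """Ground truth and generation settings for one synthetic study."""

    name: str
    truth: dict[tuple[str, str], ParametricSurvival]  # (arm, endpoint) -> model
    n_per_arm: int = 246
    censoring_rate: float = 0.0
    n_points: int = 30
    jitter_sd: float = 0.005
    seed: int = 0
    followup_months: float = FOLLOWUP_MONTHS

    def curves(self) -> dict[tuple[str, str], DigitizedCurve]:
        """Simulate, KM-estimate, and digitize every arm/endpoint curve.

        Seeds for the individual curves are derived deterministically from
        the scenario seed so the curves are independent but reproducible.
        """
        out = {}
        for i, ((arm, endpoint), model) in enumerate(sorted(self.truth.items())):
            sub_seed = (self.seed * 8 + i) % (2**31)
            ipd = simulate_ipd(model, self.n_per_arm, self.censoring_rate,
                               seed=sub_seed, t_max=self.followup_months)
            km = km_step(ipd, arm=arm, endpoint=endpoint)
            out[(arm, endpoint)] = digitize(km, self.n_points, self.jitter_sd,
                                            seed=sub_seed + 1)
        return out


def simulate_ipd(
    model: ParametricSurvival,
    n: int,
    censoring_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    t_max: float | None = None,
) -> PseudoIPD:
    """Draw n event records by inverse-transform sampling.

    Censoring is non-informative: every subject receives an independent
    censoring time C ~ Uniform(0, c_max), with c_max solved so that the
    marginal censoring probability P(C < T) equals ``censoring_rate``. If
    ``t_max`` is set, any time beyond it is administratively censored there.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (0.0 <= censoring_rate < 1.0):
        raise ValueError("censoring_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(model.quantile(rng.uniform(size=n)), dtype=float)
    times = np.minimum(np.maximum(times, 1e-9), 1e9)
    events = np.ones(n, dtype=bool)
    if censoring_rate > 0:
        c_max = _uniform_censor_bound(model, censoring_rate)
        cens_times = rng.uniform(0.0, c_max, size=n)
        censored = cens_times < times
        times[censored] = np.maximum(cens_times[censored], 1e-9)
        events[censored] = False
    if t_max is not None:
        over = times > t_max
        times[over] = t_max
        events[over] = False
    return PseudoIPD(times, events)


def _uniform_censor_bound(model: ParametricSurvival, rate: float) -> float:
    """Upper bound c_max of the Uniform(0, c_max) censoring law such that
    P(C < T) = (1/c_max) * int_0^{c_max} S(t) dt equals ``rate``."""
    from scipy.optimize import brentq

    def marginal(c: float) -> float:
        return model.mean_truncated(c, n_grid=2001) / c - rate

    lo, hi = 1e-6, 1.0
    while marginal(hi) > 0 and hi < 1e7:
        hi *= 2.0
    if marginal(hi) > 0:
        raise ValueError(
            f"cannot reach a marginal censoring rate of {rate} with uniform "
            "censoring (survival plateau too high)")
    return float(brentq(marginal, lo, hi, xtol=1e-9, rtol=1e-12))


def km_step(data: PseudoIPD, arm: str = "", endpoint: str = "OS") -> DigitizedCurve:
    """Product-limit (Kaplan-Meier) step estimate of the survival curve.

    Returns the curve anchored at (0, 1) with one point per distinct event
    time. With zero events the curve is flat at 1 up to the last censoring
    time; this is valid as a curve but unusable for fitting downstream.
    """
    if len(data) == 0:
        raise ValueError("cannot estimate a curve from zero records")
    if data.n_events == 0:
        return DigitizedCurve(arm=arm, endpoint=endpoint,
                              points=((0.0, 1.0), (float(data.times.max()), 1.0)))
    kmf = KaplanMeierFitter()
    kmf.fit(data.times, event_observed=data.events)
    event_times = np.unique(data.times[data.events])
    surv = kmf.survival_function_at_times(event_times).to_numpy(float)
    points = [(0.0, 1.0)] + list(zip(event_times, surv))
    return DigitizedCurve(arm=arm, endpoint=endpoint, points=tuple(points))


def _step_lookup(curve: DigitizedCurve, ts: np.ndarray) -> np.ndarray:
    """Right-continuous step-function values of the curve at the given times."""
    idx = np.searchsorted(curve.times, ts, side="right") - 1
    idx = np.clip(idx, 0, len(curve.points) - 1)
    return curve.survivals[idx]


def digitize(
    curve: DigitizedCurve,
    n_points: int = 30,
    jitter_sd: float = 0.005,
    seed: int = 0,
) -> DigitizedCurve:
    """Emulate manual digitization of a published KM figure.

    Samples the step function at ``n_points`` evenly spaced times over
    [0, t_max], perturbs the survival reads with truncated Gaussian noise
    (sd ``jitter_sd``, clipped to [0, 1]), and restores monotonicity by
    isotonic clipping (running minimum). The (0, 1) anchor is kept exact —
    digitizers calibrate the axes on it.
    """
    if n_points < 5:
        raise ValueError("n_points must be at least 5")
    t_max = float(curve.times[-1])
    ts = np.linspace(0.0, t_max, n_points)
    s = _step_lookup(curve, ts)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        s = np.clip(s + rng.normal(0.0, jitter_sd, size=s.shape), 0.0, 1.0)
    s[0] = 1.0
    s = np.minimum.accumulate(s)
    return DigitizedCurve(arm=curve.arm, endpoint=curve.endpoint,
                          points=tuple(zip(ts, s)))


# ---------------------------------------------------------------------------
# presets


def _models(spec: dict) -> dict[tuple[str, str], ParametricSurvival]:
    return {k: ParametricSurvival(fam, shape, scale)
            for k, (fam, shape, scale) in spec.items()}


def _preset_sunlight_like(seed: int) -> Scenario:
    return Scenario(name="sunlight_like", truth=_models(_TABLE_TRUTH),
                    n_per_arm=246, censoring_rate=0.0, n_points=30,
                    jitter_sd=0.005, seed=seed)


def _preset_stress_crossing(seed: int) -> Scenario:
    # PFS truth above the OS truth until ~18 months: exercises the clamp
    truth = dict(_TABLE_TRUTH)
    truth[("combo", "PFS")] = ("lognormal", 2.5, 0.60)
    truth[("combo", "OS")] = ("lognormal", 2.3, 0.90)
    return Scenario(name="stress_crossing", truth=_models(truth),
                    n_per_arm=246, censoring_rate=0.0, n_points=30,
                    jitter_sd=0.005, seed=seed)


def _preset_heavy_censoring(seed: int) -> Scenario:
    return Scenario(name="heavy_censoring", truth=_models(_TABLE_TRUTH),
                    n_per_arm=246, censoring_rate=0.5, n_points=30,
                    jitter_sd=0.005, seed=seed)


PRESETS = {
    "sunlight_like": _preset_sunlight_like,
    "stress_crossing": _preset_stress_crossing,
    "heavy_censoring": _preset_heavy_censoring,
}


def make_scenario(preset: str, seed: int, out_dir: str | Path | None = None) -> Scenario:
    """Build a preset scenario; if ``out_dir`` is given, also materialize a
    complete runnable workspace (curve CSVs + a pipeline config YAML whose
    survival models are the *truth* parameters).

    Identical (preset, seed) pairs produce byte-identical files.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    scenario = PRESETS[preset](seed)
    if out_dir is not None:
        _write_workspace(scenario, Path(out_dir))
    return scenario


def _write_workspace(scenario: Scenario, out_dir: Path) -> None:
    from .cli_io import default_config_dict  # deferred: cli_io imports this module

    out_dir.mkdir(parents=True, exist_ok=True)
    curves_dir = out_dir / "curves"
    curves_dir.mkdir(exist_ok=True)
    for (arm, endpoint), curve in sorted(scenario.curves().items()):
        write_curve_csv(curve, curves_dir / f"{arm}_{endpoint.lower()}.csv")
    cfg = default_config_dict()
    for strat in cfg["strategies"]:
        for endpoint, key in (("OS", "os_model"), ("PFS", "pfs_model")):
            model = scenario.truth[(strat["key"], endpoint)]
            strat[key] = {"family": model.family, "shape": model.shape,
                          "scale": model.scale}
    cfg["scenario"] = {
        "name": scenario.name, "seed": scenario.seed,
        "n_per_arm": scenario.n_per_arm,
        "censoring_rate": scenario.censoring_rate,
        "n_points": scenario.n_points, "jitter_sd": scenario.jitter_sd,
        "followup_months": scenario.followup_months,
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
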