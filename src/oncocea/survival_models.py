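"""Parametric survival families, censored maximum-likelihood fitting, and
AIC/BIC model selection.

Six families are supported: exponential, Weibull, log-normal, log-logistic,
Gompertz, and gamma. All work in **months**. The parameter conventions are:

============  =======================  ==========================================
family        shape                    scale
============  =======================  ==========================================
exponential   (unused, ``None``)       rate :math:`\\lambda`; :math:`S(t)=e^{-\\lambda t}`
weibull       :math:`k`                :math:`\\lambda`; :math:`S(t)=e^{-(t/\\lambda)^k}`
lognormal     meanlog :math:`\\mu`      sdlog :math:`\\sigma`
loglogistic   steepness :math:`\\beta`  :math:`\\alpha`; :math:`S(t)=1/(1+(t/\\alpha)^\\beta)`
gompertz      :math:`\\gamma` (any      rate :math:`\\lambda>0`;
              real; 0 = exponential)   :math:`S(t)=\\exp(-\\frac{\\lambda}{\\gamma}(e^{\\gamma t}-1))`
gamma         :math:`k`                rate :math:`\\beta` (so mean = k/rate)
============  =======================  ==========================================

Note the log-normal convention: ``shape`` is the meanlog and ``scale`` the
sdlog, both on the natural-log month scale, so the median survival time is
``exp(shape)`` months. This matches the shape/scale labelling used in the
published parameter tables this package consumes.

A Gompertz model with negative shape is *defective*: :math:`S(t)` plateaus at
:math:`\\exp(\\lambda/\\gamma) > 0` instead of tending to zero. This is permitted
(it can be the best empirical fit) but documented here because it breaks the
usual "everyone eventually dies" reading of a survival curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "N_PARAMS",
    "ParametricSurvival",
    "PseudoIPD",
    "FitResult",
    "FitError",
    "survival",
    "density",
    "hazard",
    "cumulative_hazard",
    "cumulative_incidence",
    "quantile",
    "fit_mle",
    "fit_all",
    "fit_curve_lsq",
    "select_best",
    "fits_to_frame",
]

#: Fixed family order; also the deterministic tie-break order in model selection.
FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz", "gamma")

#: Free parameters per family (exponential has no shape).
N_PARAMS = {f: (1 if f == "exponential" else 2) for f in FAMILIES}


class FitError(ValueError):
    """Raised when a fit is requested on data that cannot support it."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival distribution for event times in months."""

    family: str
    shape: float | None
    scale: float
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.time_unit != "months":
            raise ValueError("only the 'months' time unit is supported")
        if self.family == "exponential":
            if self.shape is not None:
                raise ValueError("exponential takes no shape parameter (pass shape=None)")
            if not self.scale > 0:
                raise ValueError("exponential rate (scale) must be positive")
            return
        if self.shape is None or not np.isfinite(self.shape):
            raise ValueError(f"{self.family} requires a finite shape parameter")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"{self.family} scale must be positive and finite")
        if self.family in ("weibull", "loglogistic", "gamma") and not self.shape > 0:
            raise ValueError(f"{self.family} shape must be positive")
        # lognormal shape (meanlog) and gompertz shape may be any real

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.family]

    # -- core functions ------------------------------------------------------

    def log_survival(self, t):
        """log S(t), vectorised; t >= 0."""
        t = _check_time(t)
        fam, a, b = self.family, self.shape, self.scale
        if fam == "exponential":
            return -b * t
        if fam == "weibull":
            return -np.power(t / b, a)
        if fam == "lognormal":
            with np.errstate(divide="ignore"):
                z = np.where(t > 0, (np.log(np.where(t > 0, t, 1.0)) - a) / b, -np.inf)
            return stats.norm.logsf(z)
        if fam == "loglogistic":
            return -np.log1p(np.power(t / b, a))
        if fam == "gompertz":
            if abs(a) < 1e-12:
                return -b * t
            with np.errstate(over="ignore"):  # overflow -> -inf log-survival, intended
                return -(b / a) * np.expm1(a * t)
        # gamma, rate parameterisation
        return stats.gamma.logsf(t, a, scale=1.0 / b)

    def survival(self, t):
        """S(t) = P(T > t)."""
        return np.exp(self.log_survival(t))

    def cumulative_hazard(self, t):
        """H(t) = -log S(t); returns +inf where S(t) = 0."""
        return -self.log_survival(t)

    def cumulative_incidence(self, t):
        """F(t) = 1 - S(t), the CDF of the event time."""
        return -np.expm1(self.log_survival(t))

    def log_density(self, t):
        """log f(t) for t > 0."""
        t = _check_time(t)
        if np.any(np.asarray(t) <= 0):
            raise ValueError("density requires strictly positive times")
        fam, a, b = self.family, self.shape, self.scale
        if fam == "exponential":
            return np.log(b) - b * t
        if fam == "weibull":
            return np.log(a / b) + (a - 1) * np.log(t / b) - np.power(t / b, a)
        if fam == "lognormal":
            z = (np.log(t) - a) / b
            return stats.norm.logpdf(z) - np.log(t * b)
        if fam == "loglogistic":
            return np.log(a / b) + (a - 1) * np.log(t / b) - 2 * np.log1p(np.power(t / b, a))
        if fam == "gompertz":
            if abs(a) < 1e-12:
                return np.log(b) - b * t
            with np.errstate(over="ignore"):  # overflow -> -inf log-density, intended
                return np.log(b) + a * t - (b / a) * np.expm1(a * t)
        return stats.gamma.logpdf(t, a, scale=1.0 / b)

    def density(self, t):
        return np.exp(self.log_density(t))

    def hazard(self, t):
        """h(t) = f(t)/S(t)."""
        return np.exp(self.log_density(t) - self.log_survival(t))

    def quantile(self, p):
        """Inverse of F: smallest t with 1 - S(t) >= p. Defective Gompertz
        models return +inf for p beyond the attainable event fraction."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        fam, a, b = self.family, self.shape, self.scale
        if fam == "exponential":
            return -np.log1p(-p) / b
        if fam == "weibull":
            return b * np.power(-np.log1p(-p), 1.0 / a)
        if fam == "lognormal":
            return np.exp(a + b * stats.norm.ppf(p))
        if fam == "loglogistic":
            with np.errstate(divide="ignore"):
                return b * np.power(p / (1 - p), 1.0 / a)
        if fam == "gompertz":
            if abs(a) < 1e-12:
                return -np.log1p(-p) / b
            arg = 1.0 - a * np.log1p(-p) / b
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.log(arg) / a
            return np.where(arg > 0, out, np.inf)
        return stats.gamma.ppf(p, a, scale=1.0 / b)

    def mean_truncated(self, horizon: float, n_grid: int = 20001) -> float:
        """Restricted mean survival time over [0, horizon] months, by
        numerical integration of S(t) (composite trapezoid)."""
        ts = np.linspace(0.0, horizon, n_grid)
        return float(np.trapezoid(self.survival(ts), ts))

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {"family": self.family, "shape": self.shape, "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricSurvival":
        fam = d["family"]
        shape = d.get("shape")
        return cls(family=fam, shape=None if fam == "exponential" else float(shape),
                   scale=float(d["scale"]))


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


# ---------------------------------------------------------------------------
# module-level functional interface


def survival(model: ParametricSurvival, t):
    return model.survival(t)


def density(model: ParametricSurvival, t):
    return model.density(t)


def hazard(model: ParametricSurvival, t):
    return model.hazard(t)


def cumulative_hazard(model: ParametricSurvival, t):
    return model.cumulative_hazard(t)


def cumulative_incidence(model: ParametricSurvival, t):
    return model.cumulative_incidence(t)


def quantile(model: ParametricSurvival, p):
    return model.quantile(p)


# ---------------------------------------------------------------------------
# pseudo individual-patient data


@dataclass(frozen=True)
class PseudoIPD:
    """Right-censored event records: (time in months, event indicator).

    Times must be strictly positive. Zero events is representable (a flat
    Kaplan-Meier curve reconstructs to one) but such data cannot be fitted.
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events).astype(bool)
        if times.shape != events.shape or times.ndim != 1:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if times.size and np.any(times <= 0):
            raise ValueError("all times must be strictly positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events.astype(int)})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PseudoIPD":
        return cls(df["time_months"].to_numpy(float), df["event"].to_numpy(int))


@dataclass(frozen=True)
class FitResult:
    """One family's maximum-likelihood fit, with information criteria.

    AIC = -2*loglik + 2k, BIC = -2*loglik + k*ln(n), k = free parameters.
    """

    model: ParametricSurvival | None
    loglik: float
    aic: float
    bic: float
    n: int
    converged: bool = True
    message: str = ""
    family: str = field(default="")

    def __post_init__(self) -> None:
        if self.model is not None and not self.family:
            object.__setattr__(self, "family", self.model.family)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting

_GTOL = 1e-8


def _neg_loglik(model: ParametricSurvival, data: PseudoIPD) -> float:
    ev, cen = data.events, ~data.events
    ll = 0.0
    if ev.any():
        ll += float(np.sum(model.log_density(data.times[ev])))
    if cen.any():
        ll += float(np.sum(model.log_survival(data.times[cen])))
    return -ll


def _initial_params(family: str, data: PseudoIPD) -> np.ndarray:
    """Moment-style starting values on the transformed (unconstrained) scale."""
    te = data.times[data.events]
    rate0 = max(data.n_events / float(data.times.sum()), 1e-6)
    lm = float(np.mean(np.log(te)))
    ls = max(float(np.std(np.log(te))), 0.05)
    m1 = float(np.mean(te))
    s1 = max(float(np.std(te)), 1e-3)
    if family == "exponential":
        return np.array([math.log(rate0)])
    if family == "weibull":
        k0 = max(1.2825 / ls, 0.05)  # sd of log Weibull = (pi/sqrt 6)/k
        return np.array([math.log(k0), math.log(math.exp(lm + 0.5772 / k0))])
    if family == "lognormal":
        return np.array([lm, math.log(ls)])
    if family == "loglogistic":
        b0 = max(1.8138 / ls, 0.05)  # sd of log log-logistic = pi/(sqrt3 * beta)
        return np.array([math.log(b0), lm])
    if family == "gompertz":
        return np.array([0.05, math.log(rate0)])
    # gamma, method of moments on event times
    k0 = max((m1 / s1) ** 2, 0.05)
    return np.array([math.log(k0), math.log(max(m1 / s1**2, 1e-6))])


def _decode(family: str, theta: np.ndarray) -> ParametricSurvival:
    if family == "exponential":
        return ParametricSurvival("exponential", None, math.exp(theta[0]))
    if family == "lognormal":
        return ParametricSurvival("lognormal", float(theta[0]), math.exp(theta[1]))
    if family == "loglogistic":
        return ParametricSurvival("loglogistic", math.exp(theta[0]), math.exp(theta[1]))
    if family == "gompertz":
        return ParametricSurvival("gompertz", float(theta[0]), math.exp(theta[1]))
    return ParametricSurvival(family, math.exp(theta[0]), math.exp(theta[1]))


def fit_mle(data: PseudoIPD, family: str) -> FitResult:
    """Fit one family to right-censored records by maximum likelihood.

    Positive parameters are optimised on the log scale with a bounded
    quasi-Newton method (L-BFGS-B) from three deterministic starts; the best
    converged start wins. Non-convergence yields ``FitResult(converged=False)``
    with NaN criteria rather than a silent NaN parameter set.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if data.n_events < 1:
        raise FitError("fitting requires at least one event record")
    if N_PARAMS[family] == 2 and np.unique(data.times[data.events]).size < 2:
        raise FitError(f"{family} needs at least two distinct event times")

    def objective(theta: np.ndarray) -> float:
        try:
            val = _neg_loglik(_decode(family, theta), data)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e30
        return val if np.isfinite(val) else 1e30

    theta0 = _initial_params(family, data)
    best = None
    for offset in (0.0, 0.5, -0.5):
        res = optimize.minimize(
            objective, theta0 + offset, method="L-BFGS-B",
            options={"gtol": _GTOL, "ftol": 1e-12, "maxiter": 500},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    n = len(data)
    k = N_PARAMS[family]
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e29:
        return FitResult(model=None, loglik=float("nan"), aic=float("nan"),
                         bic=float("nan"), n=n, converged=False,
                         message=f"{family}: optimizer failed to converge", family=family)
    loglik = -float(best.fun)
    return FitResult(
        model=_decode(family, best.x),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * math.log(n),
        n=n,
    )


def fit_all(data: PseudoIPD, families: Sequence[str] = FAMILIES) -> list[FitResult]:
    """Fit every requested family; failures are returned, not raised."""
    out = []
    for fam in families:
        try:
            out.append(fit_mle(data, fam))
        except FitError as exc:
            out.append(FitResult(model=None, loglik=float("nan"), aic=float("nan"),
                                 bic=float("nan"), n=len(data), converged=False,
                                 message=str(exc), family=fam))
    return out


def select_best(fits: Iterable[FitResult], criterion: str = "aic") -> FitResult:
    """Pick the fit with the smallest AIC or BIC.

    Ties break deterministically by the fixed family order
    exponential < weibull < lognormal < loglogistic < gompertz < gamma.
    All candidate fits must have converged.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_best requires at least one fit")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    bad = [f for f in fits if not f.converged]
    if bad:
        raise ValueError(f"non-converged fits passed to select_best: "
                         f"{[f.family for f in bad]}")
    return min(fits, key=lambda f: (getattr(f, criterion), FAMILIES.index(f.family)))


def fits_to_frame(fits: Iterable[FitResult]) -> pd.DataFrame:
    """One row per family: family, shape, scale, loglik, aic, bic."""
    rows = []
    for f in fits:
        rows.append({
            "family": f.family,
            "shape": None if f.model is None else f.model.shape,
            "scale": None if f.model is None else f.model.scale,
            "loglik": f.loglik, "aic": f.aic, "bic": f.bic,
            "n": f.n, "converged": f.converged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# least-squares on the log cumulative hazard (regression-on-curve cross-check)


def fit_curve_lsq(times, survivals, family: str) -> ParametricSurvival:
    """Fit a family directly to curve coordinates by least squares on
    log H(t) = log(-log S(t)).

    A diagnostic alternative to pseudo-IPD maximum likelihood: useful for
    cross-checking that the reconstruction step did not distort the fit.
    Points with S in {0, 1} are dropped (log cumulative hazard undefined).
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(survivals, dtype=float)
    keep = (s > 0) & (s < 1) & (t > 0)
    t, s = t[keep], s[keep]
    if t.size < N_PARAMS[family]:
        raise FitError("too few usable curve points for least-squares fitting")
    target = np.log(-np.log(s))

    def objective(theta):
        try:
            model = _decode(family, theta)
            h = model.cumulative_hazard(t)
        except (ValueError, OverflowError):
            return 1e30
        with np.errstate(divide="ignore", invalid="ignore"):
            lh = np.log(h)
        if not np.all(np.isfinite(lh)):
            return 1e30
        return float(np.sum((lh - target) ** 2))

    data_proxy = PseudoIPD(t, np.ones_like(t, dtype=bool))
    theta0 = _initial_params(family, data_proxy)
    best = None
    for offset in (0.0, 0.5, -0.5):
        res = optimize.minimize(objective, theta0 + offset, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return _decode(family, best.x)
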