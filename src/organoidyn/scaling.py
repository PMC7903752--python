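"""Analytic osmotic scaling law for inflating spherical organoids.

For a spherical monolayer whose surface area grows as ``A(t)`` and whose
cells secrete an osmotically active substance at a constant per-cell rate,
the lumen pressure obeys (up to a constant)

    Pi(t)  ~  integral_0^t A(s) ds  /  A(t)^(3/2)

because the amount of substance accumulates with the surface (the number of
secreting cells is proportional to ``A``) while the lumen volume scales as
``A^(3/2)``.  Pressure is time-constant exactly when ``A(t) ~ t^2``: faster
surface growth (exponential) deflates relative pressure and suppresses
rupture, slower growth (linear) inflates it and predicts recurring
rupture-driven size oscillations.

Pressure values carry no absolute units; only their time dependence matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .errors import DomainError

DEFAULT_BURNIN = 0.05  # fraction of the grid excluded from constancy checks


@dataclass(frozen=True)
class GrowthCurve:
    """A positive time series: cell count N(t) or surface area A(t)."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "count"  # "count" or "area"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if not (v > 0).all():
            raise DomainError("growth-curve values must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PressureTrace:
    """Relative lumen pressure over time (proportionality only, no units)."""

    times: np.ndarray
    values: np.ndarray


def _origin_integral(t: np.ndarray, a: np.ndarray) -> float:
    """Estimate ``integral_0^t0 A`` by local power-law extrapolation.

    The cumulative trapezoid only covers the sampled grid; for grids starting
    at ``t0 > 0`` the missing head contribution matters (for ``A = t^p`` it is
    ``A0*t0/(p+1)``, exact under this extrapolation).
    """
    t0, t1 = t[0], t[1]
    if t0 <= 0:
        return 0.0
    q = math.log(a[1] / a[0]) / math.log(t1 / t0)
    if q <= -1:  # non-integrable head; fall back to ignoring it
        return 0.0
    return float(a[0] * t0 / (q + 1.0))


def pressure_from_surface(
    surface: GrowthCurve, include_origin: bool = True
) -> PressureTrace:
    """Relative pressure trace ``Pi(t) = (integral_0^t A) / A(t)^(3/2)``.

    Uses cumulative trapezoidal integration; when the grid starts after t=0
    and ``include_origin`` is set, the head of the integral is estimated by
    power-law extrapolation of the first two samples.
    """
    t, a = surface.times, surface.values
    if len(t) < 2:
        raise DomainError("need at least two samples to integrate")
    head = _origin_integral(t, a) if include_origin else 0.0
    integral = head + cumulative_trapezoid(a, t, initial=0.0)
    return PressureTrace(times=t.copy(), values=integral / a**1.5)


def _tail_slice(n: int, burnin: float) -> slice:
    return slice(max(int(n * burnin), 1), None)


def loglog_slope(
    times: np.ndarray, values: np.ndarray, burnin: float = DEFAULT_BURNIN
) -> float:
    """Least-squares slope of log(values) against log(times) after burn-in."""
    sl = _tail_slice(len(times), burnin)
    t, v = times[sl], values[sl]
    keep = (t > 0) & (v > 0)
    if keep.sum() < 2:
        raise DomainError("not enough positive samples for a log-log slope")
    return float(np.polyfit(np.log(t[keep]), np.log(v[keep]), 1)[0])


def default_time_grid(n: int = 400) -> np.ndarray:
    return np.logspace(-1.0, 1.0, n)


@dataclass(frozen=True)
class ConstancyResult:
    exponent: float
    signed_slope: float      # least-squares log-log slope of Pi(t)
    max_abs_slope: float     # max pointwise |d log Pi / d log t| after burn-in
    balanced: bool


def pressure_constancy(
    p: float,
    t_grid: np.ndarray | None = None,
    burnin: float = DEFAULT_BURNIN,
    tol: float = 1e-3,
) -> ConstancyResult:
    """Time-variation of ``Pi(t)`` for the power-law surface ``A(t) = t^p``.

    The closed form is ``Pi ~ t^(1 - p/2) / (p + 1)``: the log-log slope is
    ``1 - p/2`` and vanishes at p = 2.
    """
    if t_grid is None:
        t_grid = default_time_grid()
    trace = pressure_from_surface(GrowthCurve(t_grid, t_grid**p, kind="area"))
    signed = loglog_slope(trace.times, trace.values, burnin)
    sl = _tail_slice(len(t_grid), burnin)
    logt = np.log(trace.times[sl])
    logv = np.log(trace.values[sl])
    local = np.diff(logv) / np.diff(logt)
    max_abs = float(np.abs(local).max())
    return ConstancyResult(
        exponent=p, signed_slope=signed, max_abs_slope=max_abs,
        balanced=max_abs < tol,
    )


def constant_pressure_exponent(
    p_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    burnin: float = DEFAULT_BURNIN,
) -> float:
    """Exponent p of ``A(t) = t^p`` that makes the pressure time-constant.

    Scans ``p_grid`` for a sign change of the log-log slope of ``Pi(t)`` and
    refines the root with Brent's method.  The analytic answer is p = 2.
    """
    if p_grid is None:
        p_grid = np.linspace(0.5, 4.0, 36)
    if t_grid is None:
        t_grid = default_time_grid()

    def signed(p: float) -> float:
        return pressure_constancy(p, t_grid, burnin).signed_slope

    scores = np.array([signed(p) for p in p_grid])
    crossings = np.nonzero(np.sign(scores[:-1]) * np.sign(scores[1:]) <= 0)[0]
    if len(crossings) == 0:
        raise DomainError("no constant-pressure exponent bracketed in p_grid")
    k = crossings[0]
    if scores[k] == 0.0:
        return float(p_grid[k])
    return float(brentq(signed, p_grid[k], p_grid[k + 1], xtol=1e-8))


# ---------------------------------------------------------------------------
# Growth-curve classification and fitting
# ---------------------------------------------------------------------------

NO_OSCILLATION = "no-oscillation-expected"
OSCILLATION = "oscillation-expected"


def _sse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(((y - yhat) ** 2).sum())


def classify_growth(
    curve: GrowthCurve, tail_fraction: float = 0.5
) -> str:
    """Predict whether rupture-driven size oscillations are expected.

    The tail of the curve (the asymptotic regime) is fitted with three
    candidate growth families on the log scale: exponential ``N0*e^{r t}``,
    power law ``c*t^b`` and affine-linear ``a + b*t``.  Exponential growth is
    faster than quadratic, so it predicts no oscillations; a power law
    predicts none iff its exponent is at least 2; linear growth is slower
    than quadratic and predicts oscillations.
    """
    t, v = curve.times, curve.values
    keep = t > 0
    t, v = t[keep], v[keep]
    if len(t) < 5:
        raise DomainError("need at least 5 positive-time points to classify")
    k = max(len(t) - int(math.ceil(len(t) * tail_fraction)), 0)
    t, v = t[k:], v[k:]
    logv = np.log(v)
    logt = np.log(t)

    r, c_exp = np.polyfit(t, logv, 1)
    sse_exp = _sse(logv, r * t + c_exp)
    b, c_pow = np.polyfit(logt, logv, 1)
    sse_pow = _sse(logv, b * logt + c_pow)
    coef = np.polyfit(t, v, 1)
    lin = np.polyval(coef, t)
    sse_lin = _sse(logv, np.log(np.clip(lin, 1e-300, None)))

    best = min(
        ("exponential", sse_exp), ("power", sse_pow), ("linear", sse_lin),
        key=lambda kv: kv[1],
    )[0]
    if best == "exponential" and r > 0:
        return NO_OSCILLATION
    if best == "power":
        return NO_OSCILLATION if b >= 2.0 - 1e-9 else OSCILLATION
    if best == "exponential":  # decaying "exponential": slower than quadratic
        return OSCILLATION
    return OSCILLATION


@dataclass(frozen=True)
class PiecewiseExpLinearFit:
    """Continuous exponential-then-linear growth fit ``N0 e^{rt} -> linear``."""

    n0: float
    rate: float          # r, per hour
    t_star: float        # transition time, h
    slope: float         # m, cells per hour after the transition
    residual: float      # root-mean-square residual on the count scale

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = self.n0 * np.exp(self.rate * self.t_star)
        return np.where(
            t <= self.t_star,
            self.n0 * np.exp(self.rate * t),
            c + self.slope * (t - self.t_star),
        )


def fit_piecewise_exp_linear(
    curve: GrowthCurve, min_exp_points: int = 3
) -> PiecewiseExpLinearFit:
    """Least-squares piecewise exponential--linear fit of a cell-count curve.

    The transition time is selected over the observed time points (finer
    resolution is not identifiable at the 30-min sampling of the data).  The
    exponential branch is fitted by linear regression on log N; the linear
    continuation is constrained to be continuous at the transition.  For
    purely exponential data the transition lands on the final time point and
    the reported slope is the instantaneous slope there.
    """
    t, v = curve.times, curve.values
    if len(t) < 8:
        raise DomainError(f"need at least 8 points for a piecewise fit, got {len(t)}")

    best: tuple[float, PiecewiseExpLinearFit] | None = None
    # ties in the residual (e.g. noiseless exponential data) resolve to the
    # latest transition, so purely exponential curves report t* at the end
    tie_tol = 1e-12 * float((v**2).sum())
    for idx in range(min_exp_points - 1, len(t)):
        t_star = t[idx]
        te, ve = t[: idx + 1], v[: idx + 1]
        rate, logn0 = np.polyfit(te, np.log(ve), 1)
        n0 = math.exp(logn0)
        c = n0 * math.exp(rate * t_star)
        tl, vl = t[idx + 1 :], v[idx + 1 :]
        if len(tl):
            dt = tl - t_star
            slope = float((dt * (vl - c)).sum() / (dt * dt).sum())
        else:
            slope = n0 * rate * math.exp(rate * t_star)
        fit = PiecewiseExpLinearFit(n0, float(rate), float(t_star), slope, 0.0)
        sse = _sse(v, fit.predict(t))
        if best is None or sse <= best[0] + tie_tol:
            best = (min(sse, best[0]) if best else sse, fit)
    sse, fit = best
    return PiecewiseExpLinearFit(
        fit.n0, fit.rate, fit.t_star, fit.slope, math.sqrt(sse / len(t))
    )
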