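"""Modified Gompertz model: fitting and second-derivative-maximum location.

The amplification curve is modelled as

    y(x) = y0 + (ymax - y0) * exp(-exp(-(x - x0) / b))

with baseline ``y0``, plateau ``ymax``, inflection cycle ``x0`` and shape
parameter ``b > 0`` (cycles).  The model is fitted to *raw* fluorescence by
Levenberg-Marquardt least squares.

The second-derivative maximum (SDM) marks the end of the exponential phase.
Writing u = exp(-(x - x0)/b), the derivatives are

    y'  = (A/b)  * u * exp(-u)
    y'' = (A/b^2) * u * (u - 1) * exp(-u)        (A = ymax - y0)

y'' is maximal where u^2 - 3u + 1 = 0 on the u > 1 branch, i.e. at
u* = (3 + sqrt(5)) / 2.  Hence

    x_SDM = x0 - b * ln(u*)
    F_SDM = y0 + A * exp(-u*)

so the SDM always sits at the fixed amplitude fraction exp(-u*) ~ 7.295% of
the rise, ln(u*) ~ 0.9624 shape units before the inflection.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import least_squares

from .errors import NoAmplificationError, ParameterError, StateError
from .io import AmplificationCurve

#: Root of u^2 - 3u + 1 = 0 on the accelerating branch (u > 1).
U_STAR: float = (3.0 + math.sqrt(5.0)) / 2.0

#: (F_SDM - y0) / (ymax - y0), an absolute constant of the Gompertz family.
SDM_AMPLITUDE_FRACTION: float = math.exp(-U_STAR)

_LOG_U_STAR: float = math.log(U_STAR)

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 200
DEFAULT_FLOOR_MULTIPLIER = 5.0


@dataclasses.dataclass(frozen=True)
class GompertzFit:
    """Fitted Gompertz parameters and diagnostics for one curve."""

    y0: float
    ymax: float
    b: float
    x0: float
    rss: float = 0.0
    n_iter: int = 0
    converged: bool = False

    @property
    def amplitude(self) -> float:
        return self.ymax - self.y0


@dataclasses.dataclass(frozen=True)
class SdmPoint:
    """Cycle and model fluorescence at the second-derivative maximum."""

    x_sdm: float
    f_sdm: float


def _model(x, y0, ymax, b, x0):
    with np.errstate(over="ignore"):
        return y0 + (ymax - y0) * np.exp(-np.exp(-(np.asarray(x, dtype=float) - x0) / b))


def gompertz_value(fit, x):
    """Evaluate the Gompertz model at cycle(s) ``x``.

    ``fit`` may be a :class:`GompertzFit` or any object with attributes
    ``y0, ymax, b, x0``.  Returns a scalar for scalar ``x``.
    """
    if fit.b <= 0:
        raise ParameterError(f"shape parameter b must be positive, got {fit.b}")
    y = _model(x, fit.y0, fit.ymax, fit.b, fit.x0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(y)
    return y


def _first_crossing(cycles: np.ndarray, fluor: np.ndarray, level: float) -> float:
    above = fluor >= level
    if not above.any():
        return float(cycles[-1])
    return float(cycles[int(np.argmax(above))])


def _initial_params(cycles: np.ndarray, fluor: np.ndarray) -> tuple[float, float, float, float]:
    # Deterministic, derivative-free starting point: baseline from the three
    # lowest observations, plateau from the maximum, x0 from the half-rise
    # crossing, b from the quartile-crossing span (floored at 0.5 cycles).
    y0 = float(np.mean(np.sort(fluor)[:3]))
    ymax = float(np.max(fluor))
    amp = ymax - y0
    if amp <= 0:
        raise NoAmplificationError("flat curve: no amplitude above baseline")
    x0 = _first_crossing(cycles, fluor, y0 + 0.5 * amp)
    x25 = _first_crossing(cycles, fluor, y0 + 0.25 * amp)
    x75 = _first_crossing(cycles, fluor, y0 + 0.75 * amp)
    b = max((x75 - x25) / 2.0, 0.5)
    return y0, ymax, b, x0


def fit_gompertz(
    curve: AmplificationCurve,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    amplitude_floor_multiplier: float = DEFAULT_FLOOR_MULTIPLIER,
) -> GompertzFit:
    """Fit the Gompertz model to raw fluorescence of one curve.

    Raises :class:`NoAmplificationError` for flat/noise-only curves: either
    the optimizer fails, or the fitted amplitude falls below
    ``amplitude_floor_multiplier`` times the residual standard deviation of
    the first five cycles (noise-only curves have no amplitude that noise
    could not explain).
    """
    cycles = np.asarray(curve.cycles, dtype=float)
    fluor = np.asarray(curve.fluorescence, dtype=float)

    y0_i, ymax_i, b_i, x0_i = _initial_params(cycles, fluor)
    p0 = np.array([y0_i, ymax_i, math.log(b_i), x0_i])

    def resid(p):
        y0, ymax, logb, x0 = p
        return _model(cycles, y0, ymax, math.exp(logb), x0) - fluor

    def jac(p):
        y0, ymax, logb, x0 = p
        b = math.exp(logb)
        # exponent clipped so u stays finite; w underflows to 0 there anyway
        u = np.exp(np.clip(-(cycles - x0) / b, None, 500.0))
        w = np.exp(-u)
        amp = ymax - y0
        return np.column_stack(
            [
                1.0 - w,                       # d/dy0
                w,                             # d/dymax
                -amp * w * u * (cycles - x0) / b,  # d/dlogb
                -amp * w * u / b,              # d/dx0
            ]
        )

    # b is fitted on the log scale to keep it positive along the LM path.
    try:
        res = least_squares(
            resid, p0, jac=jac, method="lm",
            ftol=tol, xtol=tol, gtol=tol,
            max_nfev=max_iter * (p0.size + 1),
        )
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise NoAmplificationError(f"fit failed: {exc}") from exc

    y0, ymax, logb, x0 = res.x
    b = math.exp(logb)
    fit = GompertzFit(
        y0=float(y0), ymax=float(ymax), b=float(b), x0=float(x0),
        rss=float(2.0 * res.cost), n_iter=int(res.nfev),
        converged=bool(res.success),
    )
    if not fit.converged:
        raise NoAmplificationError("fit did not converge")
    if fit.amplitude <= 0:
        raise NoAmplificationError("fitted amplitude is not positive")

    head = slice(0, 5)
    resid_head = fluor[head] - _model(cycles[head], fit.y0, fit.ymax, fit.b, fit.x0)
    noise_sd = float(np.std(resid_head, ddof=1))
    floor = amplitude_floor_multiplier * noise_sd
    if fit.amplitude < floor or fit.amplitude < 1e-12 * max(1.0, abs(fit.ymax)):
        raise NoAmplificationError(
            f"fitted amplitude {fit.amplitude:.3g} below no-amplification floor {floor:.3g}"
        )
    # The exponential phase must actually be observed: noise-chasing fits on
    # flat wells like to park the whole rise outside the cycle range.
    x_sdm = fit.x0 - fit.b * _LOG_U_STAR
    if x_sdm < cycles[0] or fit.x0 > cycles[-1]:
        raise NoAmplificationError(
            f"fitted rise (x_sdm={x_sdm:.2f}, x0={fit.x0:.2f}) lies outside "
            f"the observed cycles [{cycles[0]:.0f}, {cycles[-1]:.0f}]"
        )
    return fit


def sdm_location(fit: GompertzFit) -> SdmPoint:
    """Closed-form second-derivative maximum of a converged fit."""
    if not fit.converged:
        raise StateError("sdm_location requires a converged fit")
    if fit.b <= 0 or fit.ymax <= fit.y0:
        raise ParameterError("sdm_location requires b > 0 and ymax > y0")
    x_sdm = fit.x0 - fit.b * _LOG_U_STAR
    f_sdm = fit.y0 + fit.amplitude * SDM_AMPLITUDE_FRACTION
    return SdmPoint(x_sdm=float(x_sdm), f_sdm=float(f_sdm))


def second_derivative(fit, x):
    """Analytic second derivative of the model (used by oracle tests)."""
    if fit.b <= 0:
        raise ParameterError("b must be positive")
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        u = np.exp(-(x - fit.x0) / fit.b)
        out = (fit.ymax - fit.y0) / fit.b**2 * u * (u - 1.0) * np.exp(-u)
    return out
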