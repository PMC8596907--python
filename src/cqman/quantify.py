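"""Quantification core: Fq, Cq, per-reaction efficiency and F0.

Pipeline per curve (all on raw fluorescence):

1. fit the Gompertz model;
2. locate the second-derivative maximum (x_SDM, F_SDM) in closed form;
3. set the quantification threshold at the midpoint Fq = (y0 + F_SDM)/2;
4. invert the model analytically to get the quantification cycle
   Cq = x0 - b * ln(-ln((Fq - y0)/(ymax - y0)));
5. fit the three-parameter exponential F_n = offset + alpha * E^n over the
   integer cycles of the exponential phase (ending at floor(x_SDM), extended
   backwards to at least ``min_points`` cycles) to get the reaction's
   individual efficiency E;

then per gene: average the usable individual efficiencies, and back-calculate
each reaction's observed initial target quantity F0 = E_mean ** (-Cq).

A fixed geometry follows from the midpoint threshold: Cq always sits
b * ln(1 + ln(2)/u*) ~ 0.2349*b cycles before x_SDM, i.e. safely inside the
exponential phase, without any baseline-phase estimation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, EfficiencyError, ParameterError
from .errors import NoAmplificationError
from .gompertz import (
    GompertzFit,
    SdmPoint,
    U_STAR,
    fit_gompertz,
    gompertz_value,
    sdm_location,
)
from .io import PlateData, RESULT_COLUMNS

logger = logging.getLogger(__name__)

#: (x_SDM - Cq) / b, a constant of the midpoint-threshold construction.
CQ_SDM_SPAN_COEFF: float = math.log(1.0 + math.log(2.0) / U_STAR)

STATUS_OK = "ok"
STATUS_NO_AMPLIFICATION = "no_amplification"
STATUS_EFFICIENCY_FAILED = "efficiency_failed"


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the quantification pipeline.

    ``min_points`` defaults to 6: with the free offset of the exponential
    model, 4-point windows leave a single residual degree of freedom and the
    efficiency estimate becomes ill-conditioned under realistic noise; two
    extra baseline-side cycles anchor the offset at negligible cost on clean
    data.
    """

    min_points: int = 6
    e_bounds: tuple[float, float] = (1.0, 3.0)
    tol: float = 1e-10
    max_iter: int = 200
    amplitude_floor_multiplier: float = 5.0


@dataclasses.dataclass
class QuantResult:
    """Per-curve quantification outcome (NaN marks unavailable fields)."""

    well_id: str
    gene: str
    y0: float = math.nan
    ymax: float = math.nan
    b: float = math.nan
    x0: float = math.nan
    x_sdm: float = math.nan
    f_sdm: float = math.nan
    fq: float = math.nan
    cq: float = math.nan
    e_individual: float = math.nan
    e_mean: float = math.nan
    f0: float = math.nan
    status: str = STATUS_OK


@dataclasses.dataclass(frozen=True)
class EfficiencyFit:
    """Three-parameter exponential fit over the exponential-phase window."""

    offset: float
    alpha: float
    e: float
    window_cycles: tuple[int, ...]
    rss: float


def quantification_threshold(fit: GompertzFit, sdm: SdmPoint) -> float:
    """Midpoint threshold Fq = (y0 + F_SDM) / 2."""
    return (fit.y0 + sdm.f_sdm) / 2.0


def quantification_cycle(fit: GompertzFit, fq: float) -> float:
    """Fractional cycle at which the fitted model crosses ``fq``.

    Analytic inversion of the Gompertz model; raises :class:`DomainError`
    unless y0 < fq < ymax.
    """
    if fit.b <= 0:
        raise ParameterError("b must be positive")
    if not (fit.y0 < fq < fit.ymax):
        raise DomainError(
            f"threshold {fq} outside open interval (y0={fit.y0}, ymax={fit.ymax})"
        )
    z = (fq - fit.y0) / (fit.ymax - fit.y0)
    return float(fit.x0 - fit.b * math.log(-math.log(z)))


def exponential_window(
    cq: float, x_sdm: float, n_cycles: int, min_points: int = 4
) -> list[int]:
    """Integer cycles of the exponential phase used for the efficiency fit.

    Starts from [ceil(cq), floor(x_sdm)] and extends backwards one cycle at
    a time (never below cycle 1, never past x_sdm) until at least
    ``min_points`` cycles are included.
    """
    if min_points < 4:
        raise ParameterError("min_points must be >= 4")
    if not cq < x_sdm:
        raise DomainError(f"cq ({cq}) must precede x_sdm ({x_sdm})")
    end = min(int(math.floor(x_sdm)), int(n_cycles))
    if end < 1:
        raise EfficiencyError("exponential phase ends before cycle 1")
    start = int(math.ceil(cq))
    window = [c for c in range(max(start, 1), end + 1)]
    if not window:
        window = [end]
    while len(window) < min_points and window[0] > 1:
        window.insert(0, window[0] - 1)
    if len(window) < min_points:
        raise EfficiencyError(
            f"cannot collect {min_points} cycles in [1, {end}] for efficiency fit"
        )
    return window


def fit_individual_efficiency(
    curve,
    window: Sequence[int],
    e_bounds: tuple[float, float] = (1.0, 3.0),
) -> EfficiencyFit:
    """Fit F_n = offset + alpha * E^n over ``window`` by nonlinear least squares.

    Estimates at (or numerically against) the efficiency bounds, and
    degenerate windows, raise :class:`EfficiencyError`; such reactions are
    excluded from the gene-mean efficiency rather than clipped into it.
    """
    window = np.asarray(window, dtype=int)
    if window.size < 4:
        raise EfficiencyError("efficiency window needs at least 4 cycles")
    if window.min() < 1 or window.max() > curve.n_cycles:
        raise ParameterError("efficiency window outside curve cycles")
    n = window.astype(float)
    f = np.asarray(curve.fluorescence, dtype=float)[window - 1]
    spread = float(np.ptp(f))
    if spread <= 0:
        raise EfficiencyError("constant fluorescence in efficiency window")

    e_lo, e_hi = e_bounds
    # Log-linear warm start after a small offset guess below the window minimum.
    offset0 = float(f.min()) - 0.05 * spread
    g = f - offset0
    slope, intercept = np.polyfit(n, np.log(g), 1)
    e0 = float(np.clip(math.exp(slope), e_lo + 0.05, e_hi - 0.05))
    la0 = float(intercept)

    def resid(p):
        offset, log_alpha, e = p
        return offset + np.exp(log_alpha) * e**n - f

    def jac(p):
        _, log_alpha, e = p
        g = np.exp(log_alpha) * e**n
        return np.column_stack([np.ones_like(n), g, g * n / e])

    res = least_squares(
        resid,
        x0=np.array([offset0, la0, e0]),
        jac=jac,
        bounds=([-np.inf, -np.inf, e_lo], [np.inf, np.inf, e_hi]),
        method="trf",
        ftol=1e-13, xtol=1e-13, gtol=1e-13,
    )
    if not res.success:
        raise EfficiencyError("efficiency fit did not converge")
    offset, log_alpha, e = res.x
    if e <= e_lo + 1e-6 or e >= e_hi - 1e-6:
        raise EfficiencyError(f"efficiency estimate {e:.4f} at bound {e_bounds}")
    return EfficiencyFit(
        offset=float(offset),
        alpha=float(math.exp(log_alpha)),
        e=float(e),
        window_cycles=tuple(int(c) for c in window),
        rss=float(2.0 * res.cost),
    )


def group_mean_efficiency(results: Iterable) -> float:
    """Arithmetic mean of the usable individual efficiencies of one gene.

    Accepts QuantResults (failed ones are skipped) or plain floats.
    """
    values = []
    for r in results:
        e = r.e_individual if isinstance(r, QuantResult) else r
        if e is not None and np.isfinite(e):
            values.append(float(e))
    if not values:
        raise EfficiencyError("no usable individual efficiencies in group")
    return float(np.mean(values))


def initial_target_quantity(cq: float, e_mean: float) -> float:
    """Observed initial target quantity F0 = E_mean ** (-Cq)."""
    if not e_mean > 1.0:
        raise DomainError(f"mean efficiency must exceed 1, got {e_mean}")
    if not np.isfinite(cq):
        raise DomainError("cq must be finite")
    return float(e_mean ** (-cq))


def analyze_plate(
    plate: PlateData, config: AnalysisConfig | None = None
) -> list[QuantResult]:
    """Run the full quantification pipeline on every curve of a plate.

    Per-curve failures are recorded in ``status`` and never abort the plate.
    Deterministic: identical plate + config give identical results.
    """
    cfg = config or AnalysisConfig()
    results: list[QuantResult] = []

    for curve in plate:
        r = QuantResult(well_id=curve.well_id, gene=curve.gene)
        try:
            fit = fit_gompertz(
                curve,
                tol=cfg.tol,
                max_iter=cfg.max_iter,
                amplitude_floor_multiplier=cfg.amplitude_floor_multiplier,
            )
        except NoAmplificationError as exc:
            r.status = STATUS_NO_AMPLIFICATION
            logger.debug("well %s: no amplification (%s)", curve.well_id, exc)
            results.append(r)
            continue

        sdm = sdm_location(fit)
        r.y0, r.ymax, r.b, r.x0 = fit.y0, fit.ymax, fit.b, fit.x0
        r.x_sdm, r.f_sdm = sdm.x_sdm, sdm.f_sdm
        r.fq = quantification_threshold(fit, sdm)
        r.cq = quantification_cycle(fit, r.fq)
        try:
            window = exponential_window(
                r.cq, r.x_sdm, curve.n_cycles, min_points=cfg.min_points
            )
            eff = fit_individual_efficiency(curve, window, e_bounds=cfg.e_bounds)
            r.e_individual = eff.e
            logger.debug(
                "well %s: rss=%.3g nfev=%d cq=%.3f e=%.4f window=%s",
                curve.well_id, fit.rss, fit.n_iter, r.cq, eff.e, eff.window_cycles,
            )
        except (EfficiencyError, DomainError) as exc:
            r.status = STATUS_EFFICIENCY_FAILED
            logger.debug("well %s: efficiency failed (%s)", curve.well_id, exc)
        results.append(r)

    # Gene-level mean efficiency and F0 back-calculation.
    by_gene: dict[str, list[QuantResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    for gene, group in by_gene.items():
        try:
            e_mean = group_mean_efficiency(group)
        except EfficiencyError:
            for r in group:
                if r.status == STATUS_OK:
                    r.status = STATUS_EFFICIENCY_FAILED
            continue
        for r in group:
            if np.isfinite(r.cq):
                r.e_mean = e_mean
                r.f0 = initial_target_quantity(r.cq, e_mean)
    return results


def results_to_frame(results: Iterable[QuantResult]) -> pd.DataFrame:
    """Tabulate QuantResults in the fixed results-CSV column order."""
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return df[RESULT_COLUMNS + ["f_sdm"]]


__all__ = [
    "AnalysisConfig",
    "QuantResult",
    "EfficiencyFit",
    "CQ_SDM_SPAN_COEFF",
    "quantification_threshold",
    "quantification_cycle",
    "exponential_window",
    "fit_individual_efficiency",
    "group_mean_efficiency",
    "initial_target_quantity",
    "analyze_plate",
    "results_to_frame",
    "STATUS_OK",
    "STATUS_NO_AMPLIFICATION",
    "STATUS_EFFICIENCY_FAILED",
]
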