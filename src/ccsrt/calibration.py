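"""Prediction-error statistics and tolerance-window derivation.

The annotation filter needs, for each predicted property (CCS in Å², Rt in
min), a tolerance window beyond which a feature/candidate discrepancy is
treated as a false positive. The window is derived from a validation set of
paired (predicted, measured) values as

    tolerance = MAE + k * SD,   k = 2 by default,

where MAE is the mean absolute error and SD the sample standard deviation
(n-1 denominator) of the signed errors (predicted - measured). An alternative
centering on the signed mean error instead of the MAE is available via
``use_signed_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError


@dataclass
class CalibrationResult:
    """Linear agreement + error statistics + derived tolerance for one property."""

    property: str  # "ccs" | "rt"
    slope: float
    intercept: float
    r2: float
    mae: float
    sd_error: float
    sd_error_relative: float  # percent, relative to mean(measured)
    tolerance: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def fit_linear_calibration(predicted, measured) -> tuple[float, float, float]:
    """OLS of predicted on measured: predicted ~= slope * measured + intercept.

    Returns (slope, intercept, r2) where r2 is the coefficient of
    determination of the fit.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured must have equal length")
    n = predicted.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points for a calibration line, got {n}")
    if np.ptp(measured) == 0:
        raise DegenerateInputError("measured vector is constant; regression undefined")
    mx, my = measured.mean(), predicted.mean()
    sxx = float(np.sum((measured - mx) ** 2))
    sxy = float(np.sum((measured - mx) * (predicted - my)))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = predicted - (slope * measured + intercept)
    sst = float(np.sum((predicted - my) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return slope, intercept, r2


def error_stats(predicted, measured) -> tuple[float, float, float]:
    """(MAE, SD of signed error, SD as percent of mean measured).

    SD uses the n-1 denominator. The relative SD is expressed against the
    mean of the measured values (an assumption, flagged in reports, since a
    percent band has no unique denominator).
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured must have equal length")
    if predicted.size < 2:
        raise InsufficientDataError("need >= 2 points for error statistics")
    err = predicted - measured
    mae = float(np.mean(np.abs(err)))
    sd = float(np.std(err, ddof=1))
    rel = 100.0 * sd / float(np.mean(measured))
    return mae, sd, rel


def derive_tolerance(mae: float, sd_error: float, k: float = 2.0) -> float:
    """Matching tolerance = MAE + k * SD (same units as the property)."""
    if mae < 0 or sd_error < 0:
        raise ValueError("mae and sd_error must be non-negative")
    if k <= 0:
        raise ValueError("k must be positive")
    return mae + k * sd_error


def relative_band(sd_error_relative: float, k: float = 2.0) -> float:
    """Percent half-width of the +/- k SD band around the best-fit line."""
    if sd_error_relative < 0:
        raise ValueError("relative SD must be non-negative")
    return k * sd_error_relative


def calibrate(
    predicted,
    measured,
    property: str = "ccs",
    k: float = 2.0,
    use_signed_mean: bool = False,
) -> CalibrationResult:
    """Full calibration: line fit, error stats, and the tolerance window.

    ``use_signed_mean=True`` centers the window on |mean signed error| instead
    of the MAE (the two coincide when all errors share a sign).
    """
    slope, intercept, r2 = fit_linear_calibration(predicted, measured)
    mae, sd, rel = error_stats(predicted, measured)
    center = abs(float(np.mean(np.asarray(predicted) - np.asarray(measured)))) if use_signed_mean else mae
    tol = derive_tolerance(center, sd, k)
    return CalibrationResult(
        property=property,
        slope=slope,
        intercept=intercept,
        r2=r2,
        mae=mae,
        sd_error=sd,
        sd_error_relative=rel,
        tolerance=tol,
        n=int(np.asarray(predicted).size),
    )


def rt_tolerance_from_cv(mean_mae: float, sd_mae: float, k: float = 2.0) -> float:
    """Rt tolerance from cross-validation summaries.

    For retention time the tolerance inputs are the CV mean MAE and the SD of
    the per-fold MAE (rather than per-compound residual SD), since the CV
    statistics are what characterize prediction error on unseen compounds.
    """
    return derive_tolerance(mean_mae, sd_mae, k)
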