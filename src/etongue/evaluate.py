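"""Analytical-performance statistics for sensor calibration and model
validation.

Covers the figures of merit customary in quantitative electroanalysis:
univariate calibration lines with LOD = 3·s_yx/slope, predicted-vs-
expected comparison regressions with joint (elliptical) confidence
regions for slope and intercept, RMSE/NRMSE summaries, and repeatability
as percent relative standard deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import ValidationError, Voltammogram

__all__ = [
    "CalibrationFit",
    "RegressionComparison",
    "EjcrResult",
    "peak_height",
    "fit_calibration",
    "compare_regression",
    "ejcr_contains",
    "nrmse",
    "repeatability_rsd",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Univariate calibration line of peak height vs. concentration.

    ``lod_uM`` is 3·s_yx/slope (three times the standard error of the
    regression over the slope); it is NaN when the slope is not positive.
    """

    slope: float  # µA/µM
    intercept: float  # µA
    r_squared: float
    s_yx: float  # standard error of the regression, µA
    lod_uM: float
    conc_range_uM: tuple[float, float]
    n: int
    analyte: str = ""
    sensor_id: str = ""


@dataclass(frozen=True)
class RegressionComparison:
    """OLS of predicted (y) on expected (x) concentrations.

    Half-confidence intervals use the t distribution with n-2 df.  RMSE
    is the prediction error against the identity line (not the regression
    residual).  ``sum_x``/``sum_x2`` are retained because the joint
    slope-intercept confidence ellipse is parameterized by them.
    """

    slope: float
    slope_half_ci: float
    intercept: float
    intercept_half_ci: float
    r_squared: float
    rmse: float
    s2: float  # residual variance SSE/(n-2)
    sum_x: float
    sum_x2: float
    n: int
    confidence: float
    contains_ideal: bool  # (slope, intercept) = (1, 0) inside the EJCR
    analyte: str = ""
    subset: str = ""


@dataclass(frozen=True)
class EjcrResult:
    """Outcome of a joint slope-intercept confidence-region test."""

    inside: bool
    quadratic: float
    threshold: float
    confidence: float


def peak_height(v: Voltammogram, blank: Voltammogram | None = None) -> float:
    """Maximum (blank-subtracted) current of a trace, in µA."""
    if len(v) == 0:
        raise ValidationError("empty trace")
    net = v.currents
    if blank is not None:
        if not np.array_equal(v.potentials, blank.potentials):
            raise ValidationError(
                f"blank potential grid does not match sensor {v.sensor_id!r}"
            )
        net = net - blank.currents
    return float(np.max(net))


def fit_calibration(
    concentrations: np.ndarray,
    heights: np.ndarray,
    analyte: str = "",
    sensor_id: str = "",
) -> CalibrationFit:
    """Ordinary least-squares calibration line with LOD from s_yx."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(heights, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("calibration needs >= 3 matched points")
    if np.unique(x).size < 2:
        raise ValidationError("calibration needs >= 2 distinct concentrations")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    sse = float(np.sum((y - yhat) ** 2))
    s_yx = float(np.sqrt(sse / (x.size - 2)))
    lod = 3.0 * s_yx / res.slope if res.slope > 0 else float("nan")
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        s_yx=s_yx,
        lod_uM=float(lod),
        conc_range_uM=(float(x.min()), float(x.max())),
        n=int(x.size),
        analyte=analyte,
        sensor_id=sensor_id,
    )


def compare_regression(
    expected: np.ndarray,
    predicted: np.ndarray,
    confidence: float = 0.95,
    analyte: str = "",
    subset: str = "",
) -> RegressionComparison:
    """Predicted-vs-expected comparison regression with joint-region test."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("comparison needs >= 3 matched points")
    if np.std(x) == 0:
        raise ValidationError("expected values have zero variance")
    if not 0 < confidence < 1:
        raise ValidationError(f"confidence must be in (0, 1), got {confidence}")
    n = x.size
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    sse = float(np.sum((y - yhat) ** 2))
    s2 = sse / (n - 2)
    tval = stats.t.ppf(0.5 * (1 + confidence), df=n - 2)
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    rc = RegressionComparison(
        slope=float(res.slope),
        slope_half_ci=float(tval * res.stderr),
        intercept=float(res.intercept),
        intercept_half_ci=float(tval * res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        rmse=rmse,
        s2=float(s2),
        sum_x=float(np.sum(x)),
        sum_x2=float(np.sum(x**2)),
        n=int(n),
        confidence=confidence,
        contains_ideal=False,
        analyte=analyte,
        subset=subset,
    )
    if n >= 4:
        inside = ejcr_contains(rc, (1.0, 0.0), confidence).inside
        rc = dataclasses.replace(rc, contains_ideal=inside)
    return rc


def ejcr_contains(
    rc: RegressionComparison,
    point: tuple[float, float] = (1.0, 0.0),
    confidence: float | None = None,
) -> EjcrResult:
    """Test whether ``point = (slope0, intercept0)`` lies inside the
    elliptical joint confidence region of the comparison regression.

    The region is the classical two-parameter set

        n(a - a0)^2 + 2 Σx (a - a0)(b - b0) + Σx² (b - b0)^2
            <= 2 s² F_{2, n-2}(confidence)

    with ``a`` the intercept and ``b`` the slope.  When ``s² = 0`` the
    region degenerates to the single point of the estimates.
    """
    if rc.n < 4:
        raise ValidationError("EJCR needs n >= 4")
    confidence = rc.confidence if confidence is None else confidence
    if not 0 < confidence < 1:
        raise ValidationError(f"confidence must be in (0, 1), got {confidence}")
    slope0, intercept0 = point
    da = rc.intercept - intercept0
    db = rc.slope - slope0
    quad = rc.n * da**2 + 2.0 * rc.sum_x * da * db + rc.sum_x2 * db**2
    threshold = 2.0 * rc.s2 * stats.f.ppf(confidence, 2, rc.n - 2)
    if rc.s2 == 0.0:
        inside = bool(np.isclose(quad, 0.0, atol=1e-12))
    else:
        inside = bool(quad <= threshold)
    return EjcrResult(
        inside=inside, quadratic=float(quad), threshold=float(threshold),
        confidence=confidence,
    )


def nrmse(
    expected: np.ndarray, predicted: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-analyte RMSE vector and the global normalized RMSE.

    NRMSE = sqrt( Σ (ŷ - x)² / Σ x² ) over all samples and analytes,
    a single scale-free figure of merit across analytes with very
    different concentration ranges.
    """
    x = np.atleast_2d(np.asarray(expected, dtype=float))
    y = np.atleast_2d(np.asarray(predicted, dtype=float))
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    denom = float(np.sum(x**2))
    if denom == 0.0:
        raise ValidationError("NRMSE undefined: expected values are all zero")
    per_analyte = np.sqrt(np.mean((y - x) ** 2, axis=0))
    total = float(np.sqrt(np.sum((y - x) ** 2) / denom))
    return per_analyte, total


def repeatability_rsd(values: np.ndarray) -> float:
    """Percent relative standard deviation (sample sd over mean) of
    repeated measurements."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("RSD needs >= 2 values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ValidationError("RSD undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean
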