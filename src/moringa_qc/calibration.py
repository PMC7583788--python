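"""Ordinary least-squares calibration, linearity, LOD/LOQ and inverse prediction.

Calibration follows the external-standard construction: replicate peak
areas are averaged per concentration level and an unweighted straight
line is fitted to the (level, mean response) points. Detection and
quantification limits scale the regression noise estimate by 3 and 10
and divide by the slope, so LOQ/LOD = 10/3 whenever both use the same
σ estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CalibrationCurve
from .errors import DegenerateDesignError, InsufficientDataError, InvalidCurveError, ValidationError


@dataclass(frozen=True)
class LodLoqPolicy:
    """How detection/quantification limits are derived from a fitted line.

    ``sigma_estimator`` selects the noise term: ``residual_sd`` uses the
    residual standard deviation of the level means about the line;
    ``intercept_sd`` uses the standard error of the fitted intercept
    (the ISO 11843-style variant).
    """

    lod_multiplier: float = 3.0
    loq_multiplier: float = 10.0
    sigma_estimator: str = "residual_sd"

    def __post_init__(self) -> None:
        if not (self.loq_multiplier > self.lod_multiplier > 0):
            raise ValidationError("need loq_multiplier > lod_multiplier > 0")
        if self.sigma_estimator not in ("residual_sd", "intercept_sd"):
            raise ValidationError(f"unknown sigma_estimator {self.sigma_estimator!r}")


def _level_means(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    means = frame.groupby("level")["response"].mean().sort_index()
    return means.index.to_numpy(dtype=float), means.to_numpy(dtype=float)


def fit_calibration(
    frame: pd.DataFrame,
    *,
    compound_id: int | None = None,
    medium: str | None = None,
    policy: LodLoqPolicy | None = None,
) -> CalibrationCurve:
    """Fit a calibration line to one compound × medium replicate slice.

    ``frame`` needs ``level`` and ``response`` columns; replicates at each
    level are averaged before the fit. r² is the squared Pearson
    correlation between level means and fitted values. If ``policy`` is
    given, LOD/LOQ are attached to the returned curve.
    """
    if compound_id is None:
        compound_id = int(frame["compound"].iloc[0]) if "compound" in frame else -1
    if medium is None:
        medium = str(frame["medium"].iloc[0]) if "medium" in frame else ""

    x, y = _level_means(frame)
    if len(x) < 3:
        raise InsufficientDataError(f"need ≥ 3 distinct levels, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all levels identical; slope is undefined")

    fit = stats.linregress(x, y)
    fitted = fit.intercept + fit.slope * x
    resid = y - fitted
    dof = len(x) - 2
    s_residual = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    r_squared = float(fit.rvalue**2)

    curve = CalibrationCurve(
        compound_id=compound_id,
        medium=medium,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        s_residual=s_residual,
        n_levels=len(x),
    )
    if policy is not None:
        curve.lod, curve.loq = lod_loq(curve, policy, _design_x=x)
    return curve


def _sigma(curve: CalibrationCurve, policy: LodLoqPolicy, design_x: np.ndarray | None) -> float:
    if policy.sigma_estimator == "residual_sd":
        return curve.s_residual
    # intercept_sd: SE of the intercept from the calibration design
    if design_x is None:
        raise ValidationError("intercept_sd estimator needs the calibration levels")
    n = len(design_x)
    sxx = float(np.sum((design_x - design_x.mean()) ** 2))
    return curve.s_residual * math.sqrt(1.0 / n + design_x.mean() ** 2 / sxx)


def lod_loq(
    curve: CalibrationCurve,
    policy: LodLoqPolicy = LodLoqPolicy(),
    *,
    _design_x: np.ndarray | None = None,
) -> tuple[float, float]:
    """Detection/quantification limits: multiplier · σ / slope.

    A zero σ (noiseless fit) yields the degenerate pair (0, 0).
    """
    if not (curve.slope > 0):
        raise InvalidCurveError(f"slope must be positive, got {curve.slope}")
    sigma = _sigma(curve, policy, _design_x)
    if sigma < 0 or not np.isfinite(sigma):
        raise ValidationError(f"invalid σ estimate {sigma}")
    return (
        policy.lod_multiplier * sigma / curve.slope,
        policy.loq_multiplier * sigma / curve.slope,
    )


def inverse_predict(curve: CalibrationCurve, response: float) -> float:
    """Concentration read back from a peak area: (response − intercept)/slope."""
    if curve.slope == 0:
        raise InvalidCurveError("slope is zero; inverse prediction undefined")
    return (response - curve.intercept) / curve.slope


def curve_summary_frame(curves: list[CalibrationCurve]) -> pd.DataFrame:
    """Per-curve summary mirroring the published regression-table columns."""
    return pd.DataFrame(
        {
            "compound": [c.compound_id for c in curves],
            "medium": [c.medium for c in curves],
            "slope": [c.slope for c in curves],
            "intercept": [c.intercept for c in curves],
            "r_squared": [c.r_squared for c in curves],
            "lod": [c.lod for c in curves],
            "loq": [c.loq for c in curves],
        }
    )
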