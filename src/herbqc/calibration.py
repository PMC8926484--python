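"""Log-log linear calibration of detector response against injected mass.

The detector response of each marker follows a power law over its linear
range, so ordinary least squares is fitted in natural-log space:
``ln(area) = intercept + slope * ln(mass)``, mass in µg.  R² is the squared
Pearson correlation of the ln-transformed points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-marker regression of ln(area) on ln(injected mass)."""

    marker: str
    slope: float
    intercept: float
    r2: float
    range_ug: tuple[float, float]   # (low, high) injected mass, µg

    def __post_init__(self) -> None:
        low, high = self.range_ug
        if not low < high:
            raise DomainError(f"curve {self.marker}: range low must be < high")


class RangeWarning(UserWarning):
    """Prediction requested outside the calibrated linear range."""


def fit_curve(
    masses: Sequence[float],
    areas: Sequence[float],
    marker: str = "",
) -> CalibrationCurve:
    """Fit the log-log calibration line by ordinary least squares.

    Requires at least three points, all masses and areas strictly positive.
    The reported range is (min mass, max mass) of the fitted points.
    """
    masses = np.asarray(masses, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if masses.shape != areas.shape or masses.ndim != 1:
        raise DomainError("masses and areas must be 1-D and of equal length")
    if masses.size < 3:
        raise InsufficientDataError(f"need >= 3 calibration points, got {masses.size}")
    if np.any(masses <= 0) or np.any(areas <= 0):
        raise DomainError("all masses and areas must be > 0")
    x, y = np.log(masses), np.log(areas)
    res = stats.linregress(x, y)
    return CalibrationCurve(
        marker=marker,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        range_ug=(float(masses.min()), float(masses.max())),
    )


def predict_area(curve: CalibrationCurve, mass: float) -> float:
    """Predicted detector area for an injected mass (µg).

    Warns (does not error) when the mass falls outside the calibrated range.
    """
    if not mass > 0:
        raise DomainError(f"mass must be > 0, got {mass}")
    low, high = curve.range_ug
    if not low <= mass <= high:
        warnings.warn(
            f"mass {mass} µg outside linear range {curve.range_ug} of {curve.marker}",
            RangeWarning,
            stacklevel=2,
        )
    return float(np.exp(curve.intercept + curve.slope * np.log(mass)))


def invert_area(curve: CalibrationCurve, area: float) -> float:
    """Injected mass (µg) implied by a detector area; inverse of predict_area."""
    if not area > 0:
        raise DomainError(f"area must be > 0, got {area}")
    return float(np.exp((np.log(area) - curve.intercept) / curve.slope))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def curves_to_frame(curves: Sequence[CalibrationCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": [c.marker for c in curves],
            "slope": [c.slope for c in curves],
            "intercept": [c.intercept for c in curves],
            "r2": [c.r2 for c in curves],
            "range_low_ug": [c.range_ug[0] for c in curves],
            "range_high_ug": [c.range_ug[1] for c in curves],
        }
    )


def write_curves(curves: Sequence[CalibrationCurve], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[CalibrationCurve]:
    df = pd.read_csv(path)
    return [
        CalibrationCurve(
            marker=str(r["marker"]),
            slope=float(r["slope"]),
            intercept=float(r["intercept"]),
            r2=float(r["r2"]),
            range_ug=(float(r["range_low_ug"]), float(r["range_high_ug"])),
        )
        for _, r in df.iterrows()
    ]
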