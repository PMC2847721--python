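"""Standard-curve calibration of amplification efficiency.

A dilution series regresses Cq against log10 of the relative template input.
For a perfectly doubling reaction each 10-fold dilution costs log2(10) =
3.3219 cycles, so the slope of the regression is -3.3219 and the per-cycle
amplification factor is exactly 2.  In general

    amplification factor = 10**(-1/slope)
    efficiency (%)       = (10**(-1/slope) - 1) * 100

A slope of -3.27 therefore corresponds to a factor of 2.022 and an
efficiency of 102% — slightly "super-efficient" estimates like this are
common and reflect fit noise, not physics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Tuple, Union

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError


def amplification_factor_from_slope(slope: float) -> float:
    """Per-cycle fold change implied by a standard-curve slope (slope < 0)."""
    if slope >= 0:
        raise DomainError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope)


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency, E = (10**(-1/slope) - 1) * 100."""
    return (amplification_factor_from_slope(slope) - 1.0) * 100.0


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq vs log10(relative input) with derived efficiency."""

    slope: float            # cycles per log10 dilution step
    intercept: float        # Cq at relative input 1.0
    r_squared: float
    efficiency_percent: float
    amplification_factor: float
    n_points: int = 0

    @classmethod
    def from_slope_intercept(cls, slope: float, intercept: float,
                             r_squared: float = float("nan"),
                             n_points: int = 0) -> "StandardCurve":
        return cls(slope=slope, intercept=intercept, r_squared=r_squared,
                   efficiency_percent=efficiency_from_slope(slope),
                   amplification_factor=amplification_factor_from_slope(slope),
                   n_points=n_points)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "StandardCurve":
        return cls(**json.loads(Path(path).read_text()))


def fit_standard_curve(points: Iterable[Tuple[float, float]]) -> StandardCurve:
    """Fit Cq against log10(relative input amount) by ordinary least squares.

    Parameters
    ----------
    points
        (relative_input_amount, cq) pairs.  Replicate Cq values at the same
        dilution enter as separate points; they are not pre-averaged, which
        preserves the error structure of the series.

    Returns
    -------
    StandardCurve
        Slope, intercept, r² (squared Pearson correlation of the fit) and
        the derived efficiency fields.
    """
    pts = list(points)
    amounts = np.array([p[0] for p in pts], dtype=float)
    cqs = np.array([p[1] for p in pts], dtype=float)
    if np.any(amounts <= 0):
        raise DomainError("relative input amounts must be positive")
    if len(pts) < 3 or len(np.unique(amounts)) < 3:
        raise InsufficientDataError(
            "standard curve needs >= 3 points at >= 3 distinct input amounts")
    fit = stats.linregress(np.log10(amounts), cqs)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency_percent=efficiency_from_slope(float(fit.slope)),
        amplification_factor=amplification_factor_from_slope(float(fit.slope)),
        n_points=len(pts),
    )
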