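"""Exponential growth-rate fitting and antiparallel two-drug gradient design.

Growth rates come from an ordinary least-squares fit of ln(OD - background)
against time, restricted to an OD window inside the log-linear part of the
curve (0.01–1 for plate screens, 0.02–0.2 for post-sort cultures).  Fits
faster than 0.85 h^-1 are flagged as bacterial contamination and discarded.
Single-drug dose–response curves, cleaned up by isotonic regression, are
interpolated to iso-effective doses (e.g. the IC50), and an antiparallel
gradient mixes the two drugs linearly in units of those doses so that the
nominal overall inhibition stays constant along the series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import ExtrapolationError, InsufficientDataError, InvalidReferenceError

MAX_RATE_PER_H = 0.85  # contamination cutoff
OD_WINDOW_SCREEN = (0.01, 1.0)
OD_WINDOW_SORTED = (0.02, 0.2)


@dataclass
class GrowthCurve:
    well_id: str
    times: np.ndarray  # hours
    od: np.ndarray
    background: float | None = None  # None -> estimated at fit time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size or self.times.size < 3:
            raise ValueError("need >= 3 matching (time, od) points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class RateFit:
    well_id: str
    rate: float  # per hour
    window: tuple[float, float]
    n_points_used: int
    r_squared: float
    flagged: bool = False
    reason: str | None = None


@dataclass
class DoseResponse:
    drug_id: str
    concentrations: np.ndarray  # ascending
    relative_growth: np.ndarray  # in [0, 1], 1 at zero dose by construction

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.relative_growth = np.asarray(self.relative_growth, dtype=float)
        if self.concentrations.size != self.relative_growth.size:
            raise ValueError("concentrations and relative_growth must match")
        if not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentrations must be strictly ascending")


def estimate_background(curve: GrowthCurve) -> float:
    """Minimum of the first three OD readings, unless supplied on the curve."""
    if curve.background is not None:
        return float(curve.background)
    return float(np.min(curve.od[:3]))


def fit_growth_rate(
    curve: GrowthCurve,
    od_lo: float = OD_WINDOW_SCREEN[0],
    od_hi: float = OD_WINDOW_SCREEN[1],
) -> RateFit:
    """OLS slope of ln(OD - background) vs time within [od_lo, od_hi]."""
    if not od_lo < od_hi:
        raise ValueError("od_lo must be smaller than od_hi")
    background = estimate_background(curve)
    corrected = curve.od - background
    mask = (corrected >= od_lo) & (corrected <= od_hi)
    if int(mask.sum()) < 2:
        raise InsufficientDataError(
            f"well {curve.well_id}: fewer than 2 points with corrected OD in "
            f"[{od_lo}, {od_hi}]"
        )
    t = curve.times[mask]
    y = np.log(corrected[mask])
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RateFit(
        well_id=curve.well_id,
        rate=float(slope),
        window=(od_lo, od_hi),
        n_points_used=int(mask.sum()),
        r_squared=r2,
    )


def filter_rates(
    fits: list[RateFit], max_rate: float = MAX_RATE_PER_H
) -> tuple[list[RateFit], list[RateFit]]:
    """Split fits into kept and contamination-flagged (rate strictly above cutoff)."""
    kept, flagged = [], []
    for fit in fits:
        if fit.rate > max_rate:
            flagged.append(replace(fit, flagged=True, reason="contamination"))
        else:
            kept.append(fit)
    return kept, flagged


def relative_growth(fit: RateFit, reference: RateFit) -> float:
    """Rate relative to a drug-free reference, clipped below at zero."""
    if reference.rate <= 0:
        raise InvalidReferenceError("reference growth rate must be positive")
    return max(0.0, fit.rate / reference.rate)


def _isotonic_decreasing(dr: DoseResponse) -> np.ndarray:
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    return iso.fit_transform(dr.concentrations, dr.relative_growth)


def ic_interpolate(dr: DoseResponse, level: float) -> float:
    """Concentration at which relative growth equals ``level``.

    The response is first made monotone non-increasing by pool-adjacent-
    violators, then linearly interpolated.  Levels outside the observed
    range raise rather than extrapolate.
    """
    rel = _isotonic_decreasing(dr)
    if not rel.min() <= level <= rel.max():
        raise ExtrapolationError(
            f"{dr.drug_id}: level {level} outside observed range "
            f"[{rel.min():.3g}, {rel.max():.3g}]"
        )
    # rel is non-increasing in concentration: reverse for np.interp.
    return float(np.interp(level, rel[::-1], dr.concentrations[::-1]))


def design_antiparallel_gradient(
    dr_a: DoseResponse, dr_b: DoseResponse, level: float, n_points: int
) -> list[tuple[float, float]]:
    """Antiparallel two-drug series holding nominal inhibition constant.

    Point i mixes the iso-effective doses linearly:
    concA = ICA * (1 - i/(n-1)), concB = ICB * i/(n-1); the endpoints are
    the single-drug doses producing the target level.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    ic_a = ic_interpolate(dr_a, level)
    ic_b = ic_interpolate(dr_b, level)
    fracs = np.linspace(0.0, 1.0, n_points)
    return [(ic_a * (1 - f), ic_b * f) for f in fracs]
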