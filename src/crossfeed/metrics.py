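"""Growth-curve and substrate-depletion summary statistics.

Three estimators used throughout consortium characterisation:

* ``max_specific_growth_rate`` — μ_max as the largest sliding-window slope of
  ln(OD) versus time, restricted to points above a detection floor;
* ``lag_time`` — the tangent convention: where the log-space tangent at the
  μ_max window crosses the initial OD level;
* ``conversion_rate`` — disaccharide hydrolysis rate as the magnitude of the
  least-squares slope over the depletion segment of an HPLC concentration
  series (the segment before the concentration falls below a floor fraction
  of its initial value, which also guards against late-time evaporation
  artefacts inflating apparent concentrations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "GrowthSummary",
    "ConversionRate",
    "max_specific_growth_rate",
    "lag_time",
    "conversion_rate",
    "summarize_growth",
]

DEFAULT_WINDOW_POINTS = 5  # 2.5 h at the 0.5 h plate-reader cadence
DEFAULT_OD_FLOOR = 0.02  # below this, reads are dominated by noise


@dataclass(frozen=True)
class GrowthSummary:
    """Summary of one growth curve."""

    mu_max: float  # h^-1
    mu_max_window: tuple[float, float]  # (t_start, t_end) of the best window
    lag_h: float
    final_od: float


@dataclass(frozen=True)
class ConversionRate:
    """Disaccharide depletion slope with its segment and a rising-series flag."""

    rate: float  # g/l/h, non-negative
    window: tuple[float, float]
    n_points: int
    rising: bool = False


def _validate_series(t, y, name: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValidationError(f"t and {name} must have equal lengths")
    if len(t) < 2:
        raise ValidationError("at least two samples are required")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time points must be strictly increasing")
    return t, y


def max_specific_growth_rate(
    t,
    od,
    window_points: int = DEFAULT_WINDOW_POINTS,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> tuple[float, tuple[float, float]]:
    """Maximum specific growth rate μ_max (h⁻¹) and the window achieving it.

    Fits a straight line to ln(OD) against time in every window of
    ``window_points`` consecutive samples whose ODs all exceed ``od_floor``
    and returns the largest slope, floored at zero (a culture that only
    declines has μ_max = 0).  μ_max is invariant to rescaling the OD series
    by a positive constant.

    Raises
    ------
    DegenerateDataError
        Fewer than ``window_points`` consecutive samples above the floor.
    """
    if window_points < 2:
        raise ValidationError("window_points must be >= 2")
    t, od = _validate_series(t, od, "od")
    above = od > od_floor
    best_slope = None
    best_window = None
    for i in range(len(t) - window_points + 1):
        j = i + window_points
        if not above[i:j].all():
            continue
        slope = np.polyfit(t[i:j], np.log(od[i:j]), 1)[0]
        if best_slope is None or slope > best_slope:
            best_slope = slope
            best_window = (float(t[i]), float(t[j - 1]))
    if best_slope is None:
        raise DegenerateDataError(
            f"no window of {window_points} consecutive samples above the "
            f"OD floor {od_floor}"
        )
    return max(float(best_slope), 0.0), best_window


def lag_time(
    t,
    od,
    window_points: int = DEFAULT_WINDOW_POINTS,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> float:
    """Lag phase duration (h) by the tangent convention.

    The tangent to ln(OD) at the μ_max window is intersected with the
    initial OD level; a curve that is exponential from t = 0 has zero lag.

    Raises
    ------
    DegenerateDataError
        If no growth is detected (μ_max = 0 or no usable window).
    """
    t, od = _validate_series(t, od, "od")
    mu, window = max_specific_growth_rate(t, od, window_points, od_floor)
    if mu <= 0:
        raise DegenerateDataError("no growth detected (mu_max = 0)")
    mask = (t >= window[0]) & (t <= window[1])
    # tangent: ln od = intercept + mu * t through the window's centroid
    intercept = float(np.mean(np.log(od[mask])) - mu * np.mean(t[mask]))
    od0 = float(od[0])
    if od0 <= 0:
        od0 = float(od[od > 0][0])
    lag = (np.log(od0) - intercept) / mu
    return max(float(lag), 0.0)


def conversion_rate(
    t,
    disaccharide_g_per_l,
    depletion_floor_fraction: float = 0.1,
) -> ConversionRate:
    """Disaccharide-to-monosaccharide conversion rate from HPLC depletion.

    The depletion segment runs from the start of the series until the
    concentration first drops below ``depletion_floor_fraction`` of its
    initial value; the rate is the magnitude of the least-squares slope over
    that segment.  A series whose best-fit slope rises returns a zero rate
    with the ``rising`` flag set instead of raising.

    Raises
    ------
    ValidationError
        Fewer than 4 points in the depletion segment.
    """
    if not 0 <= depletion_floor_fraction < 1:
        raise ValidationError("depletion_floor_fraction must be in [0, 1)")
    t, c = _validate_series(t, disaccharide_g_per_l, "concentration")
    if np.any(c < 0):
        raise ValidationError("concentrations must be non-negative")
    floor = depletion_floor_fraction * c[0]
    below = np.nonzero(c < floor)[0]
    end = below[0] if len(below) else len(c)
    if end < 4:
        raise ValidationError(
            f"depletion segment has {end} points; at least 4 are required"
        )
    ts, cs = t[:end], c[:end]
    slope = float(np.polyfit(ts, cs, 1)[0])
    window = (float(ts[0]), float(ts[-1]))
    if slope >= 0:
        return ConversionRate(rate=0.0, window=window, n_points=end, rising=True)
    return ConversionRate(rate=-slope, window=window, n_points=end)


def summarize_growth(
    t,
    od,
    window_points: int = DEFAULT_WINDOW_POINTS,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> GrowthSummary:
    """μ_max, its window, the tangent lag and the final OD of one curve."""
    t, od = _validate_series(t, od, "od")
    mu, window = max_specific_growth_rate(t, od, window_points, od_floor)
    if mu > 0:
        lag = lag_time(t, od, window_points, od_floor)
    else:
        lag = 0.0
    return GrowthSummary(
        mu_max=mu, mu_max_window=window, lag_h=lag, final_od=float(od[-1])
    )
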