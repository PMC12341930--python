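"""Fluorescence-to-OD calibration and coculture strain deconvolution.

In cocultures the plate reader only measures the total OD600 plus one
fluorescence channel per strain (msfGFP for CP-X, mScarlet for CP-G).
Per-strain abundances are recovered in two steps:

1. a continuous calibration curve, fitted on monoculture wells grown in the
   same experiment, maps the GFP signal (AU) to CP-X OD;
2. the CP-G OD is the total OD minus the calibrated CP-X OD.  The direct
   mScarlet route is supported, but its slow chromophore maturation makes the
   red signal lag biomass, so subtraction is the default for CP-G.

The calibration family is a continuous two-segment curve: linear at low
fluorescence, quadratic above a breakpoint chosen to minimise the in-sample
error, with monotonicity enforced (falling back to a single linear fit when
the quadratic segment would not be monotone).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from scipy.stats import spearmanr

from .errors import CalibrationError, ValidationError

__all__ = [
    "CalibrationCurve",
    "CalibratedOD",
    "DeconvolvedOD",
    "build_calibration",
    "od_x_from_gfp",
    "od_g_from_total",
]

_MIN_POINTS = 10
_MONOTONE_TOL = 1e-9
# minimum Spearman rank correlation between fluorescence and OD for the raw
# relationship to count as monotone
_RAW_MONOTONE_RHO = 0.8


class CalibratedOD(NamedTuple):
    """OD values mapped through a calibration curve, with clamp flags."""

    od: np.ndarray
    out_of_range: np.ndarray


class DeconvolvedOD(NamedTuple):
    """Subtraction-rule CP-G ODs with negative-value clamp flags."""

    od: np.ndarray
    clamped: np.ndarray

    @property
    def n_clamped(self) -> int:
        return int(np.count_nonzero(self.clamped))


@dataclass(frozen=True)
class CalibrationCurve:
    """Continuous monotone map from fluorescence (AU) to single-strain OD.

    Piecewise form with a single breakpoint ``f_b``::

        od(f) = a + b*f                                  for f <= f_b
        od(f) = a + b*f_b + c*(f - f_b) + d*(f - f_b)^2  for f >  f_b

    Continuity at the breakpoint holds by construction.  ``breakpoint`` may
    equal the upper range limit, in which case the curve is a plain line.
    Inputs outside ``f_range`` are clamped to the boundary ODs and flagged.
    """

    channel: str
    breakpoint: float
    coefficients: tuple[float, float, float, float]  # (a, b, c, d)
    f_range: tuple[float, float]
    rmse: float

    def __post_init__(self) -> None:
        fmin, fmax = self.f_range
        if not fmin < fmax:
            raise ValidationError("f_range must satisfy fmin < fmax")
        if not (fmin <= self.breakpoint <= fmax):
            raise ValidationError("breakpoint must lie inside f_range")
        grid = np.linspace(fmin, fmax, 512)
        od = self._evaluate(grid)
        if np.any(np.diff(od) < -_MONOTONE_TOL):
            raise ValidationError("calibration curve must be monotone non-decreasing")

    def _evaluate(self, f: np.ndarray) -> np.ndarray:
        a, b, c, d = self.coefficients
        f = np.asarray(f, dtype=float)
        low = a + b * f
        df = f - self.breakpoint
        high = a + b * self.breakpoint + c * df + d * df**2
        return np.where(f <= self.breakpoint, low, high)

    def od(self, fluorescence) -> CalibratedOD:
        """Map fluorescence to OD, clamping out-of-range inputs to the
        boundary ODs and flagging them."""
        f = np.atleast_1d(np.asarray(fluorescence, dtype=float))
        fmin, fmax = self.f_range
        flags = (f < fmin) | (f > fmax)
        od = self._evaluate(np.clip(f, fmin, fmax))
        return CalibratedOD(od=od, out_of_range=flags)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "breakpoint": float(self.breakpoint),
            "coefficients": [float(c) for c in self.coefficients],
            "f_range": [float(self.f_range[0]), float(self.f_range[1])],
            "rmse": float(self.rmse),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationCurve":
        return cls(
            channel=str(d["channel"]),
            breakpoint=float(d["breakpoint"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            f_range=(float(d["f_range"][0]), float(d["f_range"][1])),
            rmse=float(d["rmse"]),
        )


def _fit_segments(
    f: np.ndarray, od: np.ndarray, fb: float
) -> tuple[tuple[float, float, float, float], float] | None:
    """Least-squares fit of the continuous two-segment model at breakpoint fb.

    Returns (coefficients, sse), or None when the fitted map is not monotone
    over the data range.
    """
    low = f <= fb
    df = np.where(low, 0.0, f - fb)
    A = np.column_stack(
        [
            np.ones_like(f),
            np.where(low, f, fb),
            df,
            df**2,
        ]
    )
    coef, *_ = np.linalg.lstsq(A, od, rcond=None)
    a, b, c, d = coef
    if b < -_MONOTONE_TOL:
        return None
    span = f.max() - fb
    # derivative of the upper quadratic at both ends of its segment
    if span > 0 and (c < -_MONOTONE_TOL or c + 2 * d * span < -_MONOTONE_TOL):
        return None
    resid = A @ coef - od
    return (float(a), float(b), float(c), float(d)), float(resid @ resid)


def build_calibration(series, channel: str = "gfp") -> CalibrationCurve:
    """Fit a continuous monotone calibration curve on monoculture data.

    Parameters
    ----------
    series
        A monoculture :class:`~crossfeed.synth.PlateReaderSeries` (or any
        object with ``od600`` and ``<channel>_au`` attributes) whose wells
        contain a single strain, so OD600 is that strain's OD.
    channel
        ``"gfp"`` or ``"mscarlet"``.

    Raises
    ------
    ValidationError
        Fewer than 10 paired points.
    CalibrationError
        The raw fluorescence–OD relationship is not monotone enough
        (Spearman rho < 0.8) to support a monotone curve.
    """
    try:
        f = np.asarray(getattr(series, f"{channel}_au"), dtype=float)
    except AttributeError:
        raise ValidationError(f"unknown fluorescence channel: {channel!r}") from None
    od = np.asarray(series.od600, dtype=float)
    if len(f) < _MIN_POINTS:
        raise ValidationError(
            f"calibration needs >= {_MIN_POINTS} points, got {len(f)}"
        )
    order = np.argsort(f, kind="stable")
    f, od = f[order], od[order]
    rho = spearmanr(f, od).statistic
    if not np.isfinite(rho) or rho < _RAW_MONOTONE_RHO:
        raise CalibrationError(
            f"fluorescence–OD relationship is not monotone (Spearman rho={rho:.3f})"
        )

    n = len(f)
    candidates = [f[i] for i in range(4, n - 4)]
    candidates.append(f[-1])  # plain linear fit as fallback breakpoint
    best: tuple[float, tuple, float] | None = None  # (sse, coef, fb)
    for fb in candidates:
        fit = _fit_segments(f, od, fb)
        if fit is None:
            continue
        coef, sse = fit
        if best is None or sse < best[0]:
            best = (sse, coef, fb)
    if best is None:
        raise CalibrationError("no monotone calibration fit found")
    sse, coef, fb = best
    return CalibrationCurve(
        channel=channel,
        breakpoint=float(fb),
        coefficients=coef,
        f_range=(float(f[0]), float(f[-1])),
        rmse=float(np.sqrt(sse / n)),
    )


def od_x_from_gfp(gfp, curve: CalibrationCurve) -> CalibratedOD:
    """CP-X OD from the GFP channel through its calibration curve.

    Out-of-range fluorescence values are clamped to the curve's boundary ODs
    and flagged rather than extrapolated.
    """
    return curve.od(gfp)


def od_g_from_total(od_total, od_x) -> DeconvolvedOD:
    """CP-G OD by the subtraction rule: ``max(od_total - od_x, 0)``.

    Negative differences (calibration noise exceeding the true CP-G biomass)
    are clamped to zero and flagged, never silently dropped.
    """
    tot = np.atleast_1d(np.asarray(od_total, dtype=float))
    odx = np.atleast_1d(np.asarray(od_x, dtype=float))
    if np.any(tot < 0) or np.any(odx < 0):
        raise ValidationError("ODs must be non-negative")
    diff = tot - odx
    clamped = diff < 0
    return DeconvolvedOD(od=np.where(clamped, 0.0, diff), clamped=clamped)
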