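"""Synthetic plate-reader and HPLC data with the structure of real cocultures.

Every downstream stage (calibration, deconvolution, fitting, metrics) is
exercised on data from these generators, which emulate the statistical
features of 96-well plate cultivation and HPLC sugar monitoring:

* per-strain fluorescence proportional to biomass, with the mScarlet channel
  low-pass filtered to mimic its slow chromophore maturation;
* additive Gaussian measurement noise on OD and fluorescence;
* optional late-time evaporation, concentrating all signals multiplicatively
  after a start time;
* linear disaccharide depletion with the hydration mass gain of hydrolysis
  (two monomers plus one water per disaccharide), minus monosaccharide
  consumption.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fitting import FitObservations
from .simulate import Scenario, simulate

__all__ = [
    "NoiseModel",
    "PlateReaderSeries",
    "HPLCSeries",
    "HYDRATION_GAIN",
    "DEFAULT_YIELDS",
    "generate_plate_reader",
    "generate_hplc",
    "generate_calibration_fixture",
    "generate_growth_observations",
]

# Molar masses (g/mol): hydrolysis of one disaccharide consumes one water, so
# 1 g of disaccharide yields slightly more than 1 g of monosaccharide.
MOLAR_MASS = {
    "cellobiose": 342.30,
    "glucose": 180.16,
    "xylobiose": 282.25,
    "xylose": 150.13,
}
HYDRATION_GAIN = {
    "cellobiose": 2 * MOLAR_MASS["glucose"] / MOLAR_MASS["cellobiose"],  # 360.32/342.30
    "xylobiose": 2 * MOLAR_MASS["xylose"] / MOLAR_MASS["xylobiose"],  # 300.26/282.25
}

#: Default fluorescence yields (AU per OD unit); instrument-specific free
#: parameters of the emulation, not physical constants.
DEFAULT_YIELDS = {"gfp": 1000.0, "mscarlet": 800.0}

DEFAULT_MATURATION_HALFTIME_H = 0.67  # ~40 min first-order mScarlet maturation


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise and drift settings for the plate-reader emulation.

    ``evaporation_rate`` is the fractional concentration increase per hour
    applied multiplicatively after ``evaporation_start_h`` (late-time loss of
    culture volume concentrates everything in the well).
    """

    od_sd: float = 0.0
    fluor_sd: float = 0.0
    evaporation_rate: float = 0.0
    evaporation_start_h: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_sd < 0 or self.fluor_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not 0 <= self.evaporation_rate < 0.01:
            raise ValidationError("evaporation_rate must be in [0, 0.01)")


@dataclass(frozen=True)
class PlateReaderSeries:
    """One well's measured time series: OD600 plus two fluorescence channels."""

    well: str
    t: np.ndarray
    od600: np.ndarray
    gfp_au: np.ndarray
    mscarlet_au: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        arrays = {}
        for name in ("od600", "gfp_au", "mscarlet_au"):
            a = np.asarray(getattr(self, name), dtype=float)
            if len(a) != len(t):
                raise ValidationError(f"{name} length must match t")
            if np.any(a < 0):
                raise ValidationError(f"{name} must be non-negative")
            arrays[name] = a
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time points must be strictly increasing")
        object.__setattr__(self, "t", t)
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t,
                "od600": self.od600,
                "gfp_au": self.gfp_au,
                "mscarlet_au": self.mscarlet_au,
            }
        )


@dataclass(frozen=True)
class HPLCSeries:
    """Saccharide concentrations (g/l) over time for the four sugars."""

    t: np.ndarray
    glucose: np.ndarray
    xylose: np.ndarray
    cellobiose: np.ndarray
    xylobiose: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time points must be strictly increasing")
        object.__setattr__(self, "t", t)
        for name in ("glucose", "xylose", "cellobiose", "xylobiose"):
            a = np.asarray(getattr(self, name), dtype=float)
            if len(a) != len(t):
                raise ValidationError(f"{name} length must match t")
            if np.any(a < 0):
                raise ValidationError(f"{name} must be non-negative")
            object.__setattr__(self, name, a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t,
                "glucose": self.glucose,
                "xylose": self.xylose,
                "cellobiose": self.cellobiose,
                "xylobiose": self.xylobiose,
            }
        )


def _first_order_lag(t: np.ndarray, signal: np.ndarray, halftime_h: float) -> np.ndarray:
    """Discrete first-order low-pass of ``signal`` with the given half-time.

    Exact exponential update per step assuming the input is constant over
    each interval; a zero half-time returns the input unchanged.  The filter
    starts at the signal's initial value (pre-existing biomass is matured).
    """
    if halftime_h <= 0:
        return signal.copy()
    k = np.log(2.0) / halftime_h
    out = np.empty_like(signal)
    out[0] = signal[0]
    decay = np.exp(-k * np.diff(t))
    for i in range(1, len(signal)):
        out[i] = signal[i] + (out[i - 1] - signal[i]) * decay[i - 1]
    return out


def _evaporation_factor(t: np.ndarray, noise: NoiseModel) -> np.ndarray:
    factor = np.ones_like(t)
    late = t > noise.evaporation_start_h
    factor[late] = (1.0 + noise.evaporation_rate) ** (
        t[late] - noise.evaporation_start_h
    )
    return factor


def generate_plate_reader(
    scenario: Scenario,
    yields: Mapping[str, float] = DEFAULT_YIELDS,
    maturation_halftime_h: float = DEFAULT_MATURATION_HALFTIME_H,
    noise: NoiseModel = NoiseModel(),
    well: str = "A1",
) -> PlateReaderSeries:
    """Emulate one coculture well: OD600, GFP and mScarlet channels.

    The underlying trajectory is the ODE solution of ``scenario``; GFP tracks
    CP-X biomass instantaneously while mScarlet follows CP-G through a
    first-order maturation lag.  Evaporation (if enabled) concentrates all
    three signals; Gaussian noise is then added per channel and the result
    clipped at zero.  Deterministic given ``noise.seed``.
    """
    if maturation_halftime_h < 0:
        raise ValidationError("maturation_halftime_h must be >= 0")
    traj = simulate(scenario)
    rng = np.random.default_rng(noise.seed)
    factor = _evaporation_factor(traj.t, noise)
    od600 = traj.total * factor
    gfp = yields["gfp"] * traj.X * factor
    mscarlet = (
        yields["mscarlet"]
        * _first_order_lag(traj.t, traj.G, maturation_halftime_h)
        * factor
    )
    if noise.od_sd > 0:
        od600 = od600 + rng.normal(0.0, noise.od_sd, len(od600))
    if noise.fluor_sd > 0:
        gfp = gfp + rng.normal(0.0, noise.fluor_sd, len(gfp))
        mscarlet = mscarlet + rng.normal(0.0, noise.fluor_sd, len(mscarlet))
    return PlateReaderSeries(
        well=well,
        t=traj.t,
        od600=np.clip(od600, 0.0, None),
        gfp_au=np.clip(gfp, 0.0, None),
        mscarlet_au=np.clip(mscarlet, 0.0, None),
    )


def generate_hplc(
    initial_disaccharides_g_per_l: Mapping[str, float],
    conversion_rates_g_per_l_h: Mapping[str, float],
    consumption_rates_g_per_l_h: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_end: float = 48.0,
    n_points: int = 16,
) -> HPLCSeries:
    """Emulate HPLC sugar monitoring of a (co)cultivation.

    Disaccharides decline linearly at their conversion rates (clipped at 0);
    the released monosaccharides gain the hydrolysis water mass
    (glucose: 360.32/342.30 per g cellobiose; xylose: 300.26/282.25 per g
    xylobiose) and are drawn down linearly at the consumption rates, clipped
    at 0.  Gaussian noise of ``noise_sd`` g/l is added to every series.  At
    zero noise and zero consumption the per-pair mass balance
    ``monosaccharide == (initial - disaccharide) * gain`` holds exactly.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    init = dict(initial_disaccharides_g_per_l)
    conv = dict(conversion_rates_g_per_l_h)
    cons = dict(consumption_rates_g_per_l_h or {})
    for d in init.values():
        if d < 0:
            raise ValidationError("initial concentrations must be >= 0")
    for r in list(conv.values()) + list(cons.values()):
        if r < 0:
            raise ValidationError("rates must be >= 0")

    t = np.linspace(0.0, float(t_end), int(n_points))
    series: dict[str, np.ndarray] = {}
    pairs = {"cellobiose": "glucose", "xylobiose": "xylose"}
    for di, mono in pairs.items():
        d0 = init.get(di, 0.0)
        rate = conv.get(di, 0.0)
        d = np.clip(d0 - rate * t, 0.0, None)
        produced = (d0 - d) * HYDRATION_GAIN[di]
        m = np.clip(produced - cons.get(mono, 0.0) * t, 0.0, None)
        series[di] = d
        series[mono] = m

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        for name in series:
            series[name] = np.clip(
                series[name] + rng.normal(0.0, noise_sd, len(t)), 0.0, None
            )
    return HPLCSeries(t=t, **series)


def generate_calibration_fixture(
    strain: str = "CP-X",
    channel: str = "gfp",
    n_points: int = 20,
    noise_sd_au: float = 0.0,
    seed: int = 0,
    yield_au_per_od: float | None = None,
) -> PlateReaderSeries:
    """Monoculture calibration well: paired OD/fluorescence spanning OD 0–1.

    The fluorescence of the strain's channel is ``yield * OD`` plus Gaussian
    noise; the other channel reads zero (single-strain well).  Time points
    are a nominal half-hour grid.
    """
    if n_points < 10:
        raise ValidationError("calibration fixtures need n_points >= 10")
    if channel not in ("gfp", "mscarlet"):
        raise ValidationError(f"unknown channel: {channel!r}")
    y = DEFAULT_YIELDS[channel] if yield_au_per_od is None else float(yield_au_per_od)
    rng = np.random.default_rng(seed)
    od = np.linspace(0.0, 1.0, n_points)
    au = y * od
    if noise_sd_au > 0:
        au = np.clip(au + rng.normal(0.0, noise_sd_au, n_points), 0.0, None)
    zeros = np.zeros(n_points)
    return PlateReaderSeries(
        well=f"cal-{strain}",
        t=0.5 * np.arange(n_points),
        od600=od,
        gfp_au=au if channel == "gfp" else zeros,
        mscarlet_au=au if channel == "mscarlet" else zeros,
    )


def generate_growth_observations(
    scenario: Scenario,
    od_sd: float = 0.01,
    seed: int = 0,
    n_replicates: int = 3,
) -> list[FitObservations]:
    """Replicate noisy (total OD, CP-X OD) series for fitting experiments.

    Each replicate adds independent Gaussian noise of ``od_sd`` to the
    simulated total and CP-X ODs (clipped at zero), emulating deconvolved
    plate-reader replicates on a shared grid.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if od_sd < 0:
        raise ValidationError("od_sd must be >= 0")
    traj = simulate(scenario)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        tot = np.clip(traj.total + rng.normal(0.0, od_sd, len(traj.t)), 0.0, None)
        odx = np.clip(traj.X + rng.normal(0.0, od_sd, len(traj.t)), 0.0, None)
        out.append(FitObservations(t=traj.t, od_total=tot, od_x=odx))
    return out
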