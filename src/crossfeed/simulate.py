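"""Scenario construction and numerical integration of the consortium ODEs.

A :class:`Scenario` bundles the model parameters, the α scaling factors, the
initial strain ODs, and the output grid.  :func:`simulate` integrates the
coupled equations with an adaptive explicit Runge–Kutta method and returns a
:class:`Trajectory` on a regular output grid; helpers translate experimental
knobs (inoculation ratios, disaccharide ratios) into model inputs, and
:func:`scenario_battery` tabulates a panel of scenario variants.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import NumericError, ValidationError
from .model import (
    BASELINE_PARAMETERS,
    IDENTITY_SCALING,
    ConsortiumState,
    ModelParameters,
    ScalingFactors,
)

__all__ = [
    "Scenario",
    "Trajectory",
    "simulate",
    "inoculation_ratio_to_state",
    "substrate_ratio_to_scaling",
    "scenario_battery",
]

# Integrator tolerances; stiffness is mild so an explicit adaptive method
# suffices.  Negative round-off excursions are clipped to 0 at output.
RTOL = 1e-8
ATOL = 1e-10
_NEG_CLIP = -1e-12


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation: model, scenario scalings, initial state
    and output grid.  Defaults mirror the plate-reader protocol (72 h read
    every 0.5 h)."""

    params: ModelParameters = BASELINE_PARAMETERS
    scaling: ScalingFactors = IDENTITY_SCALING
    initial: ConsortiumState = ConsortiumState(0.01, 0.01)
    t_end: float = 72.0
    dt_out: float = 0.5

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValidationError(f"t_end must be > 0, got {self.t_end}")
        if not self.dt_out > 0:
            raise ValidationError(f"dt_out must be > 0, got {self.dt_out}")

    @property
    def t_grid(self) -> np.ndarray:
        n = int(math.floor(self.t_end / self.dt_out + 1e-9))
        t = np.arange(n + 1) * self.dt_out
        if t[-1] < self.t_end - 1e-9:
            t = np.append(t, self.t_end)
        return t


@dataclass(frozen=True)
class Trajectory:
    """Simulated (or reconstructed) per-strain OD time courses."""

    t: np.ndarray
    X: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        X = np.asarray(self.X, dtype=float)
        G = np.asarray(self.G, dtype=float)
        if not (len(t) == len(X) == len(G)):
            raise ValidationError("t, X, G must have equal lengths")
        if len(t) == 0:
            raise ValidationError("trajectory must contain at least one point")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time points must be strictly increasing")
        if np.any(X < 0) or np.any(G < 0):
            raise ValidationError("OD values must be non-negative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "G", G)

    @property
    def total(self) -> np.ndarray:
        return self.X + self.G

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t,
                "od_x": self.X,
                "od_g": self.G,
                "od_total": self.total,
            }
        )


def _rhs(params: ModelParameters, scaling: ScalingFactors):
    r_mx = params.r_mx / scaling.alpha_Bx
    r_mg = params.r_mg
    aDg, aDx = scaling.alpha_Dg, scaling.alpha_Dx
    C_g = params.C_g
    C_x = params.C_x / scaling.alpha_Ex
    KK = scaling.alpha_K * params.K

    def f(t: float, y: np.ndarray) -> list[float]:
        X, G = y
        cap = 1.0 - (G + X) / KK
        return [
            r_mx * (aDg * G / (C_g + G)) * cap * X,
            r_mg * (aDx * X / (C_x + X)) * cap * G,
        ]

    return f


def simulate(scenario: Scenario, rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Integrate the consortium ODEs over the scenario's output grid.

    Uses an adaptive RK45 integrator; output OD values are clipped at zero to
    remove round-off-level negative excursions.  Because the mutualism is
    obligate, a scenario starting with either strain absent stays constant.

    Raises
    ------
    NumericError
        If the integrator reports failure (e.g. step-size collapse).
    """
    t_grid = scenario.t_grid
    y0 = [scenario.initial.X, scenario.initial.G]
    sol = solve_ivp(
        _rhs(scenario.params, scenario.scaling),
        (0.0, float(scenario.t_end)),
        y0,
        t_eval=t_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericError(
            f"ODE integration failed: {sol.message} (scenario={scenario})"
        )
    X, G = sol.y
    if X.min(initial=0.0) < _NEG_CLIP or G.min(initial=0.0) < _NEG_CLIP:
        raise NumericError(
            "integrator produced negative ODs beyond round-off "
            f"(min X={X.min():.3e}, min G={G.min():.3e})"
        )
    return Trajectory(t=sol.t, X=np.clip(X, 0.0, None), G=np.clip(G, 0.0, None))


def inoculation_ratio_to_state(total_od: float, ratio_x_to_g: float) -> ConsortiumState:
    """Split a total inoculum OD into per-strain ODs at a given X:G ratio.

    ``ratio_x_to_g = 10`` means ten parts CP-X to one part CP-G, so a total
    of 0.02 splits into ``X0 = 0.0182``, ``G0 = 0.0018`` (to 4 decimals).
    """
    if not total_od > 0:
        raise ValidationError(f"total_od must be > 0, got {total_od}")
    if not ratio_x_to_g > 0:
        raise ValidationError(f"ratio_x_to_g must be > 0, got {ratio_x_to_g}")
    G = total_od / (ratio_x_to_g + 1.0)
    return ConsortiumState(X=total_od - G, G=G)


def substrate_ratio_to_scaling(
    cellobiose_g_per_l: float,
    xylobiose_g_per_l: float,
    reference_g_per_l: float = 1.0,
) -> ScalingFactors:
    """Translate initial disaccharide amounts into α_Dx / α_Dg scalings.

    Substrate factors scale proportionally with the initial amount of the
    corresponding disaccharide relative to the reference cultivation
    (1 g/l of each); the enzyme and burden factors stay at 1.
    """
    if cellobiose_g_per_l < 0 or xylobiose_g_per_l < 0:
        raise ValidationError("disaccharide concentrations must be >= 0")
    if not reference_g_per_l > 0:
        raise ValidationError("reference concentration must be > 0")
    return ScalingFactors(
        alpha_Dx=cellobiose_g_per_l / reference_g_per_l,
        alpha_Dg=xylobiose_g_per_l / reference_g_per_l,
    )


_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_SCALING_KEYS = {f.name for f in dataclasses.fields(ScalingFactors)}
_INITIAL_KEYS = {"X0", "G0"}


def _apply_overrides(base: Scenario, overrides: Mapping[str, float]) -> Scenario:
    """Build a variant scenario from flat override keys (r_mx…, alpha_…, X0/G0)."""
    p = base.params.to_dict()
    s = base.scaling.to_dict()
    init = {"X0": base.initial.X, "G0": base.initial.G}
    for key, value in overrides.items():
        if key in _PARAM_KEYS:
            p[key] = float(value)
        elif key in _SCALING_KEYS:
            s[key] = float(value)
        elif key in _INITIAL_KEYS:
            init[key] = float(value)
        else:
            raise ValidationError(f"unknown scenario override key: {key!r}")
    return dataclasses.replace(
        base,
        params=ModelParameters.from_dict(p),
        scaling=ScalingFactors.from_dict(s),
        initial=ConsortiumState(X=init["X0"], G=init["G0"]),
    )


def scenario_battery(
    base: Scenario,
    variants: Mapping[str, Mapping[str, float]] | Sequence[tuple[str, Mapping[str, float]]],
) -> pd.DataFrame:
    """Simulate a named panel of scenario variants and tabulate summaries.

    Each variant is a mapping of flat override keys (model parameters,
    alpha factors, or initial ODs ``X0``/``G0``) applied on top of ``base``.
    The summary row reports the final per-strain ODs, the final X:G ratio,
    and the time at which the total OD first reaches half of the scaled
    carrying capacity ``alpha_K * K`` (NaN if never reached).
    """
    items = list(variants.items()) if isinstance(variants, Mapping) else list(variants)
    if not items:
        raise ValidationError("variant list must not be empty")
    rows = []
    for name, overrides in items:
        try:
            scen = _apply_overrides(base, overrides)
            traj = simulate(scen)
        except Exception as e:
            raise type(e)(f"variant {name!r}: {e}") from e
        half = 0.5 * scen.scaling.alpha_K * scen.params.K
        total = traj.total
        above = np.nonzero(total >= half)[0]
        rows.append(
            {
                "variant": name,
                "od_x_final": traj.X[-1],
                "od_g_final": traj.G[-1],
                "od_total_final": total[-1],
                "ratio_x_to_g_final": (
                    traj.X[-1] / traj.G[-1] if traj.G[-1] > 0 else math.inf
                ),
                "t_half_capacity_h": traj.t[above[0]] if len(above) else math.nan,
            }
        )
    return pd.DataFrame(rows)
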