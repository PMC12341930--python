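"""Estimation of the five consortium model parameters from growth curves.

The observable in a plate-reader cocultivation is the total OD600 plus the
CP-X OD reconstructed from its GFP signal (see :mod:`crossfeed.calibration`).
Fitting minimises the stacked residuals of both series against the simulated
``X(t) + G(t)`` and ``X(t)`` by bounded least squares (trust-region
reflective) in log-parameter space, restarted from several seeded log-uniform
draws inside the bounds because the objective is multimodal in the weakly
identifiable half-saturation constants ``C_x`` and ``C_g``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import DegenerateDataError, FittingError, NumericError, ValidationError
from .model import ConsortiumState, ModelParameters, ScalingFactors, IDENTITY_SCALING
from .simulate import ATOL, RTOL, Trajectory, _rhs

__all__ = [
    "FitObservations",
    "FitResult",
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "residuals",
    "fit_parameters",
]

PARAM_NAMES: tuple[str, ...] = ("r_mx", "r_mg", "C_x", "C_g", "K")

#: Generous brackets around plausible values: growth rates in [1e-3, 2] h⁻¹,
#: half-saturation constants in [1e-4, 1] OD, carrying capacity in [0.05, 5] OD.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r_mx": (1e-3, 2.0),
    "r_mg": (1e-3, 2.0),
    "C_x": (1e-4, 1.0),
    "C_g": (1e-4, 1.0),
    "K": (0.05, 5.0),
}

# Minimum relative spread of the total-OD series for a fit to be attempted.
_MIN_RELATIVE_GROWTH = 0.1


@dataclass(frozen=True)
class FitObservations:
    """One well's observed series: total OD and the deconvolved CP-X OD."""

    t: np.ndarray
    od_total: np.ndarray
    od_x: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        tot = np.asarray(self.od_total, dtype=float)
        odx = np.asarray(self.od_x, dtype=float)
        if not (len(t) == len(tot) == len(odx)):
            raise ValidationError("t, od_total, od_x must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time points must be strictly increasing")
        if np.any(tot < 0) or np.any(odx < 0):
            raise ValidationError("OD values must be non-negative")
        w = self.weights
        if w is not None:
            w = np.asarray(w, dtype=float)
            if len(w) != len(t):
                raise ValidationError("weights length must match t")
            if np.any(w < 0):
                raise ValidationError("weights must be non-negative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "od_total", tot)
        object.__setattr__(self, "od_x", odx)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multistart bounded least-squares fit."""

    params: ModelParameters
    residual_norm: float
    n_iter: int
    converged: bool
    at_bounds: dict[str, bool]
    start_costs: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "residual_norm": float(self.residual_norm),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "at_bounds": dict(self.at_bounds),
            "start_costs": [float(c) for c in self.start_costs],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        return cls(
            params=ModelParameters.from_dict(dict(d["params"])),
            residual_norm=float(d["residual_norm"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            at_bounds=dict(d["at_bounds"]),
            start_costs=tuple(float(c) for c in d.get("start_costs", ())),
        )


def _as_obs_list(obs) -> list[FitObservations]:
    if isinstance(obs, FitObservations):
        return [obs]
    out = list(obs)
    if not out:
        raise ValidationError("at least one observation series is required")
    return out


def _simulate_on(params: ModelParameters, scaling, initial, t: np.ndarray) -> Trajectory:
    """Integrate once on the exact observation grid."""
    t_eval = t
    prepend = t[0] > 0.0
    if prepend:
        t_eval = np.concatenate(([0.0], t))
    sol = solve_ivp(
        _rhs(params, scaling),
        (0.0, float(t[-1])),
        [initial.X, initial.G],
        t_eval=t_eval,
        method="RK45",
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise NumericError(f"ODE integration failed during fit: {sol.message}")
    X, G = sol.y
    if prepend:
        X, G = X[1:], G[1:]
    return Trajectory(t=t, X=np.clip(X, 0.0, None), G=np.clip(G, 0.0, None))


def residuals(
    params: ModelParameters,
    obs: FitObservations | Sequence[FitObservations],
    scaling: ScalingFactors = IDENTITY_SCALING,
    initial: ConsortiumState | None = None,
) -> np.ndarray:
    """Stacked, weighted residuals of the model against one or more wells.

    For each observation series the residual blocks are
    ``sim(X+G) - od_total`` and ``sim(X) - od_x`` on the observation grid,
    concatenated (total block first) and multiplied elementwise by the
    per-point weights when given.  Both blocks enter with equal weight.

    Raises
    ------
    NumericError
        If the simulation fails; the offending parameter values are included
        in the message.
    """
    obs_list = _as_obs_list(obs)
    init = initial if initial is not None else _initial_from_data(obs_list)
    blocks: list[np.ndarray] = []
    try:
        cache: dict[tuple, Trajectory] = {}
        for ob in obs_list:
            key = (ob.t.tobytes(),)
            traj = cache.get(key)
            if traj is None:
                traj = _simulate_on(params, scaling, init, ob.t)
                cache[key] = traj
            r = np.concatenate([traj.total - ob.od_total, traj.X - ob.od_x])
            if ob.weights is not None:
                r *= np.tile(ob.weights, 2)
            blocks.append(r)
    except NumericError as e:
        raise NumericError(f"{e} at params={params.to_dict()}") from e
    return np.concatenate(blocks)


def _initial_from_data(obs_list: Sequence[FitObservations]) -> ConsortiumState:
    """First-time-point split of the observed total OD by the observed CP-X OD.

    Both components are floored at 1e-4 OD: read noise at inoculation-level
    densities can otherwise zero a strain and freeze the obligate mutualism,
    making every parameter set fit equally badly.
    """
    x0 = float(np.mean([ob.od_x[0] for ob in obs_list]))
    g0 = float(np.mean([ob.od_total[0] - ob.od_x[0] for ob in obs_list]))
    return ConsortiumState(X=max(x0, 1e-4), G=max(g0, 1e-4))


def _check_growth_signal(obs_list: Sequence[FitObservations]) -> None:
    tot = np.concatenate([ob.od_total for ob in obs_list])
    peak = float(tot.max())
    if peak <= 0 or (peak - float(tot.min())) / peak < _MIN_RELATIVE_GROWTH:
        raise DegenerateDataError(
            "total-OD series shows no usable growth signal "
            f"(relative range < {_MIN_RELATIVE_GROWTH})"
        )


def fit_parameters(
    obs: FitObservations | Sequence[FitObservations],
    scaling: ScalingFactors = IDENTITY_SCALING,
    initial: ConsortiumState | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Best-of-multistart bounded least-squares estimate of the five parameters.

    The optimisation runs in log10-parameter space (all parameters are
    positive and span orders of magnitude) with the trust-region reflective
    method.  The first start is the geometric midpoint of the bounds; the
    remaining ``n_starts - 1`` are log-uniform draws seeded by ``seed``, so
    the whole procedure is deterministic given its inputs.

    Parameters whose estimate lands on a bound are flagged in
    ``FitResult.at_bounds``.  Replicate wells may be passed as a sequence;
    their residuals are pooled symmetrically, so the fit is invariant to
    their order.
    """
    obs_list = _as_obs_list(obs)
    for ob in obs_list:
        if len(ob) < 10:
            raise ValidationError(
                f"each observation series needs >= 10 time points, got {len(ob)}"
            )
    _check_growth_signal(obs_list)
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update({k: (float(lo), float(hi)) for k, (lo, hi) in bounds.items()})
    for name in PARAM_NAMES:
        lo, hi = b[name]
        if not (0 < lo < hi):
            raise ValidationError(f"bounds for {name} must satisfy 0 < lo < hi")
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")

    init = initial if initial is not None else _initial_from_data(obs_list)
    lo = np.log10([b[n][0] for n in PARAM_NAMES])
    hi = np.log10([b[n][1] for n in PARAM_NAMES])

    def objective(theta: np.ndarray) -> np.ndarray:
        params = ModelParameters(**dict(zip(PARAM_NAMES, 10.0 ** theta)))
        try:
            return residuals(params, obs_list, scaling, init)
        except NumericError:
            # an unintegrable parameter draw: steer the optimiser away
            n = 2 * sum(len(ob) for ob in obs_list)
            return np.full(n, 1e3)

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    starts += [rng.uniform(lo, hi) for _ in range(n_starts - 1)]

    best = None
    start_costs: list[float] = []
    failures: list[str] = []
    for theta0 in starts:
        try:
            res = least_squares(
                objective, theta0, bounds=(lo, hi), method="trf", x_scale="jac"
            )
        except Exception as e:  # pragma: no cover - defensive
            failures.append(f"start {theta0}: {e}")
            continue
        start_costs.append(float(res.cost))
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FittingError(
            "all multistart attempts failed:\n" + "\n".join(failures)
        )

    values = 10.0 ** best.x
    params = ModelParameters(**dict(zip(PARAM_NAMES, values)))
    at_bounds = {
        name: bool(
            abs(best.x[i] - lo[i]) < 1e-8 or abs(best.x[i] - hi[i]) < 1e-8
        )
        for i, name in enumerate(PARAM_NAMES)
    }
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(best.fun)),
        n_iter=int(best.nfev),
        converged=bool(best.status > 0),
        at_bounds=at_bounds,
        start_costs=tuple(start_costs),
    )
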