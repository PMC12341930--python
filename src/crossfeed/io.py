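"""Readers, writers and run configuration.

CSV is the only tabular interchange format (UTF-8, '.' decimal separator,
header required); calibration curves and fit results are serialized as JSON.
The run configuration is a YAML file with strictly validated sections —
unknown sections or keys are rejected, and the model-parameter section has
no silent defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCurve
from .errors import SchemaError, ValidationError
from .fitting import FitObservations, FitResult
from .model import ConsortiumState, ModelParameters, ScalingFactors
from .simulate import Scenario, Trajectory
from .synth import HPLCSeries, NoiseModel, PlateReaderSeries

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "read_timeseries_csv",
    "write_trajectory_csv",
    "write_fit_json",
    "read_fit_json",
    "write_calibration_json",
    "read_calibration_json",
    "write_summary_csv",
    "load_config",
]

#: Required columns per series kind (optional columns in the second set).
SCHEMAS: dict[str, tuple[set[str], set[str]]] = {
    "plate": ({"time_h", "od600", "gfp_au", "mscarlet_au"}, set()),
    "hplc": ({"time_h", "glucose", "xylose", "cellobiose", "xylobiose"}, set()),
    "obs": ({"time_h", "od_total", "od_x"}, {"weight"}),
    "traj": ({"time_h", "od_x", "od_g"}, {"od_total"}),
}


def _load_frame(path, kind: str) -> pd.DataFrame:
    if kind not in SCHEMAS:
        raise ValidationError(f"unknown series kind: {kind!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path)
    required, optional = SCHEMAS[kind]
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {sorted(missing)} for kind {kind!r}"
        )
    cols = sorted(required) + sorted(optional & set(df.columns))
    df = df[cols]
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.nonzero((bad | df[col].isna()).to_numpy())[0][0])
            raise SchemaError(f"{path}: non-numeric or missing cell at row {row}, column {col!r}")
        if col != "time_h" and (vals < 0).any():
            row = int(np.nonzero((vals < 0).to_numpy())[0][0])
            raise SchemaError(f"{path}: negative value at row {row}, column {col!r}")
        df[col] = vals.astype(float)
    df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
    if df["time_h"].duplicated().any():
        row = int(np.nonzero(df["time_h"].duplicated().to_numpy())[0][0])
        raise SchemaError(f"{path}: duplicate time point at sorted row {row}")
    return df


def read_timeseries_csv(
    path, kind: str
) -> PlateReaderSeries | HPLCSeries | FitObservations | Trajectory:
    """Read and validate a time-series CSV of the given kind.

    ``kind`` is one of ``"plate"``, ``"hplc"``, ``"obs"`` or ``"traj"``;
    rows are sorted by time, and missing columns, non-numeric cells,
    negative signals or duplicate time points raise :class:`SchemaError`
    naming the offending row/column.
    """
    df = _load_frame(path, kind)
    t = df["time_h"].to_numpy()
    if kind == "plate":
        return PlateReaderSeries(
            well=Path(path).stem,
            t=t,
            od600=df["od600"].to_numpy(),
            gfp_au=df["gfp_au"].to_numpy(),
            mscarlet_au=df["mscarlet_au"].to_numpy(),
        )
    if kind == "hplc":
        return HPLCSeries(
            t=t,
            glucose=df["glucose"].to_numpy(),
            xylose=df["xylose"].to_numpy(),
            cellobiose=df["cellobiose"].to_numpy(),
            xylobiose=df["xylobiose"].to_numpy(),
        )
    if kind == "obs":
        return FitObservations(
            t=t,
            od_total=df["od_total"].to_numpy(),
            od_x=df["od_x"].to_numpy(),
            weights=df["weight"].to_numpy() if "weight" in df.columns else None,
        )
    return Trajectory(t=t, X=df["od_x"].to_numpy(), G=df["od_g"].to_numpy())


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def write_fit_json(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_fit_json(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


def write_calibration_json(curve: CalibrationCurve, path) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), indent=2) + "\n")


def read_calibration_json(path) -> CalibrationCurve:
    return CalibrationCurve.from_dict(json.loads(Path(path).read_text()))


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration assembled from a YAML file."""

    params: ModelParameters
    scaling: ScalingFactors
    initial: ConsortiumState
    t_end: float
    dt_out: float
    fitting: dict
    noise: NoiseModel
    hplc: dict

    @property
    def scenario(self) -> Scenario:
        return Scenario(
            params=self.params,
            scaling=self.scaling,
            initial=self.initial,
            t_end=self.t_end,
            dt_out=self.dt_out,
        )


_KNOWN_SECTIONS = {"model", "scaling", "scenario", "fitting", "noise", "hplc"}
_SCENARIO_KEYS = {"X0", "G0", "t_end", "dt_out"}
_FITTING_KEYS = {"n_starts", "seed", "bounds"}
_NOISE_KEYS = {"od_sd", "fluor_sd", "evaporation_rate", "evaporation_start_h", "seed"}
_HPLC_KEYS = {"initial", "conversion", "consumption", "noise_sd", "t_end", "n_points"}


def _check_keys(section: str, d: dict, allowed: set[str]) -> None:
    extra = set(d) - allowed
    if extra:
        raise SchemaError(f"config section {section!r}: unknown key(s) {sorted(extra)}")


def load_config(path) -> RunConfig:
    """Load and strictly validate a YAML run configuration.

    The ``model`` section must spell out all five parameters (no silent
    defaults); ``scaling``, ``scenario``, ``fitting``, ``noise`` and ``hplc``
    are optional and fall back to package defaults.  Unknown sections or
    keys raise :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config root must be a mapping")
    extra = set(raw) - _KNOWN_SECTIONS
    if extra:
        raise SchemaError(f"{path}: unknown config section(s) {sorted(extra)}")
    if "model" not in raw:
        raise SchemaError(f"{path}: required section 'model' is missing")

    try:
        params = ModelParameters.from_dict(dict(raw["model"]))
        scaling = ScalingFactors.from_dict(dict(raw.get("scaling", {})))
    except ValidationError as e:
        raise SchemaError(f"{path}: {e}") from e

    scen = dict(raw.get("scenario", {}))
    _check_keys("scenario", scen, _SCENARIO_KEYS)
    initial = ConsortiumState(
        X=float(scen.get("X0", 0.01)), G=float(scen.get("G0", 0.01))
    )
    t_end = float(scen.get("t_end", 72.0))
    dt_out = float(scen.get("dt_out", 0.5))

    fitting = dict(raw.get("fitting", {}))
    _check_keys("fitting", fitting, _FITTING_KEYS)
    fitting.setdefault("n_starts", 8)
    fitting.setdefault("seed", 0)

    noise_raw = dict(raw.get("noise", {}))
    _check_keys("noise", noise_raw, _NOISE_KEYS)
    noise = NoiseModel(**{k: (int(v) if k == "seed" else float(v)) for k, v in noise_raw.items()})

    hplc = dict(raw.get("hplc", {}))
    _check_keys("hplc", hplc, _HPLC_KEYS)

    return RunConfig(
        params=params,
        scaling=scaling,
        initial=initial,
        t_end=t_end,
        dt_out=dt_out,
        fitting=fitting,
        noise=noise,
        hplc=hplc,
    )
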