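"""File formats: parameter YAML, response/condition/motion CSV.

Every CSV writer prepends a provenance header of ``#``-prefixed comment
lines (package version, the resolved parameters, the seed where one
applies); every reader skips such lines, so writer output round-trips
through the corresponding reader.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .fitting import RESPONSE_COLUMNS, validate_response_table
from .observer import MotionProfile, ObserverParams
from .static_models import MittelstaedtParams, StaticModelParams
from .synth import SynthDesign

__all__ = [
    "load_observer_params",
    "save_observer_params",
    "load_static_params",
    "load_design",
    "read_conditions",
    "read_response_table",
    "write_response_table",
    "read_motion_profile",
    "write_table",
]

PROFILE_COLUMNS = ["t_s", "wx_dps", "wy_dps", "wz_dps", "fx_g", "fy_g", "fz_g"]


def _package_yaml(name: str) -> dict:
    with resources.files("gravitilt").joinpath("params", name).open() as fh:
        return yaml.safe_load(fh)


def load_observer_params(path=None) -> ObserverParams:
    """Observer parameters from YAML (packaged defaults when path is None)."""
    raw = _package_yaml("observer_default.yaml") if path is None else \
        yaml.safe_load(open(path))
    try:
        gains = raw.get("gains", {})
        settle = raw.get("settle", {})
        return ObserverParams(
            tau_canal=float(raw["tau_canal_s"]),
            k_w=float(gains["k_w"]),
            k_f=float(gains["k_f"]),
            k_fw=float(gains["k_fw"]),
            k_wf=float(gains["k_wf"]),
            utricular_weight=float(raw["utricular_weight"]),
            theta_utricle_deg=float(raw["theta_utricle_deg"]),
            dt=float(raw.get("dt_s", 0.01)),
            settle_time=float(settle.get("time_s", 60.0)),
            settle_tol=float(settle.get("tol_dps", 1e-3)),
            max_horizon=float(raw.get("max_horizon_s", 300.0)),
        )
    except KeyError as exc:
        raise SchemaError(f"observer parameter file missing key {exc}") from None


def save_observer_params(params: ObserverParams, path) -> None:
    doc = {
        "tau_canal_s": params.tau_canal,
        "gains": {"k_w": params.k_w, "k_f": params.k_f,
                  "k_fw": params.k_fw, "k_wf": params.k_wf},
        "utricular_weight": params.utricular_weight,
        "theta_utricle_deg": params.theta_utricle_deg,
        "dt_s": params.dt,
        "settle": {"time_s": params.settle_time, "tol_dps": params.settle_tol},
        "max_horizon_s": params.max_horizon,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_static_params(path=None):
    """Static-model name and parameter objects from YAML.

    Returns ``(model_name, {"modshear"|"shear": StaticModelParams,
    "mittelstaedt": MittelstaedtParams})``-style pair: the named model plus
    the parameter object appropriate for it (None for the tangent model).
    """
    raw = _package_yaml("static_default.yaml") if path is None else \
        yaml.safe_load(open(path))
    model = raw.get("model", "modshear")
    if model in ("modshear", "shear"):
        params = StaticModelParams(
            K=float(raw.get("K", 64.6)),
            M=float(raw.get("M", 0.26)),
            rho=float(raw.get("rho", -0.29)),
            theta_utricle_deg=float(raw.get("theta_utricle_deg", 30.0)),
        )
    elif model == "mittelstaedt":
        params = MittelstaedtParams(
            idiotropic_magnitude=float(raw.get("idiotropic_magnitude", 0.1)),
            theta_utricle_deg=float(raw.get("theta_utricle_deg", 30.0)),
            transduction_exponent=float(raw.get("transduction_exponent", 1.0)),
        )
    elif model == "tangent":
        params = None
    else:
        raise SchemaError(f"unknown model {model!r} in parameter file")
    return model, params


def load_design(path=None) -> SynthDesign:
    """Synthetic-experiment design from YAML (defaults when path is None)."""
    if path is None:
        return SynthDesign()
    raw = yaml.safe_load(open(path)) or {}
    kwargs = {}
    for key in ("n_subjects", "reps_per_condition", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for key in ("subject_intercept_sd", "trial_noise_sd", "true_K", "true_M"):
        if key in raw:
            kwargs[key] = float(raw[key])
    for key in ("angles_deg", "g_levels"):
        if key in raw:
            kwargs[key] = tuple(float(v) for v in raw[key])
    return SynthDesign(**kwargs)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CSV with a ``#`` provenance header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# gravitilt {__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def read_conditions(path) -> pd.DataFrame:
    """Condition grid CSV: axis, angle_deg, g_level."""
    df = _read_csv(path)
    missing = [c for c in ("axis", "angle_deg", "g_level") if c not in df.columns]
    if missing:
        raise SchemaError(f"condition file missing columns {missing}")
    return df


def read_response_table(path) -> pd.DataFrame:
    return validate_response_table(_read_csv(path))


def write_response_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(validate_response_table(df), path, meta)


def read_motion_profile(path) -> MotionProfile:
    """Motion profile CSV with uniform time; validated."""
    df = _read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"motion profile missing columns {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError("motion profile needs at least 2 samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9) or dts[0] <= 0:
        raise SchemaError("motion profile time base must be uniform and increasing")
    return MotionProfile(
        dt=float(dts[0]),
        omega=df[["wx_dps", "wy_dps", "wz_dps"]].to_numpy(dtype=float),
        f=df[["fx_g", "fy_g", "fz_g"]].to_numpy(dtype=float),
    )
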