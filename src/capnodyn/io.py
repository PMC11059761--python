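"""CSV/JSON readers and writers with embedded provenance.

Schemas are fixed and unit-suffixed (``*_ml``, ``*_mmHg``, ``*_s``) so a
feature table produced by the simulator, by the capnograph pipeline or by
an external recorder is interchangeable at the solver. Every file starts
with comment lines carrying the package version and the serialized
:class:`~capnodyn.config.RunConfig` that produced it.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .capno import BreathFeatures, BreathSignal
from .config import DEFAULT_CONFIG, VERSION, RunConfig
from .simulator import BreathRecord
from .solver import CapnoEstimate

FEATURE_COLUMNS = [
    "index", "dt_s", "hold_flag", "faco2", "vtco2_ml", "vt_ml", "vdaw_ml",
]
ESTIMATE_COLUMNS = [
    "breath_index", "eelv_raw_ml", "eelv_corr_ml", "epbf_lpm", "cvco2",
    "fit_error_mmHg", "valid",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _header(config: RunConfig) -> str:
    return f"# {VERSION}\n# config: {config.to_json()}\n"


def _write_csv(df: pd.DataFrame, path: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False)


def _read_csv(path: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


# -- per-breath feature tables ---------------------------------------------

def write_feature_csv(
    records: list[BreathRecord],
    path: str,
    vt: float,
    vdaw: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> None:
    """Write simulator records as a solver-ready feature table."""
    df = pd.DataFrame({
        "index": [r.index for r in records],
        "dt_s": [r.dt * 60.0 for r in records],
        "hold_flag": [int(r.hold) for r in records],
        "faco2": [r.faco2 for r in records],
        "vtco2_ml": [r.vtco2 * 1000.0 for r in records],
        "vt_ml": [vt * 1000.0] * len(records),
        "vdaw_ml": [vdaw * 1000.0] * len(records),
    })
    _write_csv(df, path, config)


def write_features_from_capno(
    features: list[BreathFeatures], path: str, config: RunConfig = DEFAULT_CONFIG
) -> None:
    """Write capnograph-derived features (adds PET/PE CO2 columns)."""
    df = pd.DataFrame({
        "index": np.arange(len(features)),
        "dt_s": [f.dt * 60.0 for f in features],
        "hold_flag": [0] * len(features),
        "faco2": [f.faco2 for f in features],
        "vtco2_ml": [f.vtco2 * 1000.0 for f in features],
        "vt_ml": [f.vt_exp * 1000.0 for f in features],
        "vdaw_ml": [f.vdaw * 1000.0 for f in features],
        "petco2_mmHg": [f.petco2 for f in features],
        "peco2_mmHg": [f.peco2 for f in features],
        "valid": [int(f.valid) for f in features],
    })
    _write_csv(df, path, config)


def read_feature_csv(path: str) -> list[BreathFeatures]:
    """Read a feature table into the solver's input type."""
    df = _read_csv(path, ["dt_s", "faco2", "vtco2_ml", "vdaw_ml"])
    vt = df["vt_ml"] if "vt_ml" in df.columns else df["vtco2_ml"] * 0 + np.nan
    out = []
    for i in range(len(df)):
        row = df.iloc[i]
        out.append(BreathFeatures(
            faco2=float(row["faco2"]),
            vtco2=float(row["vtco2_ml"]) / 1000.0,
            dt=float(row["dt_s"]) / 60.0,
            vt_exp=float(vt.iloc[i]) / 1000.0,
            vdaw=float(row["vdaw_ml"]) / 1000.0,
            petco2=float(row.get("petco2_mmHg", np.nan)),
            peco2=float(row.get("peco2_mmHg", np.nan)),
            valid=bool(row.get("valid", 1)),
        ))
    return out


# -- waveforms -------------------------------------------------------------

def write_waveform_csv(
    signal: BreathSignal, path: str, config: RunConfig = DEFAULT_CONFIG
) -> None:
    df = pd.DataFrame({
        "time_s": signal.t, "flow_lps": signal.flow, "fco2": signal.fco2,
    })
    _write_csv(df, path, config)


def read_waveform_csv(path: str) -> BreathSignal:
    df = _read_csv(path, ["time_s", "flow_lps", "fco2"])
    return BreathSignal(
        t=df["time_s"].to_numpy(),
        flow=df["flow_lps"].to_numpy(),
        fco2=df["fco2"].to_numpy(),
    )


# -- estimates -------------------------------------------------------------

def write_estimate_csv(
    estimates: list[CapnoEstimate], path: str, config: RunConfig = DEFAULT_CONFIG
) -> None:
    df = pd.DataFrame({
        "breath_index": [e.window_end_index for e in estimates],
        "eelv_raw_ml": [e.eelv_raw * 1000.0 for e in estimates],
        "eelv_corr_ml": [e.eelv_corr * 1000.0 for e in estimates],
        "epbf_lpm": [e.epbf for e in estimates],
        "cvco2": [e.cvco2 for e in estimates],
        "fit_error_mmHg": [e.fit_error for e in estimates],
        "valid": [int(e.valid) for e in estimates],
    })
    _write_csv(df, path, config)


def read_pairs_csv(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Paired method/reference values for agreement analysis."""
    df = _read_csv(path, ["method_ml", "reference_ml"])
    return df["method_ml"].to_numpy(float), df["reference_ml"].to_numpy(float)


def write_json(payload: dict, path: str, config: RunConfig = DEFAULT_CONFIG) -> None:
    payload = dict(payload)
    payload.setdefault("provenance", {})
    payload["provenance"].update({"version": VERSION, "config": config.to_dict()})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
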