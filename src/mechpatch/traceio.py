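"""CSV/JSON file formats for traces, fields and configuration.

Traces are stored as plain CSV with the header
``time_ms,pressure_mmHg,voltage_mV,current_pA`` plus a JSON sidecar
(``<name>.meta.json``) carrying protocol, ground truth and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import PatchTrace

__all__ = [
    "TRACE_COLUMNS",
    "write_trace",
    "read_trace",
    "write_field_csv",
    "read_field_csv",
    "load_json",
    "dump_json",
    "config_hash",
]

TRACE_COLUMNS = ("time_ms", "pressure_mmHg", "voltage_mV", "current_pA")
FLOAT_FORMAT = "%.6g"


def _jsonable(obj):
    """Make numpy containers JSON-serialisable."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(trace: PatchTrace, path: str | Path, metadata: bool = True) -> Path:
    """Write a trace as CSV (+ JSON sidecar with its metadata)."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_ms": trace.time,
            "pressure_mmHg": trace.pressure,
            "voltage_mV": trace.voltage,
            "current_pA": trace.current,
        }
    )
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if metadata and trace.metadata:
        meta = {k: v for k, v in trace.metadata.items() if k != "n_open"}
        _sidecar(path).write_text(json.dumps(_jsonable(meta), indent=2))
    return path


def read_trace(path: str | Path) -> PatchTrace:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trace file {path} is missing columns: {sorted(missing)}")
    metadata = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return PatchTrace(
        time=frame["time_ms"].to_numpy(float),
        pressure=frame["pressure_mmHg"].to_numpy(float),
        voltage=frame["voltage_mV"].to_numpy(float),
        current=frame["current_pA"].to_numpy(float),
        metadata=metadata,
    )


def write_field_csv(field, path: str | Path) -> Path:
    """Write channel coordinates as ``x_um,y_um,parent_id``."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "x_um": field.points[:, 0],
            "y_um": field.points[:, 1],
            "parent_id": field.parent_index,
        }
    )
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def read_field_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read channel coordinates; returns (points, parent_index)."""
    frame = pd.read_csv(path)
    points = frame[["x_um", "y_um"]].to_numpy(float)
    return points, frame["parent_id"].to_numpy(int)


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def dump_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
    return path


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict."""
    canon = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:12]
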