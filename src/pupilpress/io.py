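"""File formats: area-series CSV, measurement-table CSV, JSON configs.

All dialects round-trip exactly; unknown columns and config keys are
preserved or warned about, never silently dropped as errors.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import ProtocolConfig
from .series import AreaTimeSeries, PHASES
from .study import MEASUREMENT_COLUMNS, SESSIONS

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "write_series",
    "read_series",
    "write_measurements",
    "read_measurements",
    "read_config",
]


class SchemaError(ValueError):
    """A CSV/JSON input violates its declared schema."""


def write_series(
    series: AreaTimeSeries, path: str | Path, protocol: ProtocolConfig | None = None
) -> Path:
    """Write an area series as CSV (`time_s,area_mm2,phase`) + JSON sidecar."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    sidecar = {
        "fps": series.fps,
        "flash_on_s": series.flash_on_s,
        "flash_off_s": series.flash_off_s,
    }
    if protocol is not None:
        sidecar["protocol"] = protocol.to_dict()
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path: str | Path) -> AreaTimeSeries:
    """Read an area-series CSV written by :func:`write_series`."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["time_s", "area_mm2", "phase"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad = df.index[~df["phase"].isin(PHASES)]
    if len(bad):
        raise SchemaError(
            f"{path}: invalid phase at data row(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fps = meta["fps"]
        flash_on, flash_off = meta["flash_on_s"], meta["flash_off_s"]
    else:  # infer from the data itself
        t = df["time_s"].to_numpy()
        fps = 1.0 / float(np.median(np.diff(t)))
        flash = df["phase"] == "flash"
        if not flash.any():
            raise SchemaError(f"{path}: no sidecar and no flash phase to infer markers")
        flash_on = float(df.loc[flash, "time_s"].iloc[0])
        rec = df["phase"] == "recovery"
        flash_off = (
            float(df.loc[rec, "time_s"].iloc[0])
            if rec.any()
            else float(df.loc[flash, "time_s"].iloc[-1]) + 1.0 / fps
        )
    return AreaTimeSeries(
        time_s=df["time_s"].to_numpy(),
        area_mm2=df["area_mm2"].to_numpy(),
        phase=df["phase"].to_numpy(),
        fps=fps,
        flash_on_s=flash_on,
        flash_off_s=flash_off,
    )


def write_measurements(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a measurement table as CSV, schema-checked first."""
    _check_measurements(table, str(path))
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def _check_measurements(df: pd.DataFrame, source: str) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")
    bad_session = df.index[~df["session"].isin(SESSIONS)]
    if len(bad_session):
        raise SchemaError(
            f"{source}: unknown session at data row(s) "
            f"{[int(i) + 2 for i in bad_session[:5]]}"
        )
    if not np.issubdtype(df["iop_mmHg"].dtype, np.number) or df["iop_mmHg"].isna().any():
        bad = df.index[pd.to_numeric(df["iop_mmHg"], errors="coerce").isna()]
        raise SchemaError(
            f"{source}: non-numeric iop_mmHg at data row(s) "
            f"{[int(i) + 2 for i in bad[:5]]}"
        )


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement-table CSV.

    Unknown columns are preserved; schema violations raise
    :class:`SchemaError` naming the offending column or data rows
    (1-based line numbers including the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_measurements(df, str(path))
    df["is_calibration"] = df["is_calibration"].astype(bool)
    return df


def read_config(path: str | Path, known_keys: set[str] | None = None) -> dict:
    """Read a JSON config; unknown top-level keys warn, never error."""
    path = Path(path)
    cfg = json.loads(path.read_text())
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a JSON object")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            warnings.warn(
                f"{path}: ignoring unknown config key(s) {sorted(unknown)}",
                stacklevel=2,
            )
    return cfg
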