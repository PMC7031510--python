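"""Plain-text file formats: trace CSVs with JSON sidecars, fits/features
tables, similarity matrices.  Column layouts are documented in FORMATS.md."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from hvcx.hh import Trace
from hvcx.popstats import G_COLUMNS

__all__ = [
    "write_trace",
    "read_trace",
    "write_fits_table",
    "read_fits_table",
    "write_similarity",
    "read_similarity",
]

FITS_COLUMNS = ["neuron_id", "bird_id", *G_COLUMNS, "error", "disregarded_count"]


def write_trace(trace: Trace, path: str | Path) -> Path:
    """CSV with header time_ms,voltage_mV,current_pA plus a ``.meta.json``
    sidecar carrying the protocol and provenance metadata."""
    path = Path(path)
    df = pd.DataFrame({"time_ms": trace.t, "voltage_mV": trace.v, "current_pA": trace.i})
    df.to_csv(path, index=False, float_format="%.8g")
    meta = {k: v for k, v in trace.meta.items()}
    meta["dt_ms"] = trace.dt
    sidecar = path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" else path.with_name(path.stem + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1, default=float))
    return path


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_name(path.stem + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Trace(
        t=df["time_ms"].to_numpy(float),
        v=df["voltage_mV"].to_numpy(float),
        i=df["current_pA"].to_numpy(float),
        meta=meta,
    )


def write_fits_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in FITS_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)
    return path


def read_fits_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("neuron_id", "bird_id", *G_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"fits table missing columns: {missing}")
    return df


def write_similarity(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(Path(path), index_label="bird_id")
    return Path(path)


def read_similarity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df
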