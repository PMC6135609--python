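"""Plain-text persistence of trace series.

A series is written as a directory: one CSV per trace (columns ``time_s``,
``anisotropy``) plus a YAML manifest recording the scheme, calibration,
instrument settings, and per-trace metadata (all concentrations in nM).
Unknown metadata keys are preserved so that externally annotated series
survive a round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import Scheme
from .simulate import AnisotropyCalibration, InstrumentSpec, Trace, TraceSeries

__all__ = ["write_series", "read_series", "MANIFEST_NAME"]

MANIFEST_NAME = "series.yaml"
FORMAT = "parpflow-series/1"


def _plain(value):
    """Convert numpy scalars to YAML-friendly builtins."""
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


def write_series(series: TraceSeries, path) -> Path:
    """Write a series to directory ``path``; returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, trace in enumerate(series.traces):
        fname = f"trace_{i:03d}.csv"
        df = pd.DataFrame({"time_s": trace.times, "anisotropy": trace.values})
        df.to_csv(path / fname, index=False, float_format="%.17g")
        entries.append({"file": fname, "meta": _plain(trace.meta)})
    manifest = {
        "format": FORMAT,
        "units": {"time": "s", "signal": "anisotropy", "concentration": "nM"},
        "scheme": series.scheme.value,
        "calibration": {
            "r_free": series.calibration.r_free,
            "r_bound": series.calibration.r_bound,
        },
        "instrument": _plain(series.instrument.as_dict()),
        "meta": _plain(series.meta),
        "traces": entries,
    }
    manifest_path = path / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_series(path) -> TraceSeries:
    """Read a series directory written by :func:`write_series`."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME if path.is_dir() else path
    if not manifest_path.exists():
        raise FileNotFoundError(f"series manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("scheme", "calibration", "instrument", "traces"):
        if key not in manifest:
            raise ValueError(f"manifest {manifest_path} is missing field {key!r}")
    base = manifest_path.parent
    traces = []
    for entry in manifest["traces"]:
        fname = entry.get("file")
        csv_path = base / fname
        if not csv_path.exists():
            raise FileNotFoundError(
                f"manifest lists trace file {fname!r} but it does not exist in {base}"
            )
        try:
            df = pd.read_csv(csv_path, float_precision="round_trip")
        except Exception as exc:
            raise ValueError(f"could not parse trace file {fname!r}: {exc}") from exc
        for col in ("time_s", "anisotropy"):
            if col not in df.columns:
                raise ValueError(
                    f"trace file {fname!r} is missing required column {col!r}"
                )
        for col in ("time_s", "anisotropy"):
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))].index
                line = int(bad[0]) + 2 if len(bad) else "?"
                raise ValueError(
                    f"trace file {fname!r}: non-numeric value in column {col!r} "
                    f"near line {line}"
                )
        traces.append(
            Trace(
                times=df["time_s"].to_numpy(),
                values=df["anisotropy"].to_numpy(),
                meta=dict(entry.get("meta", {})),
            )
        )
    return TraceSeries(
        traces=traces,
        scheme=Scheme.parse(manifest["scheme"]),
        calibration=AnisotropyCalibration(**manifest["calibration"]),
        instrument=InstrumentSpec(**manifest["instrument"]),
        meta=dict(manifest.get("meta", {})),
    )
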