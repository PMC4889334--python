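"""CSV/JSON/YAML I/O for traces, trajectories, truth records and manifests.

Trace files use a single flat schema shared by intensity traces and 2D
tracks: columns ``dataset_id, mrna_id, time_s, green, red, x_um, y_um``
(unused columns left empty).
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import IntensityTrace, Trajectory2D

__all__ = [
    "TRACE_COLUMNS",
    "write_traces",
    "write_tracks",
    "read_traces",
    "read_tracks",
    "write_json",
    "read_json",
    "load_scenario_config",
    "write_manifest",
]

TRACE_COLUMNS = ["dataset_id", "mrna_id", "time_s", "green", "red", "x_um", "y_um"]


def traces_to_frame(traces: Sequence[IntensityTrace], dataset_id: str = "dataset") -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "dataset_id": dataset_id,
                    "mrna_id": tr.mrna_id,
                    "time_s": tr.times,
                    "green": tr.green,
                    "red": tr.red,
                    "x_um": np.nan,
                    "y_um": np.nan,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TRACE_COLUMNS)


def tracks_to_frame(tracks: Sequence[Trajectory2D], dataset_id: str = "dataset") -> pd.DataFrame:
    rows = []
    for t in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "dataset_id": dataset_id,
                    "mrna_id": t.mrna_id,
                    "time_s": t.times,
                    "green": np.nan,
                    "red": np.nan,
                    "x_um": t.x_um,
                    "y_um": t.y_um,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TRACE_COLUMNS)


def write_traces(traces: Sequence[IntensityTrace], path: str | Path, dataset_id: str = "dataset") -> None:
    traces_to_frame(traces, dataset_id).to_csv(path, index=False, float_format="%.8g")


def write_tracks(tracks: Sequence[Trajectory2D], path: str | Path, dataset_id: str = "dataset") -> None:
    tracks_to_frame(tracks, dataset_id).to_csv(path, index=False, float_format="%.8g")


def _validated_frame(path: str | Path, needed: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"trace file {path} is missing required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"trace file {path} contains no rows")
    return df


def read_traces(path: str | Path) -> list[IntensityTrace]:
    """Read intensity traces grouped by mrna_id (order of first appearance)."""
    df = _validated_frame(path, ["mrna_id", "time_s", "green"])
    traces = []
    for mid, g in df.groupby("mrna_id", sort=False):
        times = g["time_s"].to_numpy(dtype=float)
        dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
        red = g["red"].to_numpy(dtype=float) if "red" in g else np.zeros_like(times)
        red = np.nan_to_num(red)
        traces.append(
            IntensityTrace(
                mrna_id=str(mid),
                times=times,
                green=g["green"].to_numpy(dtype=float),
                red=red,
                frame_interval_s=dt,
            )
        )
    return traces


def read_tracks(path: str | Path) -> list[Trajectory2D]:
    df = _validated_frame(path, ["mrna_id", "time_s", "x_um", "y_um"])
    tracks = []
    for mid, g in df.groupby("mrna_id", sort=False):
        tracks.append(
            Trajectory2D(
                mrna_id=str(mid),
                times=g["time_s"].to_numpy(dtype=float),
                x_um=g["x_um"].to_numpy(dtype=float),
                y_um=g["y_um"].to_numpy(dtype=float),
            )
        )
    return tracks


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def load_scenario_config(path: str | Path):
    """Load a ScenarioConfig from a YAML (or JSON) file."""
    from .synthetic import ScenarioConfig

    path = Path(path)
    data = read_json(path) if path.suffix == ".json" else yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "scenario" not in data:
        raise ValueError("scenario config must be a mapping with a 'scenario' key")
    return ScenarioConfig(**data)


def write_manifest(path: str | Path, command: str, config: dict, seed, outputs: dict,
                   wall_time_s: float, extra: dict | None = None) -> None:
    from importlib.metadata import version

    try:
        pkg_version = version("ribotrace")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "command": command,
        "package_version": pkg_version,
        "seed": seed,
        "config": config,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "wall_time_s": wall_time_s,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    write_json(manifest, path)
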