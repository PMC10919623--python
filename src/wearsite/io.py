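"""CSV/JSON artifact I/O.

All artifacts are plain text: recordings as ``t,x,y,z`` CSV (seconds and g),
calorimetry as ``t,vo2`` CSV, profiles as CSV, and a session manifest as
JSON linking participants, wear-sites, files, seeds, bout annotations and
latent per-bout MET draws.  Every writer prepends a ``# config_hash:``
comment so artifacts are traceable to the run configuration; readers skip
``#`` comment lines.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import (CalorimetrySeries, ParticipantProfile,
                        TriaxialRecording)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str | None,
               float_format: str = "%.6f") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format=float_format, lineterminator="\n")


def write_recording(recording: TriaxialRecording, path,
                    config_hash: str | None = None) -> None:
    df = pd.DataFrame({"t": recording.t, "x": recording.xyz[:, 0],
                       "y": recording.xyz[:, 1], "z": recording.xyz[:, 2]})
    _write_csv(df, Path(path), config_hash)


def read_recording(path, site: str, sample_rate: float | None = None,
                   bout_annotations: list | None = None) -> TriaxialRecording:
    """Read a ``t,x,y,z`` CSV; malformed or non-monotone rows are rejected
    with their line number."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    expected = ["t", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, "
                         f"got {list(df.columns)}")
    bad = df.isna().any(axis=1)
    if bad.any():
        line = int(np.argmax(bad.values)) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: malformed row at line {line}")
    t = df["t"].to_numpy(dtype=np.float64)
    if t.size == 0:
        logging.getLogger("wearsite").warning("%s: header-only file, "
                                              "empty recording", path)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.argmax(dt <= 0)) + 3
            raise ValueError(
                f"{path}: non-increasing timestamp at line {line}")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 100.0
    return TriaxialRecording(
        site=site, sample_rate=float(np.round(sample_rate, 6)), t=t,
        xyz=df[["x", "y", "z"]].to_numpy(dtype=np.float32),
        bout_annotations=list(bout_annotations or []))


def write_calorimetry(series: CalorimetrySeries, path,
                      config_hash: str | None = None) -> None:
    _write_csv(pd.DataFrame({"t": series.t, "vo2": series.vo2}), Path(path),
               config_hash, float_format="%.4f")


def read_calorimetry(path, rest_start: float = 0.0,
                     rest_end: float = 600.0) -> CalorimetrySeries:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != ["t", "vo2"]:
        raise ValueError(f"{path}: expected columns ['t', 'vo2']")
    t = df["t"].to_numpy(dtype=np.float64)
    interval = float(np.median(np.diff(t))) if t.size > 1 else 5.0
    return CalorimetrySeries(interval=interval, t=t,
                             vo2=df["vo2"].to_numpy(dtype=np.float64),
                             rest_start=rest_start, rest_end=rest_end)


def write_profiles(profiles: list[ParticipantProfile], path,
                   config_hash: str | None = None) -> None:
    df = pd.DataFrame([{"id": p.id, "group": p.group, "sex": p.sex,
                        "age": p.age, "height": p.height, "weight": p.weight,
                        "resting_vo2": p.resting_vo2} for p in profiles])
    _write_csv(df, Path(path), config_hash, float_format="%.4f")


def read_profiles(path) -> list[ParticipantProfile]:
    df = pd.read_csv(path, comment="#")
    return [ParticipantProfile(id=str(r.id), group=str(r.group),
                               sex=str(r.sex), age=float(r.age),
                               height=float(r.height), weight=float(r.weight),
                               resting_vo2=float(r.resting_vo2))
            for r in df.itertuples()]


def write_manifest(manifest: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
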