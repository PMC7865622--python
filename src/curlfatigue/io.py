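"""Reading and writing session recordings and derived tables.

A session is stored as one CSV of samples (``t``, the nine IMU channels,
``heart_rate`` and, if computed, the two derived signals) plus a JSON
sidecar carrying the metadata (subject, arm, sampling rate, 0-based
half-open set boundaries, per-set reported RPE, dumbbell mass).  Externally
supplied recordings converted to this schema are read the same way.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .simulate import IMU_CHANNELS, SessionRecording

__all__ = [
    "write_session",
    "read_session",
    "write_ground_truth",
    "read_ground_truth",
    "write_feature_matrix",
    "read_feature_matrix",
    "session_paths",
]

SAMPLE_COLUMNS = ("t",) + tuple(IMU_CHANNELS) + ("heart_rate",)
_FLOAT_FORMAT = "%.12g"


def session_paths(directory: str | Path, subject_id: str, arm: str) -> tuple[Path, Path]:
    base = Path(directory) / f"{subject_id}_{arm}"
    return base.with_suffix(".csv"), base.with_suffix(".json")


def write_session(session: SessionRecording, directory: str | Path) -> tuple[Path, Path]:
    """Write one session as CSV + JSON sidecar; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path, meta_path = session_paths(directory, session.subject_id, session.arm)
    session.samples.to_csv(csv_path, index=False, float_format=_FLOAT_FORMAT)
    meta = {
        "subject_id": session.subject_id,
        "arm": session.arm,
        "sampling_rate": session.sampling_rate,
        "set_boundaries": [list(b) for b in session.set_boundaries],
        "reported_rpe": list(map(int, session.reported_rpe)),
        "dumbbell_mass": session.dumbbell_mass,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return csv_path, meta_path


def read_session(csv_path: str | Path, meta_path: str | Path | None = None) -> SessionRecording:
    """Read a session from its CSV and JSON sidecar."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    samples = pd.read_csv(csv_path)
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"session CSV {csv_path} missing columns: {missing}")
    return SessionRecording(
        subject_id=str(meta["subject_id"]),
        arm=str(meta["arm"]),
        sampling_rate=float(meta["sampling_rate"]),
        samples=samples,
        set_boundaries=[tuple(b) for b in meta["set_boundaries"]],
        reported_rpe=[int(r) for r in meta["reported_rpe"]],
        dumbbell_mass=float(meta["dumbbell_mass"]),
    )


def read_sessions(directory: str | Path) -> list[SessionRecording]:
    """All sessions found in a directory (every CSV with a JSON sidecar)."""
    directory = Path(directory)
    sessions = []
    for csv_path in sorted(directory.glob("*.csv")):
        meta_path = csv_path.with_suffix(".json")
        if meta_path.exists():
            sessions.append(read_session(csv_path, meta_path))
    if not sessions:
        raise FileNotFoundError(f"no session CSV/JSON pairs under {directory}")
    return sessions


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
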