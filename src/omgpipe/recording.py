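"""In-memory containers for one participant-session and their CSV/JSON round trip.

A :class:`SensorRecording` holds the 18 raw displacement streams (mm) sampled
uniformly at 50 Hz, per-sample condition labels, and the list of labelled
expression events (half-open sample intervals).  On disk a recording is a CSV
(``time_s`` + 18 stream columns + label columns) with a JSON sidecar carrying
the participant profile, protocol and event table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab

log = logging.getLogger(__name__)


class RecordingParseError(ValueError):
    """A recording file violates the on-disk contract."""


@dataclass(frozen=True)
class ExpressionEvent:
    """One labelled expression instance over samples ``[start, end)``."""

    expression: str
    start: int
    end: int
    intensity: str
    duration: str
    head_movement: str = "none"
    glasses_position: str = "medium"
    task: str = "A"

    def __post_init__(self) -> None:
        if self.expression not in vocab.EXPRESSIONS:
            raise ValueError(f"unknown expression {self.expression!r}")
        if self.end <= self.start:
            raise ValueError("event must satisfy end > start")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {
            "expression": self.expression,
            "start": int(self.start),
            "end": int(self.end),
            "intensity": self.intensity,
            "duration": self.duration,
            "head_movement": self.head_movement,
            "glasses_position": self.glasses_position,
            "task": self.task,
        }


@dataclass
class SensorRecording:
    """One participant-session: timestamps, 18 streams, labels and events."""

    participant_id: str
    timestamps: np.ndarray  # seconds, uniform 50 Hz
    data: pd.DataFrame  # columns = vocab.STREAMS, mm
    labels: pd.DataFrame  # columns = vocab.LABEL_COLUMNS
    events: list[ExpressionEvent] = field(default_factory=list)
    profile: dict | None = None
    sampling_rate_hz: float = vocab.SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if len(self.data) != n or len(self.labels) != n:
            raise ValueError("streams, labels and timestamps must have equal length")
        missing = [c for c in vocab.STREAMS if c not in self.data.columns]
        if missing:
            raise RecordingParseError(f"missing stream columns: {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    def stream(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def site_xyz(self, site: str) -> np.ndarray:
        """(n, 3) array of a site's three displacement axes."""
        cols = [f"{site}_{a}" for a in vocab.AXES]
        return self.data[cols].to_numpy()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(recording: SensorRecording, path: str | Path) -> Path:
    """Write a recording as CSV plus a ``<path>.json`` sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({"time_s": recording.timestamps})
    for col in vocab.STREAMS:
        frame[col] = recording.data[col].to_numpy()
    for col in vocab.LABEL_COLUMNS:
        frame[col] = recording.labels[col].to_numpy()
    frame.to_csv(path, index=False, float_format="%.17g")  # exact float64 round trip
    sidecar = {
        "participant_id": recording.participant_id,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "profile": recording.profile,
        "events": [e.to_dict() for e in recording.events],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


_LABEL_VOCAB = {
    "expression": set(vocab.CLASSES),
    "intensity": set(vocab.INTENSITIES) | {"none"},
    "duration": set(vocab.DURATION_CLASSES) | {"none"},
    "head_movement": set(vocab.HEAD_MOVEMENTS),
    "glasses_position": set(vocab.GLASSES_POSITIONS),
    "task": set(vocab.TASKS),
}


def read_recording(path: str | Path) -> SensorRecording:
    """Read a CSV recording (and its JSON sidecar, if present) back into memory.

    Unknown extra columns are preserved on ``data`` but ignored downstream, with
    a logged warning; missing required streams, non-uniform timestamps and
    out-of-vocabulary labels raise :class:`RecordingParseError` naming the
    offending column.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in frame.columns:
        raise RecordingParseError("missing required column 'time_s'")
    missing = [c for c in vocab.STREAMS if c not in frame.columns]
    if missing:
        raise RecordingParseError(f"missing stream column(s): {', '.join(missing)}")
    missing_lab = [c for c in vocab.LABEL_COLUMNS if c not in frame.columns]
    if missing_lab:
        raise RecordingParseError(f"missing label column(s): {', '.join(missing_lab)}")

    t = frame["time_s"].to_numpy(float)
    if len(t) >= 2:
        steps = np.diff(t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-6):
            raise RecordingParseError("column 'time_s' is not strictly increasing and uniform")

    for col, allowed in _LABEL_VOCAB.items():
        bad = set(frame[col].astype(str).unique()) - allowed
        if bad:
            raise RecordingParseError(f"column {col!r} contains unknown label(s): {sorted(bad)}")

    known = {"time_s", *vocab.STREAMS, *vocab.LABEL_COLUMNS}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        log.warning("ignoring unknown column(s) in %s: %s", path.name, extra)
        warnings.warn(f"ignoring unknown column(s): {extra}", stacklevel=2)

    participant_id = path.stem
    profile = None
    events: list[ExpressionEvent] = []
    sampling = vocab.SAMPLING_RATE_HZ
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        participant_id = meta.get("participant_id", participant_id)
        profile = meta.get("profile")
        sampling = meta.get("sampling_rate_hz", sampling)
        events = [ExpressionEvent(**e) for e in meta.get("events", [])]

    return SensorRecording(
        participant_id=participant_id,
        timestamps=t,
        data=pd.concat(
            [frame[list(vocab.STREAMS)].astype(float), frame[extra]], axis=1
        )
        if extra
        else frame[list(vocab.STREAMS)].astype(float),
        labels=frame[list(vocab.LABEL_COLUMNS)].astype(str),
        events=events,
        profile=profile,
        sampling_rate_hz=sampling,
    )
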