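"""Windowed statistical feature extraction for expression recognition.

Each of the 18 preprocessed streams is cut into contiguous, non-overlapping
0.1 s windows (5 samples at 50 Hz) and summarised by nine statistics —
mean, standard deviation, minimum, maximum, range, interquartile range,
kurtosis, skewness and root mean square — giving 18 x 9 = 162 features per
window.  Windows are labelled by per-sample majority (ties broken in favour
of the non-neutral class) and carry the condition metadata of their samples.
Finally each participant's feature block is standardized to zero mean and
unit variance per feature.

Conventions: standard deviation and the higher moments are the
bias-uncorrected (population) estimators; kurtosis is excess kurtosis
(Gaussian -> 0); skewness and kurtosis of a zero-variance window are defined
as 0; the interquartile range uses the linear-interpolation quantile rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vocab
from .preprocessing import FilterSpec, preprocess_for_ml
from .recording import SensorRecording

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "std",
    "min",
    "max",
    "range",
    "iqr",
    "kurtosis",
    "skewness",
    "rms",
)

METADATA_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "label",
    "intensity",
    "duration",
    "head_movement",
    "glasses_position",
    "task",
)


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping sliding window (stride equals window length)."""

    window_s: float = 0.1
    stride_s: float = 0.1

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise FeatureError("window length must be positive")
        if abs(self.stride_s - self.window_s) > 1e-12:
            raise FeatureError("stride must equal window length (no overlap)")

    def samples(self, fs: float = vocab.SAMPLING_RATE_HZ) -> int:
        n = round(self.window_s * fs)
        if n < 2:
            raise FeatureError("window must contain at least 2 samples")
        return n


def feature_columns() -> list[str]:
    return [f"{stream}__{feat}" for stream in vocab.STREAMS for feat in FEATURE_NAMES]


def segment(streams: np.ndarray, spec: WindowSpec, fs: float = vocab.SAMPLING_RATE_HZ) -> np.ndarray:
    """Cut (n, k) streams into (n_windows, w, k) contiguous windows.

    The trailing remainder shorter than one window is dropped (floor policy).
    """
    arr = np.asarray(streams, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    w = spec.samples(fs)
    n_windows = arr.shape[0] // w
    if n_windows < 1:
        raise FeatureError("stream shorter than one window")
    return arr[: n_windows * w].reshape(n_windows, w, arr.shape[1])


def _moment_features(block: np.ndarray) -> np.ndarray:
    """(n_windows, w, k) -> (n_windows, k, 9) feature block."""
    mean = block.mean(axis=1)
    centred = block - mean[:, None, :]
    m2 = (centred**2).mean(axis=1)
    std = np.sqrt(m2)
    mn = block.min(axis=1)
    mx = block.max(axis=1)
    rng = mx - mn
    q1, q3 = np.quantile(block, [0.25, 0.75], axis=1)
    iqr = q3 - q1
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = (centred**3).mean(axis=1) / m2**1.5
        kurt = (centred**4).mean(axis=1) / m2**2 - 3.0
    degenerate = m2 == 0
    skew[degenerate] = 0.0
    kurt[degenerate] = 0.0
    rms = np.sqrt((block**2).mean(axis=1))
    return np.stack([mean, std, mn, mx, rng, iqr, kurt, skew, rms], axis=2)


def compute_features(window: np.ndarray) -> np.ndarray:
    """Nine statistics of one 1-d window, in :data:`FEATURE_NAMES` order."""
    window = np.asarray(window, float)
    if window.ndim != 1 or window.size < 2:
        raise FeatureError("a window must be 1-d with at least 2 samples")
    return _moment_features(window[None, :, None])[0, 0]


def _majority_codes(codes: np.ndarray, n_classes: int, prefer_nonzero: bool) -> np.ndarray:
    """Per-window majority of (n_windows, w) integer codes.

    With ``prefer_nonzero``, code 0 (the neutral class) wins only a strict
    majority over the best non-zero code.
    """
    counts = np.stack([(codes == c).sum(axis=1) for c in range(n_classes)], axis=1)
    if prefer_nonzero and n_classes > 1:
        best_nonzero = counts[:, 1:].argmax(axis=1) + 1
        return np.where(counts[:, 0] > counts[:, 1:].max(axis=1), 0, best_nonzero)
    return counts.argmax(axis=1)


def label_window(window_labels: np.ndarray) -> str:
    """Majority label of one window; ties with neutral go to the expression."""
    cats = list(vocab.CLASSES)
    codes = np.array([[cats.index(x) for x in window_labels]])
    return cats[_majority_codes(codes, len(cats), prefer_nonzero=True)[0]]


def _window_metadata(labels: pd.DataFrame, n_windows: int, w: int) -> pd.DataFrame:
    out = {}
    for col in vocab.LABEL_COLUMNS:
        series = labels[col].astype(str)
        cats = sorted(series.unique())
        codes = np.searchsorted(cats, series.to_numpy())[: n_windows * w].reshape(n_windows, w)
        prefer = col == "expression"
        if prefer:
            # majority with the neutral tie rule needs neutral at code 0
            cats = [vocab.NEUTRAL] + [c for c in cats if c != vocab.NEUTRAL]
            lut = {c: i for i, c in enumerate(cats)}
            codes = (
                series.map(lut).to_numpy()[: n_windows * w].reshape(n_windows, w)
            )
        maj = _majority_codes(codes, len(cats), prefer_nonzero=prefer)
        out[col] = np.asarray(cats, dtype=object)[maj]
    frame = pd.DataFrame(out)
    return frame.rename(columns={"expression": "label"})


def extract_features(
    recording: SensorRecording,
    windowspec: WindowSpec | None = None,
    filterspec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Feature table (162 columns + label/metadata) for one recording, unstandardized."""
    windowspec = windowspec or WindowSpec()
    streams = preprocess_for_ml(recording, filterspec)
    w = windowspec.samples(recording.sampling_rate_hz)
    block = segment(streams.to_numpy(), windowspec, recording.sampling_rate_hz)
    feats = _moment_features(block)  # (n_windows, 18, 9)
    table = pd.DataFrame(feats.reshape(feats.shape[0], -1), columns=feature_columns())
    meta = _window_metadata(recording.labels, block.shape[0], w)
    table["participant_id"] = recording.participant_id
    for col in meta.columns:
        table[col] = meta[col].to_numpy()
    return table


def standardize_per_participant(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every feature within each participant block.

    A feature that is constant within a participant maps to all zeros, with a
    warning naming it.  Participants need at least two windows.
    """
    cols = feature_columns()
    out = table.copy()
    for pid, idx in table.groupby("participant_id", sort=False).groups.items():
        block = table.loc[idx, cols].to_numpy(float)
        if block.shape[0] < 2:
            raise FeatureError(f"participant {pid!r} has fewer than 2 windows")
        mean = block.mean(axis=0)
        std = block.std(axis=0)
        zero = std == 0
        if zero.any():
            names = [c for c, z in zip(cols, zero) if z][:5]
            warnings.warn(
                f"participant {pid!r}: zero-variance feature(s) set to 0 (e.g. {names})",
                stacklevel=2,
            )
            std[zero] = 1.0
        z = (block - mean) / std
        z[:, zero] = 0.0
        out.loc[idx, cols] = z
    return out


def build_feature_table(
    recordings: list[SensorRecording],
    windowspec: WindowSpec | None = None,
    filterspec: FilterSpec | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Cohort-level feature table: windows x (162 features + metadata).

    Standardization is fit per participant on all of that participant's
    windows; set ``standardize=False`` to defer (e.g. to train-only scoping).
    """
    parts = [extract_features(r, windowspec, filterspec) for r in recordings]
    table = pd.concat(parts, ignore_index=True)
    if standardize:
        table = standardize_per_participant(table)
    return table
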