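"""Signal preprocessing: the statistics chain and the ML filtering path.

Two distinct paths operate on a raw recording:

* the statistics chain — per-stream linear detrend, per-sensor vector
  magnitude sqrt(x^2+y^2+z^2), bilateral (left+right) sum for the cheek and
  brow regions, and a centered 15-sample rolling median;
* the ML path — a zero-phase low-pass filter followed by a linear detrend on
  each of the 18 streams, keeping the per-axis structure for feature
  extraction.

Detrending fits a single least-squares line over the whole recording (the
drift it removes is a slow, session-long effect); the rolling median shrinks
its window at both edges so output length equals input length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import vocab
from .recording import SensorRecording


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass + smoothing configuration for the two preprocessing paths."""

    lowpass_cutoff_hz: float = 10.0
    order: int = 4
    zero_phase: bool = True
    median_window: int = 15
    out_of_range_mm: float | None = None  # optional sensor-range mask, off by default

    def __post_init__(self) -> None:
        if not (0 < self.lowpass_cutoff_hz < vocab.SAMPLING_RATE_HZ / 2):
            raise PreprocessingError("low-pass cutoff must lie in (0, Nyquist)")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise PreprocessingError("median window must be odd and >= 1")


@dataclass
class ProcessedTraces:
    """Combined cheek and brow magnitude traces (mm) for the statistics path."""

    participant_id: str
    cheek: np.ndarray
    brow: np.ndarray
    sampling_rate_hz: float = vocab.SAMPLING_RATE_HZ

    def signal(self, name: str) -> np.ndarray:
        if name not in ("cheek", "brow"):
            raise KeyError(name)
        return self.cheek if name == "cheek" else self.brow


def remove_linear_trend(stream: np.ndarray) -> np.ndarray:
    """Subtract the least-squares best-fit line; idempotent."""
    stream = np.asarray(stream, float)
    if stream.ndim != 1 or stream.size < 2:
        raise PreprocessingError("detrend requires a 1-d stream of length >= 2")
    return sps.detrend(stream, type="linear")


def vector_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three displacement axes."""
    x, y, z = (np.asarray(a, float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise PreprocessingError("axis streams must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def combine_bilateral(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Sum of left and right sensor magnitudes (total regional movement)."""
    left, right = np.asarray(left, float), np.asarray(right, float)
    if left.shape != right.shape:
        raise PreprocessingError("bilateral streams must have equal length")
    return left + right


def rolling_median(stream: np.ndarray, window: int = 15) -> np.ndarray:
    """Centered rolling median; windows shrink at the edges (length preserved)."""
    if window < 1 or window % 2 == 0:
        raise PreprocessingError("median window must be odd and >= 1")
    s = pd.Series(np.asarray(stream, float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def preprocess_for_statistics(
    recording: SensorRecording, spec: FilterSpec | None = None
) -> ProcessedTraces:
    """Detrend -> magnitude -> bilateral sum -> rolling median, per region."""
    spec = spec or FilterSpec()
    mags = {}
    for site in vocab.CHEEK_SITES + vocab.BROW_SITES:
        axes = [remove_linear_trend(recording.stream(f"{site}_{a}")) for a in vocab.AXES]
        mags[site] = vector_magnitude(*axes)
    cheek = rolling_median(combine_bilateral(mags["cheek_left"], mags["cheek_right"]), spec.median_window)
    brow = rolling_median(combine_bilateral(mags["brow_left"], mags["brow_right"]), spec.median_window)
    if spec.out_of_range_mm is not None:
        cheek = np.minimum(cheek, spec.out_of_range_mm)
        brow = np.minimum(brow, spec.out_of_range_mm)
    return ProcessedTraces(
        participant_id=recording.participant_id,
        cheek=cheek,
        brow=brow,
        sampling_rate_hz=recording.sampling_rate_hz,
    )


def lowpass(stream: np.ndarray, spec: FilterSpec, fs: float = vocab.SAMPLING_RATE_HZ) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass."""
    if spec.lowpass_cutoff_hz >= fs / 2:
        raise PreprocessingError("cutoff must be below Nyquist")
    sos = sps.butter(spec.order, spec.lowpass_cutoff_hz, btype="low", fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, np.asarray(stream, float))
    return sps.sosfilt(sos, np.asarray(stream, float))


def preprocess_for_ml(
    recording: SensorRecording, spec: FilterSpec | None = None
) -> pd.DataFrame:
    """Low-pass then detrend each of the 18 streams; columns preserved."""
    spec = spec or FilterSpec()
    out = {}
    for stream in vocab.STREAMS:
        out[stream] = remove_linear_trend(
            lowpass(recording.stream(stream), spec, recording.sampling_rate_hz)
        )
    return pd.DataFrame(out, columns=list(vocab.STREAMS))
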