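"""Seeded generator of synthetic optomyography (OMG) recordings.

The generative model is deliberately simple: each expression event drives a
trapezoidal activation envelope (raised-cosine onset/offset, flat plateau)
whose plateau height is an expression-by-site coupling (mm), modulated by a
per-participant lognormal amplitude scale, a low-intensity attenuation
factor, and a glasses-position gain.  The site activation is distributed over
the sensor's three axes along a fixed per-site unit direction (with a small
per-participant perturbation), then superimposed on per-stream linear drift,
a constant offset and white Gaussian noise.  Head movement adds a zero-mean,
sub-1-Hz artifact so that, by construction, it does not shift mean movement —
a designed null.

Default plateau couplings are *calibrated*: a small linear solve converts the
reported combined (left + right) high-intensity event-mean medians into
per-site plateau heights, correcting for the envelope duty cycle and for the
offset introduced by whole-recording linear detrending downstream.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vocab
from .protocol import ProtocolSpec, default_protocol
from .recording import ExpressionEvent, SensorRecording


class GeneratorConfigError(ValueError):
    """Invalid generator configuration."""


# Reported combined (L+R) event-mean medians at high intensity, mm.  These are
# the calibration targets for the default coupling matrix.
HIGH_INTENSITY_TARGETS_MM: dict[str, dict[str, float]] = {
    "cheek": {"brow_raise": 4.70, "frown": 5.17, "smile": 12.14, "squeezed_eyes": 12.70},
    "brow": {"brow_raise": 16.16, "frown": 11.51, "smile": 4.00, "squeezed_eyes": 14.14},
}

#: per-site plateau couplings for the temple sensors (mm); no published target.
TEMPLE_COUPLING_MM: dict[str, float] = {
    "brow_raise": 0.8,
    "frown": 0.5,
    "smile": 1.4,
    "squeezed_eyes": 1.0,
}

RAMP_S: float = 0.25  # raised-cosine onset/offset length

#: base unit direction of skin displacement per site (perturbed per participant)
_BASE_DIRECTIONS: dict[str, np.ndarray] = {
    "cheek_left": np.array([0.45, 0.35, 0.82]),
    "cheek_right": np.array([-0.45, 0.35, 0.82]),
    "brow_left": np.array([0.20, 0.65, 0.73]),
    "brow_right": np.array([-0.20, 0.65, 0.73]),
    "temple_left": np.array([0.60, 0.10, 0.79]),
    "temple_right": np.array([-0.60, 0.10, 0.79]),
}
_BASE_DIRECTIONS = {k: v / np.linalg.norm(v) for k, v in _BASE_DIRECTIONS.items()}


@dataclass(frozen=True)
class PositionGains:
    """Multiplicative activation gains by glasses position.

    Brow-site activation is attenuated or amplified by frame position for the
    brow-driven expressions (the upper-frame sensors sit closer to the brow
    when the glasses ride high on the nasal bridge); the smile is unaffected.
    Squeezed eyes additionally modulates the cheek sensors.
    """

    brow: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "brow_raise": {"low": 0.9, "medium": 0.9, "high": 1.2},
            "frown": {"low": 0.9, "medium": 0.9, "high": 1.2},
            "squeezed_eyes": {"low": 0.88, "medium": 0.97, "high": 1.15},
            "smile": {"low": 1.0, "medium": 1.0, "high": 1.0},
        }
    )
    cheek: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "brow_raise": {"low": 1.0, "medium": 1.0, "high": 1.0},
            "frown": {"low": 1.0, "medium": 1.0, "high": 1.0},
            "squeezed_eyes": {"low": 0.89, "medium": 0.99, "high": 1.12},
            "smile": {"low": 1.0, "medium": 1.0, "high": 1.0},
        }
    )

    def gain(self, expression: str, site: str, position: str) -> float:
        if position not in vocab.GLASSES_POSITIONS:
            raise GeneratorConfigError(f"unknown glasses position {position!r}")
        if site in vocab.BROW_SITES:
            return self.brow[expression][position]
        if site in vocab.CHEEK_SITES:
            return self.cheek[expression][position]
        return 1.0

    @classmethod
    def identity(cls) -> "PositionGains":
        one = {e: {p: 1.0 for p in vocab.GLASSES_POSITIONS} for e in vocab.EXPRESSIONS}
        return cls(brow={e: dict(v) for e, v in one.items()}, cheek={e: dict(v) for e, v in one.items()})


@dataclass(frozen=True)
class CouplingMatrix:
    """Expression x site peak (plateau) combined-magnitude contribution, mm."""

    table: pd.DataFrame  # index = expressions, columns = sites

    def __post_init__(self) -> None:
        t = self.table
        if list(t.index) != list(vocab.EXPRESSIONS) or list(t.columns) != list(vocab.SITES):
            raise GeneratorConfigError("coupling table must be expressions x sites")
        if (t.to_numpy() < 0).any():
            raise GeneratorConfigError("coupling entries must be non-negative")

    def value(self, expression: str, site: str) -> float:
        return float(self.table.at[expression, site])

    def validate_structure(self) -> None:
        """Check the qualitative orderings the generator is designed around."""
        cheek = self.table[list(vocab.CHEEK_SITES)].sum(axis=1)
        brow = self.table[list(vocab.BROW_SITES)].sum(axis=1)
        if not (
            min(cheek["smile"], cheek["squeezed_eyes"]) > max(cheek["brow_raise"], cheek["frown"])
        ):
            raise GeneratorConfigError("cheek coupling must favour smile/squeezed eyes")
        if not (brow["brow_raise"] > brow.drop("brow_raise").max()):
            raise GeneratorConfigError("brow coupling must peak at brow raise")
        if not (brow["smile"] < brow.drop("smile").min()):
            raise GeneratorConfigError("smile must have the smallest brow coupling")


@dataclass
class ParticipantProfile:
    """Per-participant generative parameters."""

    participant_id: str
    amplitude_scale: dict[str, float]  # per site, lognormal around 1
    expression_gain: dict[str, float]  # per "region:expression", around 1
    noise_std_mm: float
    drift_slope_mm_s: dict[str, float]  # per stream
    offset_mm: dict[str, float]  # per stream
    attenuation: float  # low-intensity factor in (0, 1)
    directions: dict[str, np.ndarray]  # per site unit vector
    trial_sigma: float = 0.2  # per-event symmetric effort jitter

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.amplitude_scale.values()):
            raise GeneratorConfigError("amplitude scales must be positive")
        if not (0 < self.attenuation < 1):
            raise GeneratorConfigError("attenuation factor must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "amplitude_scale": self.amplitude_scale,
            "expression_gain": self.expression_gain,
            "trial_sigma": self.trial_sigma,
            "noise_std_mm": self.noise_std_mm,
            "drift_slope_mm_s": self.drift_slope_mm_s,
            "offset_mm": self.offset_mm,
            "attenuation": self.attenuation,
            "directions": {k: list(map(float, v)) for k, v in self.directions.items()},
        }


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults reproduce the study conditions."""

    coupling: CouplingMatrix | None = None  # None -> calibrated default
    position_gains: PositionGains = field(default_factory=PositionGains)
    ramp_s: float = RAMP_S
    noise_std_mm: float = 0.12
    drift_slope_scale_mm_s: float = 0.003
    offset_scale_mm: float = 0.4
    amplitude_sigma: float = 0.15  # lognormal sigma of per-site scales
    expression_sigma: float = 0.15  # lognormal sigma of per-(region, expression) gains
    # symmetric multiplicative jitters (1 + N(0, sigma), clipped positive): a
    # symmetric law keeps the median of an n-trial mean at 1 for every n, so
    # condition cells pooling different numbers of trials stay comparable
    trial_sigma: float = 0.2  # per-event effort jitter
    block_sigma: float = 0.15  # per-condition-block vigour
    attenuation_mean: float = 0.5
    attenuation_jitter: float = 0.04
    head_movement_amplitude_mm: float = 0.35  # 0 disables the artifact
    #: shuffle the expression order within each condition group per participant,
    #: so no expression is pinned to a fixed offset within the session
    shuffle_expression_order: bool = True
    # slow non-linear baseline wander (per stream): random-phase sinusoids
    wander_amplitude_mm: float = 0.5
    wander_components: int = 3
    wander_period_range_s: tuple[float, float] = (120.0, 600.0)


# ---------------------------------------------------------------------------
# envelope + calibration


def trapezoid_envelope(n_samples: int, fs: float, ramp_s: float = RAMP_S) -> np.ndarray:
    """Raised-cosine on/off trapezoid of unit plateau over ``n_samples``."""
    t = np.arange(n_samples) / fs
    duration = n_samples / fs
    ramp = min(ramp_s, duration / 2)
    env = np.ones(n_samples)
    up = t < ramp
    env[up] = 0.5 * (1 - np.cos(np.pi * t[up] / ramp))
    down = t > duration - ramp
    env[down] = 0.5 * (1 - np.cos(np.pi * (duration - t[down]) / ramp))
    return env


def _duty(duration_s: float, ramp_s: float) -> float:
    """Mean of the trapezoid envelope over the event, as fraction of plateau."""
    ramp = min(ramp_s, duration_s / 2)
    return (duration_s - ramp) / duration_s


def _activation_weights(
    protocols: tuple[ProtocolSpec, ...],
    position_gains: PositionGains,
    site: str,
    attenuation: float,
    ramp_s: float,
) -> tuple[dict[str, float], float]:
    """Per-expression activation-seconds weights and total recording seconds."""
    w = {e: 0.0 for e in vocab.EXPRESSIONS}
    total_s = 0.0
    for spec in protocols:
        for block in spec.blocks:
            per_rep = spec.neutral_gap_s + block.duration_s
            total_s += block.repetitions * per_rep
            factor = attenuation if block.intensity == "low" else 1.0
            gain = position_gains.gain(block.expression, site, block.glasses_position)
            w[block.expression] += (
                block.repetitions * block.duration_s * _duty(block.duration_s, ramp_s) * factor * gain
            )
        total_s += spec.neutral_gap_s  # trailing rest at the end of each task
    return {e: v / total_s for e, v in w.items()}, total_s


def _forward_group_means(
    c: np.ndarray,
    group_site: str,
    protocols: tuple[ProtocolSpec, ...],
    position_gains: PositionGains,
    attenuation: float,
    ramp_s: float,
    fs: float,
) -> np.ndarray:
    """Noiseless forward model of one sensor group's statistics chain.

    Builds the site activation time course at unit amplitude scale for plateau
    couplings ``c`` (ordered as :data:`vocab.EXPRESSIONS`), pushes it through
    detrend -> magnitude -> bilateral sum -> rolling median exactly as the
    statistics path does, and returns the per-expression mean of the event
    means over the pooled high-intensity Task A events.

    For a noiseless, drift-free site whose axes are proportional to one unit
    vector, per-axis detrending followed by the vector magnitude collapses to
    ``|detrend(A)|`` of the scalar activation, and the two symmetric sites of
    a group double it.
    """
    from scipy.signal import detrend as _lin_detrend

    segments, n = _schedule(protocols, fs)
    activation = np.zeros(n)
    expr_index = {e: i for i, e in enumerate(vocab.EXPRESSIONS)}
    event_spans: dict[str, list[tuple[int, int]]] = {e: [] for e in vocab.EXPRESSIONS}
    for seg in segments:
        if seg["kind"] != "event":
            continue
        block = seg["block"]
        env = trapezoid_envelope(seg["end"] - seg["start"], fs, ramp_s)
        amp = (
            c[expr_index[block.expression]]
            * (attenuation if block.intensity == "low" else 1.0)
            * position_gains.gain(block.expression, group_site, block.glasses_position)
        )
        activation[seg["start"] : seg["end"]] += amp * env
        if seg["task"] == "A" and block.intensity == "high":
            event_spans[block.expression].append((seg["start"], seg["end"]))
    combined = 2.0 * np.abs(_lin_detrend(activation))
    smoothed = (
        pd.Series(combined).rolling(15, center=True, min_periods=1).median().to_numpy()
    )
    out = np.empty(len(vocab.EXPRESSIONS))
    for e, i in expr_index.items():
        out[i] = float(np.mean([smoothed[a:b].mean() for a, b in event_spans[e]]))
    return out


def calibrate_coupling(
    targets: dict[str, dict[str, float]] | None = None,
    protocols: tuple[ProtocolSpec, ...] | None = None,
    position_gains: PositionGains | None = None,
    attenuation: float = 0.5,
    ramp_s: float = RAMP_S,
    max_iter: int = 12,
    tol_mm: float = 0.01,
) -> CouplingMatrix:
    """Fix plateau couplings so cohort event-mean medians land on targets.

    The statistics chain detrends each raw stream over the whole recording,
    which both offsets and folds the magnitude trace, so the map from plateau
    coupling to measured event mean is not a simple duty-cycle scaling.  A
    deterministic fixed-point iteration against the noiseless forward model of
    the full chain inverts that map to within ``tol_mm``.
    """
    targets = targets or HIGH_INTENSITY_TARGETS_MM
    protocols = protocols or default_protocol()
    position_gains = position_gains or PositionGains()
    fs = protocols[0].sampling_rate_hz
    duty_pooled = 0.5 * (_duty(1.0, ramp_s) + _duty(3.0, ramp_s))

    table = pd.DataFrame(0.0, index=list(vocab.EXPRESSIONS), columns=list(vocab.SITES))
    for group, sites in (("cheek", vocab.CHEEK_SITES), ("brow", vocab.BROW_SITES)):
        t = np.array([targets[group][e] for e in vocab.EXPRESSIONS])
        c = t / (2.0 * duty_pooled)  # per-site first guess, ignoring detrend
        for _ in range(max_iter):
            predicted = _forward_group_means(
                c, sites[0], protocols, position_gains, attenuation, ramp_s, fs
            )
            err = t - predicted
            if np.max(np.abs(err)) < tol_mm:
                break
            c = c + err / (2.0 * duty_pooled)
            if (c <= 0).any():
                raise GeneratorConfigError("calibration produced a non-positive coupling")
        for site in sites:
            table.loc[list(vocab.EXPRESSIONS), site] = c
    for site in vocab.TEMPLE_SITES:
        for e in vocab.EXPRESSIONS:
            table.at[e, site] = TEMPLE_COUPLING_MM[e]
    coupling = CouplingMatrix(table)
    coupling.validate_structure()
    return coupling


@functools.lru_cache(maxsize=1)
def default_coupling() -> CouplingMatrix:
    """The calibrated default coupling matrix (computed once per process)."""
    return calibrate_coupling()


# ---------------------------------------------------------------------------
# participant sampling and rendering


def _region(site: str) -> str:
    return site.split("_")[0]


def _sym_jitter(rng: np.random.Generator, sigma: float) -> float:
    """Symmetric multiplicative jitter around 1, clipped away from zero."""
    return float(np.clip(1.0 + rng.normal(0.0, sigma), 0.1, None))


def sample_profile(participant_id: str, rng: np.random.Generator, config: GeneratorConfig) -> ParticipantProfile:
    scales = {s: float(rng.lognormal(0.0, config.amplitude_sigma)) for s in vocab.SITES}
    expr_gain = {
        f"{region}:{e}": float(rng.lognormal(0.0, config.expression_sigma))
        for region in ("cheek", "brow", "temple")
        for e in vocab.EXPRESSIONS
    }
    drift = {st: float(rng.uniform(-1, 1) * config.drift_slope_scale_mm_s) for st in vocab.STREAMS}
    offset = {st: float(rng.uniform(-1, 1) * config.offset_scale_mm) for st in vocab.STREAMS}
    atten = float(np.clip(rng.normal(config.attenuation_mean, config.attenuation_jitter), 0.35, 0.65))
    directions = {}
    for site in vocab.SITES:
        u = _BASE_DIRECTIONS[site] + rng.normal(0.0, 0.05, 3)
        directions[site] = u / np.linalg.norm(u)
    return ParticipantProfile(
        participant_id=participant_id,
        amplitude_scale=scales,
        expression_gain=expr_gain,
        trial_sigma=config.trial_sigma,
        noise_std_mm=config.noise_std_mm,
        drift_slope_mm_s=drift,
        offset_mm=offset,
        attenuation=atten,
        directions=directions,
    )


def apply_glasses_position(
    activation: np.ndarray,
    expression: str,
    position: str,
    gains: PositionGains | None = None,
) -> np.ndarray:
    """Scale a (n, 6) site-activation segment by the glasses-position gains."""
    gains = gains or PositionGains()
    if position not in vocab.GLASSES_POSITIONS:
        raise GeneratorConfigError(f"unknown glasses position {position!r}")
    out = activation.copy()
    for j, site in enumerate(vocab.SITES):
        out[:, j] *= gains.gain(expression, site, position)
    return out


_DIRECTION_AXES: dict[str, np.ndarray] = {
    "left": np.array([-1.0, 0.2, 0.0]),
    "right": np.array([1.0, 0.2, 0.0]),
    "up": np.array([0.0, 0.3, 1.0]),
    "down": np.array([0.0, 0.3, -1.0]),
}
_DIRECTION_AXES = {k: v / np.linalg.norm(v) for k, v in _DIRECTION_AXES.items()}


def head_movement_artifact(
    n_samples: int,
    direction: str,
    fs: float = vocab.SAMPLING_RATE_HZ,
    amplitude_mm: float = 0.35,
) -> np.ndarray:
    """Zero-mean, sub-1-Hz (for events >= 2 s) head-movement artifact, (n, 3).

    A sine with an integer number of cycles over the segment, projected onto a
    direction-specific axis pattern; integrating to zero guarantees it cannot
    shift an event's mean displacement.
    """
    if direction not in _DIRECTION_AXES:
        raise GeneratorConfigError(f"unknown head-movement direction {direction!r}")
    duration = n_samples / fs
    cycles = max(1, round(duration / 1.5))
    t = np.arange(n_samples) / fs
    wave = amplitude_mm * np.sin(2 * np.pi * cycles * t / duration)
    return wave[:, None] * _DIRECTION_AXES[direction][None, :]


def apply_head_movement(
    segment: np.ndarray,
    direction: str,
    fs: float = vocab.SAMPLING_RATE_HZ,
    amplitude_mm: float = 0.35,
) -> np.ndarray:
    """Add the head-movement artifact to every stream of an (n, 18) segment."""
    seg = np.asarray(segment, float)
    art = head_movement_artifact(seg.shape[0], direction, fs, amplitude_mm)
    out = seg.copy()
    for j in range(len(vocab.SITES)):
        out[:, 3 * j : 3 * j + 3] += art
    return out


def render_expression(
    event: ExpressionEvent,
    coupling: CouplingMatrix,
    profile: ParticipantProfile,
    rng: np.random.Generator | None = None,
    fs: float = vocab.SAMPLING_RATE_HZ,
    ramp_s: float = RAMP_S,
    position_gains: PositionGains | None = None,
) -> np.ndarray:
    """Render one event as an (n, 18) stream segment (activation+drift+noise).

    Passing ``rng=None`` renders the noiseless, drift-free activation, which is
    exactly linear in the coupling and the profile amplitude scales.
    """
    n = event.n_samples
    if n / fs < 0.5:
        raise GeneratorConfigError("event duration must be >= 0.5 s")
    gains = position_gains or PositionGains()
    env = trapezoid_envelope(n, fs, ramp_s)
    factor = profile.attenuation if event.intensity == "low" else 1.0
    trial = _sym_jitter(rng, profile.trial_sigma) if rng is not None else 1.0
    out = np.zeros((n, 18))
    t = np.arange(n) / fs
    for j, site in enumerate(vocab.SITES):
        amp = (
            coupling.value(event.expression, site)
            * profile.amplitude_scale[site]
            * profile.expression_gain[f"{_region(site)}:{event.expression}"]
            * trial
            * factor
            * gains.gain(event.expression, site, event.glasses_position)
        )
        out[:, 3 * j : 3 * j + 3] = (amp * env)[:, None] * profile.directions[site][None, :]
    if rng is not None:
        for k, stream in enumerate(vocab.STREAMS):
            out[:, k] += profile.offset_mm[stream] + profile.drift_slope_mm_s[stream] * t
        out += rng.normal(0.0, profile.noise_std_mm, out.shape)
    if event.head_movement != "none":
        out = apply_head_movement(out, event.head_movement, fs)
    return out


# ---------------------------------------------------------------------------
# cohort generation


def _schedule(protocols: tuple[ProtocolSpec, ...], fs: float) -> tuple[list[dict], int]:
    """Lay out gaps and events on the sample grid; returns segments + total n."""
    segments: list[dict] = []
    cursor = 0
    for spec in protocols:
        gap_n = round(spec.neutral_gap_s * fs)
        for block in spec.blocks:
            ev_n = round(block.duration_s * fs)
            for _ in range(block.repetitions):
                segments.append({"kind": "gap", "start": cursor, "end": cursor + gap_n, "block": block, "task": spec.task})
                cursor += gap_n
                segments.append({"kind": "event", "start": cursor, "end": cursor + ev_n, "block": block, "task": spec.task})
                cursor += ev_n
        last = spec.blocks[-1]
        segments.append({"kind": "gap", "start": cursor, "end": cursor + gap_n, "block": last, "task": spec.task})
        cursor += gap_n
    return segments, cursor


def _shuffle_within_condition(spec: ProtocolSpec, rng: np.random.Generator) -> ProtocolSpec:
    """Permute expression order inside each run of same-condition blocks."""
    blocks = list(spec.blocks)
    out: list = []
    i = 0
    while i < len(blocks):
        key = (blocks[i].intensity, blocks[i].duration_s, blocks[i].head_movement, blocks[i].glasses_position)
        j = i
        while j < len(blocks) and (
            blocks[j].intensity,
            blocks[j].duration_s,
            blocks[j].head_movement,
            blocks[j].glasses_position,
        ) == key:
            j += 1
        group = blocks[i:j]
        out.extend(group[k] for k in rng.permutation(len(group)))
        i = j
    return ProtocolSpec(
        task=spec.task,
        blocks=tuple(out),
        neutral_gap_s=spec.neutral_gap_s,
        sampling_rate_hz=spec.sampling_rate_hz,
    )


def generate_recording(
    participant_id: str,
    profile: ParticipantProfile,
    protocols: tuple[ProtocolSpec, ...],
    coupling: CouplingMatrix,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> SensorRecording:
    fs = protocols[0].sampling_rate_hz
    if config.shuffle_expression_order:
        protocols = tuple(_shuffle_within_condition(spec, rng) for spec in protocols)
    segments, n = _schedule(protocols, fs)
    t = np.arange(n) / fs

    # site activation magnitudes
    activation = np.zeros((n, len(vocab.SITES)))
    events: list[ExpressionEvent] = []
    labels = {
        "expression": np.full(n, vocab.NEUTRAL, dtype=object),
        "intensity": np.full(n, "none", dtype=object),
        "duration": np.full(n, "none", dtype=object),
        "head_movement": np.full(n, "none", dtype=object),
        "glasses_position": np.full(n, "medium", dtype=object),
        "task": np.full(n, "A", dtype=object),
    }
    block_vigour: dict[int, float] = {}
    for seg in segments:
        block, sl = seg["block"], slice(seg["start"], seg["end"])
        if id(block) not in block_vigour:
            block_vigour[id(block)] = _sym_jitter(rng, config.block_sigma)
        labels["intensity"][sl] = block.intensity
        labels["duration"][sl] = block.duration_class
        labels["glasses_position"][sl] = block.glasses_position
        labels["task"][sl] = seg["task"]
        if seg["kind"] != "event":
            continue
        labels["expression"][sl] = block.expression
        labels["head_movement"][sl] = block.head_movement
        env = trapezoid_envelope(seg["end"] - seg["start"], fs, config.ramp_s)
        factor = profile.attenuation if block.intensity == "low" else 1.0
        trial = _sym_jitter(rng, profile.trial_sigma)
        for j, site in enumerate(vocab.SITES):
            amp = (
                coupling.value(block.expression, site)
                * profile.amplitude_scale[site]
                * profile.expression_gain[f"{_region(site)}:{block.expression}"]
                * block_vigour[id(block)]
                * trial
                * factor
                * config.position_gains.gain(block.expression, site, block.glasses_position)
            )
            activation[sl, j] += amp * env
        events.append(
            ExpressionEvent(
                expression=block.expression,
                start=seg["start"],
                end=seg["end"],
                intensity=block.intensity,
                duration=block.duration_class,
                head_movement=block.head_movement,
                glasses_position=block.glasses_position,
                task=seg["task"],
            )
        )

    # project onto axes, add drift + offset + noise
    data = np.empty((n, 18))
    for j, site in enumerate(vocab.SITES):
        data[:, 3 * j : 3 * j + 3] = activation[:, j : j + 1] * profile.directions[site][None, :]
    for k, stream in enumerate(vocab.STREAMS):
        data[:, k] += profile.offset_mm[stream] + profile.drift_slope_mm_s[stream] * t
    if config.wander_amplitude_mm > 0:
        lo, hi = config.wander_period_range_s
        for k in range(len(vocab.STREAMS)):
            for _ in range(config.wander_components):
                amp = config.wander_amplitude_mm * abs(rng.normal())
                freq = 1.0 / rng.uniform(lo, hi)
                phase = rng.uniform(0, 2 * np.pi)
                data[:, k] += amp * np.sin(2 * np.pi * freq * t + phase)
    data += rng.normal(0.0, profile.noise_std_mm, data.shape)

    if config.head_movement_amplitude_mm > 0:
        for ev in events:
            if ev.head_movement != "none":
                art = head_movement_artifact(
                    ev.n_samples, ev.head_movement, fs, config.head_movement_amplitude_mm
                )
                for j in range(len(vocab.SITES)):
                    data[ev.start : ev.end, 3 * j : 3 * j + 3] += art

    return SensorRecording(
        participant_id=participant_id,
        timestamps=t,
        data=pd.DataFrame(data, columns=list(vocab.STREAMS)),
        labels=pd.DataFrame(labels),
        events=events,
        profile=profile.to_dict(),
        sampling_rate_hz=fs,
    )


def generate_cohort(
    n_participants: int = 27,
    protocols: tuple[ProtocolSpec, ...] | None = None,
    seed: int = 42,
    config: GeneratorConfig | None = None,
) -> list[SensorRecording]:
    """Generate a seeded cohort; identical (seed, config) gives identical output."""
    if n_participants < 1:
        raise GeneratorConfigError("n_participants must be >= 1")
    protocols = tuple(protocols) if protocols is not None else default_protocol()
    if not protocols:
        raise GeneratorConfigError("at least one protocol is required")
    config = config or GeneratorConfig()
    coupling = config.coupling
    if coupling is None:
        default = GeneratorConfig()
        if (
            config.position_gains == default.position_gains
            and config.attenuation_mean == default.attenuation_mean
            and config.ramp_s == default.ramp_s
        ):
            coupling = default_coupling()
        else:
            coupling = calibrate_coupling(
                position_gains=config.position_gains,
                attenuation=config.attenuation_mean,
                ramp_s=config.ramp_s,
            )
    recordings = []
    for i in range(n_participants):
        rng = np.random.default_rng([seed, i])
        pid = f"P{i + 1:02d}"
        profile = sample_profile(pid, rng, config)
        recordings.append(generate_recording(pid, profile, protocols, coupling, config, rng))
    return recordings
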