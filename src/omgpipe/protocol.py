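"""Data-collection protocol: the three posed-expression tasks.

A protocol is an ordered list of condition blocks.  Each block fixes one
(expression, intensity, duration, head-movement, glasses-position) condition
and is performed ``repetitions`` times, with a neutral rest gap before every
repetition.  The default protocol mirrors the study design:

* Task A — all four intensity x duration combinations, head still.
* Task B — high-intensity, long (3 s) expressions with head movement in each
  of four directions.
* Task C — high-intensity, short and long expressions with the glasses worn
  low, medium and high on the nasal bridge.

Every expression is repeated three times per condition block.  The neutral
rest gap between repetitions is task-specific (3 s, 4.3 s and 5.2 s for A, B
and C): the statistics path removes one least-squares line per stream over
the whole session, so any trend in the expected activation level (Task A
ramps from low- to high-intensity blocks; Tasks B and C differ in event
density) would tilt the recovered baseline of one task relative to another
and leak a spurious condition effect.  The B/C gaps are set, given the Task A
gap of 3 s, where that whole-session activation trend vanishes, making the
designed between-task null conditions hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from . import vocab


class ProtocolError(ValueError):
    """Invalid protocol configuration."""


@dataclass(frozen=True)
class ConditionBlock:
    """One expression performed ``repetitions`` times under a fixed condition."""

    expression: str
    intensity: str
    duration_s: float
    head_movement: str = "none"
    glasses_position: str = "medium"
    repetitions: int = 3

    def __post_init__(self) -> None:
        if self.expression not in vocab.EXPRESSIONS:
            raise ProtocolError(f"unknown expression {self.expression!r}")
        if self.intensity not in vocab.INTENSITIES:
            raise ProtocolError(f"unknown intensity {self.intensity!r}")
        if self.head_movement not in vocab.HEAD_MOVEMENTS:
            raise ProtocolError(f"unknown head movement {self.head_movement!r}")
        if self.glasses_position not in vocab.GLASSES_POSITIONS:
            raise ProtocolError(f"unknown glasses position {self.glasses_position!r}")
        if self.duration_s < 0.5:
            raise ProtocolError("expression duration must be >= 0.5 s")
        if self.repetitions < 1:
            raise ProtocolError("repetitions must be >= 1")

    @property
    def duration_class(self) -> str:
        return vocab.duration_class(self.duration_s)


@dataclass(frozen=True)
class ProtocolSpec:
    """One task: an ordered list of condition blocks at a fixed sampling rate."""

    task: str
    blocks: tuple[ConditionBlock, ...]
    neutral_gap_s: float = 3.0
    sampling_rate_hz: float = vocab.SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        if self.task not in vocab.TASKS:
            raise ProtocolError(f"unknown task {self.task!r}")
        if not self.blocks:
            raise ProtocolError("protocol has no condition blocks")
        if self.neutral_gap_s <= 0:
            raise ProtocolError("neutral gap must be positive")

    @property
    def n_events(self) -> int:
        return sum(b.repetitions for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "neutral_gap_s": self.neutral_gap_s,
            "sampling_rate_hz": self.sampling_rate_hz,
            "blocks": [asdict(b) for b in self.blocks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(
            task=d["task"],
            blocks=tuple(ConditionBlock(**b) for b in d["blocks"]),
            neutral_gap_s=d["neutral_gap_s"],
            sampling_rate_hz=d["sampling_rate_hz"],
        )


def _blocks(task: str, combos: list[dict]) -> tuple[ConditionBlock, ...]:
    out = []
    for combo in combos:
        for expr in vocab.EXPRESSIONS:
            out.append(ConditionBlock(expression=expr, **combo))
    return tuple(out)


def task_a() -> ProtocolSpec:
    """Intensity x duration grid, head still, glasses at the medium position."""
    combos = [
        {"intensity": "low", "duration_s": 1.0},
        {"intensity": "low", "duration_s": 3.0},
        {"intensity": "high", "duration_s": 1.0},
        {"intensity": "high", "duration_s": 3.0},
    ]
    return ProtocolSpec(task="A", blocks=_blocks("A", combos), neutral_gap_s=3.0)


def task_b() -> ProtocolSpec:
    """High-intensity 3 s expressions with head movement in four directions."""
    combos = [
        {"intensity": "high", "duration_s": 3.0, "head_movement": d}
        for d in ("left", "right", "up", "down")
    ]
    return ProtocolSpec(task="B", blocks=_blocks("B", combos), neutral_gap_s=4.3)


def task_c() -> ProtocolSpec:
    """High-intensity short/long expressions at three glasses positions."""
    combos = [
        {"intensity": "high", "duration_s": dur, "glasses_position": pos}
        for pos in ("low", "medium", "high")
        for dur in (1.0, 3.0)
    ]
    return ProtocolSpec(task="C", blocks=_blocks("C", combos), neutral_gap_s=5.2)


def default_protocol() -> tuple[ProtocolSpec, ...]:
    """The full three-task session (168 expression events per participant)."""
    return (task_a(), task_b(), task_c())


def protocols_by_name(name: str) -> tuple[ProtocolSpec, ...]:
    name = name.upper() if name.lower() != "all" else "all"
    table = {"A": (task_a(),), "B": (task_b(),), "C": (task_c(),), "all": default_protocol()}
    if name not in table:
        raise ProtocolError(f"unknown protocol selection {name!r} (expected A, B, C or all)")
    return table[name]
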