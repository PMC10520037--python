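"""Closed vocabularies shared across the pipeline.

The glasses carry six 3-axis optical skin-displacement (OMG) sensors placed
over the zygomaticus major (cheeks), frontalis/corrugator region (brows) and
the temples.  Every module speaks in terms of these fixed site, axis and
label vocabularies; streams are named ``{site}_{axis}``.
"""

from __future__ import annotations

SAMPLING_RATE_HZ: float = 50.0
DT_S: float = 1.0 / SAMPLING_RATE_HZ

SITES: tuple[str, ...] = (
    "cheek_left",
    "cheek_right",
    "brow_left",
    "brow_right",
    "temple_left",
    "temple_right",
)
AXES: tuple[str, ...] = ("x", "y", "z")
STREAMS: tuple[str, ...] = tuple(f"{site}_{axis}" for site in SITES for axis in AXES)

CHEEK_SITES: tuple[str, ...] = ("cheek_left", "cheek_right")
BROW_SITES: tuple[str, ...] = ("brow_left", "brow_right")
TEMPLE_SITES: tuple[str, ...] = ("temple_left", "temple_right")

EXPRESSIONS: tuple[str, ...] = ("brow_raise", "frown", "smile", "squeezed_eyes")
NEUTRAL: str = "neutral"
CLASSES: tuple[str, ...] = (NEUTRAL,) + EXPRESSIONS

INTENSITIES: tuple[str, ...] = ("low", "high")
DURATION_CLASSES: tuple[str, ...] = ("short", "long")
HEAD_MOVEMENTS: tuple[str, ...] = ("none", "left", "right", "up", "down")
GLASSES_POSITIONS: tuple[str, ...] = ("low", "medium", "high")
TASKS: tuple[str, ...] = ("A", "B", "C")

LABEL_COLUMNS: tuple[str, ...] = (
    "expression",
    "intensity",
    "duration",
    "head_movement",
    "glasses_position",
    "task",
)

#: sample count of a 1 s / 3 s expression at 50 Hz, by duration class
DURATION_S: dict[str, float] = {"short": 1.0, "long": 3.0}


def duration_class(duration_s: float) -> str:
    return "short" if duration_s <= 2.0 else "long"
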