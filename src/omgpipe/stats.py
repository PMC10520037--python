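"""Paired statistical comparison of mean facial movement across conditions.

For each participant, the mean combined cheek/brow movement is computed per
condition level (expression type, head still vs moving, or glasses position)
as the mean over that participant's matching expression events of the event's
trace mean.  Condition levels are then compared all-pairs with the two-sided
Wilcoxon signed-rank (paired) test, Bonferroni-corrected within each analysis
family (alpha = 0.05), and annotated on the conventional descending star
ladder (**** for p < 1e-4 down to ns).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from . import vocab
from .preprocessing import ProcessedTraces
from .recording import ExpressionEvent

ALPHA: float = 0.05


class MissingConditionError(ValueError):
    """A participant has no events for a required condition cell."""


@dataclass(frozen=True)
class PairedTestResult:
    """One paired comparison within a Bonferroni family."""

    signal: str  # 'cheek' or 'brow'
    pair: tuple[str, str]
    p_raw: float
    p_adjusted: float
    family_size: int
    annotation: str
    median_a: float
    median_b: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA

    def to_dict(self) -> dict:
        return {
            "signal": self.signal,
            "pair": list(self.pair),
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "family_size": self.family_size,
            "significant": self.significant,
            "annotation": self.annotation,
            "median_a": self.median_a,
            "median_b": self.median_b,
        }


@dataclass
class ComparisonResult:
    """All paired tests of one analysis plus the per-level cohort medians."""

    analysis: str
    tests: list[PairedTestResult]
    #: per signal, per level: median across participants of per-participant means (mm)
    medians: dict[str, dict[str, float]] = field(default_factory=dict)

    def for_signal(self, signal: str) -> list[PairedTestResult]:
        return [t for t in self.tests if t.signal == signal]

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis,
            "tests": [t.to_dict() for t in self.tests],
            "medians": self.medians,
        }


# ---------------------------------------------------------------------------
# primitives


def event_mean(trace: np.ndarray, event: ExpressionEvent) -> float:
    return float(np.mean(trace[event.start : event.end]))


def mean_movement(
    traces: ProcessedTraces,
    events: list[ExpressionEvent],
    signal: str,
    predicate=None,
) -> dict[str, float]:
    """Per-expression mean movement (mm) for one participant.

    The per-instance statistic is the trace mean over the event interval; the
    per-expression value averages instances passing ``predicate``.
    """
    trace = traces.signal(signal)
    sums: dict[str, list[float]] = {e: [] for e in vocab.EXPRESSIONS}
    for ev in events:
        if predicate is not None and not predicate(ev):
            continue
        sums[ev.expression].append(event_mean(trace, ev))
    out = {}
    for expr, vals in sums.items():
        if not vals:
            raise MissingConditionError(
                f"participant {traces.participant_id}: no events for {expr!r} under the given filter"
            )
        out[expr] = float(np.mean(vals))
    return out


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded; the exact null distribution is used for
    n <= 25 non-zero differences without ties, otherwise the normal
    approximation with tie and continuity correction.  Identical samples give
    p = 1 with a warning.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and of equal length")
    if a.size < 5:
        raise ValueError("paired test requires at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    ranks_tied = len(np.unique(np.abs(d))) < d.size
    if d.size <= 25 and not ranks_tied:
        res = spstats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
    else:
        res = spstats.wilcoxon(
            d, zero_method="wilcox", alternative="two-sided", method="approx", correction=True
        )
    return float(res.pvalue)


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) for a family of m tests."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    p = np.asarray(p_values, float)
    if m < p.size:
        raise ValueError("family size m must cover the number of tests")
    return np.minimum(1.0, m * p)


def annotate(p_adjusted: float) -> str:
    """Descending significance ladder: **** < 1e-4 ... * < 0.05, else ns."""
    if not (0 <= p_adjusted <= 1):
        raise ValueError("p must lie in [0, 1]")
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (ALPHA, "*")):
        if p_adjusted < threshold:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# analyses


def _level_table(
    cohort_traces: list[ProcessedTraces],
    cohort_events: list[list[ExpressionEvent]],
    signal: str,
    levels: list[str],
    level_of,
    event_filter,
) -> pd.DataFrame:
    """Participants x condition-levels table of mean movement (mm)."""
    rows = []
    for traces, events in zip(cohort_traces, cohort_events, strict=True):
        trace = traces.signal(signal)
        cells: dict[str, list[float]] = {lv: [] for lv in levels}
        for ev in events:
            if not event_filter(ev):
                continue
            lv = level_of(ev)
            if lv in cells:
                cells[lv].append(event_mean(trace, ev))
        row = {}
        for lv in levels:
            if not cells[lv]:
                raise MissingConditionError(
                    f"participant {traces.participant_id}: no events for level {lv!r} ({signal})"
                )
            row[lv] = float(np.mean(cells[lv]))
        rows.append(row)
    return pd.DataFrame(rows, index=[t.participant_id for t in cohort_traces])


def _paired_family(
    table: pd.DataFrame, signal: str, pairs: list[tuple[str, str]], m: int
) -> list[PairedTestResult]:
    raw = [wilcoxon_signed_rank(table[a].to_numpy(), table[b].to_numpy()) for a, b in pairs]
    adj = bonferroni(raw, m)
    return [
        PairedTestResult(
            signal=signal,
            pair=(a, b),
            p_raw=float(p),
            p_adjusted=float(q),
            family_size=m,
            annotation=annotate(float(q)),
            median_a=float(table[a].median()),
            median_b=float(table[b].median()),
        )
        for (a, b), p, q in zip(pairs, raw, adj, strict=True)
    ]


def run_expression_comparison(
    cohort_traces: list[ProcessedTraces],
    cohort_events: list[list[ExpressionEvent]],
    intensity: str = "high",
) -> ComparisonResult:
    """All-pairs expression comparison at one intensity (short+long pooled).

    Six pairwise tests per signal, Bonferroni family m = 6 per signal.
    """
    if intensity not in vocab.INTENSITIES:
        raise ValueError(f"unknown intensity {intensity!r}")
    pairs = list(itertools.combinations(vocab.EXPRESSIONS, 2))
    result = ComparisonResult(analysis=f"expressions_{intensity}", tests=[])
    for signal in ("cheek", "brow"):
        table = _level_table(
            cohort_traces,
            cohort_events,
            signal,
            list(vocab.EXPRESSIONS),
            level_of=lambda ev: ev.expression,
            event_filter=lambda ev: ev.task == "A" and ev.intensity == intensity,
        )
        result.tests.extend(_paired_family(table, signal, pairs, m=6))
        result.medians[signal] = {lv: float(table[lv].median()) for lv in table.columns}
    return result


def run_movement_comparison(
    cohort_traces: list[ProcessedTraces],
    cohort_events: list[list[ExpressionEvent]],
) -> ComparisonResult:
    """Head still vs moving, per expression (high-intensity, 3 s events only).

    One test per expression per signal, Bonferroni family m = 4 per signal.
    """
    result = ComparisonResult(analysis="head_movement", tests=[])
    for signal in ("cheek", "brow"):
        for expr in vocab.EXPRESSIONS:
            table = _level_table(
                cohort_traces,
                cohort_events,
                signal,
                ["still", "moving"],
                level_of=lambda ev: "still" if ev.head_movement == "none" else "moving",
                event_filter=lambda ev, e=expr: (
                    ev.task in ("A", "B")
                    and ev.expression == e
                    and ev.intensity == "high"
                    and ev.duration == "long"
                ),
            )
            res = _paired_family(table, signal, [("still", "moving")], m=4)[0]
            result.tests.append(
                PairedTestResult(
                    signal=signal,
                    pair=(f"{expr}:still", f"{expr}:moving"),
                    p_raw=res.p_raw,
                    p_adjusted=res.p_adjusted,
                    family_size=res.family_size,
                    annotation=res.annotation,
                    median_a=res.median_a,
                    median_b=res.median_b,
                )
            )
    return result


def run_position_comparison(
    cohort_traces: list[ProcessedTraces],
    cohort_events: list[list[ExpressionEvent]],
) -> ComparisonResult:
    """Glasses position (low/medium/high), per expression, high intensity.

    Three pairwise position tests per expression per signal, Bonferroni
    family m = 3 within each (expression, signal).
    """
    pos_pairs = [("high", "medium"), ("high", "low"), ("medium", "low")]
    result = ComparisonResult(analysis="glasses_position", tests=[])
    for signal in ("cheek", "brow"):
        for expr in vocab.EXPRESSIONS:
            table = _level_table(
                cohort_traces,
                cohort_events,
                signal,
                list(vocab.GLASSES_POSITIONS),
                level_of=lambda ev: ev.glasses_position,
                event_filter=lambda ev, e=expr: ev.task == "C" and ev.expression == e,
            )
            for res in _paired_family(table, signal, pos_pairs, m=3):
                result.tests.append(
                    PairedTestResult(
                        signal=signal,
                        pair=(f"{expr}:{res.pair[0]}", f"{expr}:{res.pair[1]}"),
                        p_raw=res.p_raw,
                        p_adjusted=res.p_adjusted,
                        family_size=res.family_size,
                        annotation=res.annotation,
                        median_a=res.median_a,
                        median_b=res.median_b,
                    )
                )
    return result
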