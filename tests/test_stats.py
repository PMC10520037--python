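import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omgpipe import vocab
from omgpipe.preprocessing import ProcessedTraces
from omgpipe.recording import ExpressionEvent
from omgpipe.stats import (
    MissingConditionError,
    annotate,
    bonferroni,
    mean_movement,
    run_expression_comparison,
    run_movement_comparison,
    wilcoxon_signed_rank,
)
from omgpipe.synthetic import GeneratorConfig, generate_cohort
from omgpipe.protocol import task_a
from omgpipe import preprocess_for_statistics


def signflip_wilcoxon_oracle(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Zero differences are discarded and |d| is ranked; the p-value is the
    symmetric two-tail probability 2*min(P(W <= w), P(W >= w)) capped at 1,
    with W the positive-rank sum under random sign flips.
    """
    d = diffs[diffs != 0]
    n = len(d)
    ranks = np.empty(n)
    order = np.argsort(np.abs(d))
    ranks[order] = np.arange(1, n + 1)
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_identical_samples_p_one_with_warning(self):
        a = np.arange(6.0)
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank(a, a) == 1.0

    def test_six_positive_differences_exact(self):
        # all-positive differences at n=6: both tails contribute 1/64 each
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        b = a - np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert wilcoxon_signed_rank(a, b) == pytest.approx(2 / 64)

    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False).filter(lambda x: abs(x) > 1e-6),
            min_size=5,
            max_size=12,
            unique_by=lambda x: round(abs(x), 6),
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_signflip_enumeration(self, diffs):
        d = np.array(diffs)
        p_impl = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p_impl == pytest.approx(signflip_wilcoxon_oracle(d), abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [0.0, 1.0])


class TestBonferroni:
    def test_known_values(self):
        assert bonferroni([0.01], 6) == pytest.approx([0.06])
        assert bonferroni([0.5], 6) == pytest.approx([1.0])
        assert bonferroni([0.0], 1000) == pytest.approx([0.0])

    def test_monotone_in_p(self, rng):
        p = np.sort(rng.random(6))
        adj = bonferroni(p, 6)
        assert (np.diff(adj) >= 0).all()

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            bonferroni([0.1], 0)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestAnnotate:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.2, "ns"),
            (0.05, "ns"),
            (0.03, "*"),
            (0.005, "**"),
            (5e-4, "***"),
            (5e-5, "****"),
        ],
    )
    def test_ladder(self, p, expected):
        assert annotate(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            annotate(1.5)


def _fake_participant(event_means: dict[str, list[float]], trace_len=4000):
    """Build traces + events whose cheek event means equal the given values."""
    trace = np.zeros(trace_len)
    events, cursor = [], 0
    for expr, means in event_means.items():
        for m in means:
            trace[cursor : cursor + 50] = m
            events.append(
                ExpressionEvent(
                    expression=expr,
                    start=cursor,
                    end=cursor + 50,
                    intensity="high",
                    duration="short",
                    task="A",
                )
            )
            cursor += 100
    traces = ProcessedTraces(participant_id="F", cheek=trace, brow=trace.copy())
    return traces, events


class TestMeanMovement:
    def test_constant_trace_returns_constant(self):
        traces, events = _fake_participant({e: [4.0, 4.0] for e in vocab.EXPRESSIONS})
        means = mean_movement(traces, events, "cheek")
        assert all(v == pytest.approx(4.0) for v in means.values())

    def test_two_instances_average(self):
        traces, events = _fake_participant(
            {"smile": [4.0, 6.0], "frown": [1.0], "brow_raise": [1.0], "squeezed_eyes": [1.0]}
        )
        assert mean_movement(traces, events, "cheek")["smile"] == pytest.approx(5.0)

    def test_missing_condition_raises(self):
        traces, events = _fake_participant({"smile": [4.0]})
        with pytest.raises(MissingConditionError, match="brow_raise"):
            mean_movement(traces, events, "cheek")


class TestComparisons:
    def test_identical_levels_give_p_one(self):
        cohort = [_fake_participant({e: [float(i + 1)] * 2 for e in vocab.EXPRESSIONS}) for i in range(27)]
        traces = [c[0] for c in cohort]
        events = [c[1] for c in cohort]
        with pytest.warns(UserWarning):
            res = run_expression_comparison(traces, events, "high")
        assert len(res.tests) == 12  # 6 pairs x 2 signals
        assert all(t.p_adjusted == 1.0 for t in res.tests)
        assert all(t.family_size == 6 for t in res.tests)

    def test_designed_direction_recovered(self, traces_events_a6):
        traces, events = traces_events_a6
        res = run_expression_comparison(traces, events, "high")
        med = res.medians
        assert med["cheek"]["smile"] > med["cheek"]["brow_raise"]
        assert med["brow"]["brow_raise"] == max(med["brow"].values())
        assert med["brow"]["smile"] == min(med["brow"].values())

    def test_uniform_coupling_controls_type_one_error(self):
        # designed null: all expressions share one coupling row and the
        # glasses-position gains are flattened -> no family should fire often
        from omgpipe.synthetic import CouplingMatrix, PositionGains, default_coupling

        table = default_coupling().table.copy()
        for e in vocab.EXPRESSIONS:
            table.loc[e] = table.loc["smile"]
        cfg = GeneratorConfig(
            coupling=CouplingMatrix(table), position_gains=PositionGains.identity()
        )
        family_hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort = generate_cohort(15, protocols=(task_a(),), seed=1000 + seed, config=cfg)
            traces = [preprocess_for_statistics(r) for r in cohort]
            events = [r.events for r in cohort]
            res = run_expression_comparison(traces, events, "high")
            for signal in ("cheek", "brow"):
                if any(t.significant for t in res.for_signal(signal)):
                    family_hits += 1
        assert family_hits / (2 * n_seeds) <= 0.1

    def test_movement_comparison_requires_task_b(self, traces_events_a6):
        traces, events = traces_events_a6
        with pytest.raises(MissingConditionError):
            run_movement_comparison(traces, events)
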