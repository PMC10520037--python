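import numpy as np
import pytest
from scipy.signal import periodogram

from omgpipe import vocab
from omgpipe.protocol import task_a, task_b
from omgpipe.recording import ExpressionEvent
from omgpipe.synthetic import (
    CouplingMatrix,
    GeneratorConfig,
    GeneratorConfigError,
    ParticipantProfile,
    PositionGains,
    apply_glasses_position,
    apply_head_movement,
    default_coupling,
    generate_cohort,
    head_movement_artifact,
    render_expression,
    sample_profile,
    trapezoid_envelope,
)


def _profile(rng):
    return sample_profile("P00", rng, GeneratorConfig())


class TestCoupling:
    def test_calibrated_coupling_orderings(self):
        table = default_coupling().table
        cheek = table[list(vocab.CHEEK_SITES)].sum(axis=1)
        brow = table[list(vocab.BROW_SITES)].sum(axis=1)
        assert (table.to_numpy() >= 0).all()
        assert min(cheek["smile"], cheek["squeezed_eyes"]) > max(
            cheek["brow_raise"], cheek["frown"]
        )
        assert brow["brow_raise"] == brow.max()
        assert brow["smile"] == brow.min()

    def test_invalid_coupling_rejected(self):
        table = default_coupling().table.copy()
        table.iloc[0, 0] = -1.0
        with pytest.raises(GeneratorConfigError):
            CouplingMatrix(table)


class TestCohort:
    def test_event_count_per_participant(self, cohort3):
        # 3 reps x 14 condition groups x 4 expressions
        assert all(len(r.events) == 168 for r in cohort3)

    def test_task_a_only_has_no_head_movement(self):
        rec = generate_cohort(1, protocols=(task_a(),), seed=5)[0]
        assert set(rec.labels["head_movement"]) == {"none"}
        assert all(e.head_movement == "none" for e in rec.events)

    def test_same_seed_bit_identical(self):
        a = generate_cohort(2, protocols=(task_a(),), seed=7)
        b = generate_cohort(2, protocols=(task_a(),), seed=7)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data.to_numpy(), rb.data.to_numpy())
            assert ra.events == rb.events
            assert (ra.labels == rb.labels).all().all()

    def test_different_seed_differs(self):
        a = generate_cohort(1, protocols=(task_a(),), seed=7)[0]
        b = generate_cohort(1, protocols=(task_a(),), seed=8)[0]
        assert not np.array_equal(a.data.to_numpy(), b.data.to_numpy())

    def test_labels_consistent_with_events(self, recording):
        expr = recording.labels["expression"].to_numpy()
        inside = np.zeros(recording.n_samples, bool)
        for ev in recording.events:
            assert (expr[ev.start : ev.end] == ev.expression).all()
            inside[ev.start : ev.end] = True
        assert (expr[~inside] == vocab.NEUTRAL).all()

    def test_timestamps_uniform(self, recording):
        steps = np.diff(recording.timestamps)
        assert np.allclose(steps, 0.02, atol=1e-9)

    def test_bad_config_rejected(self):
        with pytest.raises(GeneratorConfigError):
            generate_cohort(0, seed=1)
        with pytest.raises(GeneratorConfigError):
            generate_cohort(1, protocols=(), seed=1)


class TestRenderExpression:
    def _event(self, n=150, expression="smile", intensity="high"):
        return ExpressionEvent(
            expression=expression, start=0, end=n, intensity=intensity, duration="long"
        )

    def test_noiseless_plateau_matches_coupling(self, rng):
        profile = _profile(rng)
        coupling = default_coupling()
        seg = render_expression(self._event(), coupling, profile, rng=None)
        mid = seg[60:90]  # plateau
        for j, site in enumerate(vocab.SITES):
            mag = np.linalg.norm(mid[:, 3 * j : 3 * j + 3], axis=1)
            expected = (
                coupling.value("smile", site)
                * profile.amplitude_scale[site]
                * profile.expression_gain["%s:smile" % site.split("_")[0]]
            )
            assert mag == pytest.approx(expected, rel=1e-9)

    def test_zero_coupling_row_gives_silence(self, rng):
        profile = _profile(rng)
        table = default_coupling().table.copy()
        table.loc["smile"] = 0.0
        seg = render_expression(self._event(), CouplingMatrix(table), profile, rng=None)
        assert np.abs(seg).max() == 0.0

    def test_amplitude_scale_is_linear(self, rng):
        profile = _profile(rng)
        doubled = ParticipantProfile(
            participant_id=profile.participant_id,
            amplitude_scale={k: 2 * v for k, v in profile.amplitude_scale.items()},
            expression_gain=profile.expression_gain,
            trial_sigma=profile.trial_sigma,
            noise_std_mm=profile.noise_std_mm,
            drift_slope_mm_s=profile.drift_slope_mm_s,
            offset_mm=profile.offset_mm,
            attenuation=profile.attenuation,
            directions=profile.directions,
        )
        seg1 = render_expression(self._event(), default_coupling(), profile, rng=None)
        seg2 = render_expression(self._event(), default_coupling(), doubled, rng=None)
        assert np.allclose(seg2, 2 * seg1)

    def test_low_intensity_attenuated(self, rng):
        profile = _profile(rng)
        hi = render_expression(self._event(), default_coupling(), profile, rng=None)
        lo = render_expression(
            self._event(intensity="low"), default_coupling(), profile, rng=None
        )
        assert np.allclose(lo, profile.attenuation * hi)

    def test_too_short_event_rejected(self, rng):
        with pytest.raises(GeneratorConfigError):
            render_expression(self._event(n=10), default_coupling(), _profile(rng))


class TestHeadMovement:
    def test_artifact_integrates_to_zero(self):
        art = head_movement_artifact(150, "up")
        assert np.abs(art.mean(axis=0)).max() < 1e-12

    def test_artifact_power_below_1hz(self):
        art = head_movement_artifact(150, "left")[:, 0]
        freqs, power = periodogram(art, fs=50.0)
        assert power[freqs < 1.0].sum() / power.sum() > 0.95

    def test_unknown_direction_rejected(self):
        with pytest.raises(GeneratorConfigError):
            head_movement_artifact(150, "backwards")

    def test_mean_magnitude_shift_small_on_neutral_segments(self):
        # artifact-induced shift of the mean vector magnitude stays below 5%
        # of a high-intensity smile cheek plateau (~7 mm per site)
        plateau = default_coupling().value("smile", "cheek_left")
        shifts = []
        for seed in range(100):
            seg = np.random.default_rng(seed).normal(0.0, 0.12, (150, 18))
            moved = apply_head_movement(seg, "up")
            for j in range(6):
                before = np.linalg.norm(seg[:, 3 * j : 3 * j + 3], axis=1).mean()
                after = np.linalg.norm(moved[:, 3 * j : 3 * j + 3], axis=1).mean()
                shifts.append(abs(after - before))
        assert max(shifts) < 0.05 * plateau


class TestGlassesPosition:
    def test_brow_gain_ordering(self):
        gains = PositionGains()
        for expr in ("brow_raise", "frown", "squeezed_eyes"):
            g = [gains.gain(expr, "brow_left", p) for p in ("low", "medium", "high")]
            assert g[2] > g[1] >= g[0]
        assert all(gains.gain("smile", "cheek_left", p) == 1.0 for p in vocab.GLASSES_POSITIONS)

    def test_identity_config_is_noop(self, rng):
        activation = rng.random((100, 6))
        out = apply_glasses_position(activation, "brow_raise", "high", PositionGains.identity())
        assert np.array_equal(out, activation)

    def test_position_scales_brow_activation(self, rng):
        activation = np.ones((10, 6))
        out = apply_glasses_position(activation, "brow_raise", "high")
        gains = PositionGains()
        for j, site in enumerate(vocab.SITES):
            assert out[0, j] == pytest.approx(gains.gain("brow_raise", site, "high"))

    def test_unknown_position_rejected(self, rng):
        with pytest.raises(GeneratorConfigError):
            apply_glasses_position(np.ones((5, 6)), "smile", "tilted")


class TestProfile:
    def test_profile_invariants(self, rng):
        profile = _profile(rng)
        assert all(v > 0 for v in profile.amplitude_scale.values())
        assert 0 < profile.attenuation < 1
        for u in profile.directions.values():
            assert np.linalg.norm(u) == pytest.approx(1.0)

    def test_invalid_profile_rejected(self, rng):
        profile = _profile(rng)
        with pytest.raises(GeneratorConfigError):
            ParticipantProfile(
                participant_id="X",
                amplitude_scale={k: -1.0 for k in profile.amplitude_scale},
                expression_gain=profile.expression_gain,
                noise_std_mm=0.1,
                drift_slope_mm_s=profile.drift_slope_mm_s,
                offset_mm=profile.offset_mm,
                attenuation=0.5,
                directions=profile.directions,
            )


def test_trapezoid_envelope_shape():
    env = trapezoid_envelope(150, 50.0, ramp_s=0.25)
    assert env[0] == 0.0
    assert env[len(env) // 2] == 1.0
    assert np.allclose(env[1:], env[1:][::-1], atol=1e-9)  # symmetric about D/2
    assert env.min() >= 0 and env.max() <= 1
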