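"""Synthetic trial generation, trace rendering, and round-trip recovery."""

import numpy as np
import pytest

from ambifocal.model import ModelParams
from ambifocal.synth import (
    BACKGROUND,
    RenderConfig,
    TrialGroundTruth,
    generate_trial_events,
    render_gaze_trace,
)

FS = 2000.0


def mk(p_sw=0.2, pie=0.1, pte=0.9, pil=0.9, ptl=0.55, p_bg=0.2, n_fix=12, init="object"):
    return ModelParams(p_sw, pie, pte, pil, ptl, p_bg, n_fix, init)


class TestTrialGeneration:
    def test_counts_and_spatial_invariants(self, layout5):
        truth = generate_trial_events(mk(), layout5, seed=5)
        assert len(truth.saccade_list) == truth.n_fixations - 1
        centers = layout5.centers
        by_id = {o.id: o for o in layout5.objects}
        for label, pos in zip(truth.fixation_labels, truth.fixation_positions):
            d = np.hypot(centers[:, 0] - pos[0], centers[:, 1] - pos[1])
            if label == BACKGROUND:
                assert d.min() > 1.5
            else:
                obj = by_id[label]
                assert np.hypot(pos[0] - obj.x, pos[1] - obj.y) <= obj.radius

    def test_forced_trans_chain_links_distinct_objects(self, layout5):
        params = mk(p_sw=0.0, pie=0.0, pte=1.0, p_bg=0.0)
        truth = generate_trial_events(params, layout5, seed=2)
        labels = truth.fixation_labels
        assert all(a != b for a, b in zip(labels, labels[1:]))
        assert BACKGROUND not in labels

    def test_all_background_after_protected_first(self, layout5):
        truth = generate_trial_events(mk(p_bg=1.0), layout5, seed=3)
        assert truth.fixation_labels[0] != BACKGROUND
        assert all(l == BACKGROUND for l in truth.fixation_labels[1:])

    def test_switch_step_matches_geometric_expectation(self, layout5):
        # censoring at n_fix=21 slightly lowers the observed mean below 1/p
        steps = []
        rng = np.random.default_rng(11)
        for _ in range(800):
            truth = generate_trial_events(mk(n_fix=21), layout5, seed=rng)
            if truth.true_switch_step is not None:
                steps.append(truth.true_switch_step - 1)
        assert 4.2 < np.mean(steps) < 5.2

    def test_durations_increase_over_trial(self, layout5):
        durs = np.zeros((300, 12))
        rng = np.random.default_rng(8)
        for k in range(300):
            truth = generate_trial_events(mk(), layout5, seed=rng)
            durs[k] = truth.fixation_durations
        mean = durs.mean(axis=0)
        assert mean[-1] > mean[0]
        assert np.corrcoef(np.arange(12), mean)[0, 1] > 0.9

    def test_consecutive_fixations_are_separated(self, layout5):
        truth = generate_trial_events(mk(p_bg=0.4), layout5, seed=13)
        assert truth.saccade_amplitudes.min() >= 0.5

    def test_two_object_minimum(self, layout5):
        single = type(layout5)(layout5.width, layout5.height, layout5.objects[:1])
        with pytest.raises(ValueError, match="at least 2"):
            generate_trial_events(mk(), single, seed=0)

    def test_seed_determinism(self, layout5):
        a = generate_trial_events(mk(), layout5, seed=99)
        b = generate_trial_events(mk(), layout5, seed=99)
        assert np.array_equal(a.fixation_positions, b.fixation_positions)
        assert np.array_equal(a.fixation_durations, b.fixation_durations)
        assert a.fixation_labels == b.fixation_labels


class TestRendering:
    def test_single_saccade_displacement_exact(self):
        truth = TrialGroundTruth(
            np.array([[0.0, 0.0], [5.0, 0.0]]), np.array([0.3, 0.3]),
            [1, 2], [(0, 1)], None,
        )
        trace = render_gaze_trace(truth, RenderConfig(sampling_rate=FS))
        assert trace.x[-1] - trace.x[0] == pytest.approx(5.0)
        assert trace.stimulus_onset == 0.5

    def test_fixation_only_trace_is_static(self):
        truth = TrialGroundTruth(
            np.array([[1.0, -2.0]]), np.array([0.5]), [1], [], None,
        )
        trace = render_gaze_trace(truth, RenderConfig(sampling_rate=FS))
        assert np.all(np.gradient(trace.x) == 0)
        assert np.all(np.gradient(trace.y) == 0)

    def test_raised_cosine_peak_velocity_closed_form(self):
        # peak velocity of the cosine-bell profile is twice the mean, 2A/D
        cfg = RenderConfig(sampling_rate=20_000.0,
                           saccade_duration_intercept=0.02,
                           saccade_duration_slope=0.002)
        A = 2.0
        D = cfg.saccade_duration(A)
        truth = TrialGroundTruth(
            np.array([[0.0, 0.0], [A, 0.0]]), np.array([0.3, 0.3]),
            [1, 2], [(0, 1)], None,
        )
        trace = render_gaze_trace(truth, cfg)
        peak = np.abs(np.gradient(trace.x, trace.t)).max()
        assert D == pytest.approx(0.024)
        assert peak == pytest.approx(2 * A / D, rel=0.01)  # 166.7 deg/s

    def test_sampling_rate_too_low_rejected(self):
        truth = TrialGroundTruth(
            np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([0.3, 0.3]),
            [1, 2], [(0, 1)], None,
        )
        with pytest.raises(ValueError, match="5 samples"):
            render_gaze_trace(truth, RenderConfig(sampling_rate=200.0))

    def test_nonpositive_duration_rejected(self):
        truth = TrialGroundTruth(
            np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([0.3, -0.1]),
            [1, 2], [(0, 1)], None,
        )
        with pytest.raises(ValueError, match="positive"):
            render_gaze_trace(truth, RenderConfig(sampling_rate=FS))


class TestRoundTrip:
    def test_detection_recovers_all_saccades_exactly(self, rendered_suite):
        """Noise-free render -> detect: recall and precision are 1 and
        amplitudes match within 0.05 deg (events after the exclusion
        window; the generator's first saccade may fall within 150 ms)."""
        for item in rendered_suite:
            truth, trace = item["truth"], item["trace"]
            detected = [s.base for s in item["trial"].saccades]
            true_amps = truth.saccade_amplitudes
            onset = trace.stimulus_onset
            # ground-truth saccade onsets
            t_cursor = onset + truth.fixation_durations[0]
            expected = []
            for j, amp in enumerate(true_amps):
                dur = 0.012 + 0.0012 * amp
                if not (onset < t_cursor < onset + 0.15):
                    expected.append((t_cursor, amp))
                t_cursor += dur + truth.fixation_durations[j + 1]
            assert len(detected) == len(expected)
            for det, (t_exp, amp) in zip(detected, expected):
                assert det.onset == pytest.approx(t_exp, abs=0.01)
                assert det.amplitude == pytest.approx(amp, abs=0.05)

    def test_labels_round_trip(self, rendered_suite, layout5):
        """Classification of noise-free rendered fixations reproduces the
        generator's labels (fixations near the 1.5 deg boundary exempt)."""
        centers = layout5.centers
        for item in rendered_suite:
            truth = item["truth"]
            fixations = item["trial"].fixations
            # match detected fixations to truth by position
            truth_by_pos = {
                (round(p[0], 3), round(p[1], 3)): lab
                for p, lab in zip(truth.fixation_positions, truth.fixation_labels)
            }
            for fix in fixations:
                key = (round(fix.base.position[0], 3), round(fix.base.position[1], 3))
                if key not in truth_by_pos:
                    continue
                true_label = truth_by_pos[key]
                d = np.hypot(
                    centers[:, 0] - fix.base.position[0],
                    centers[:, 1] - fix.base.position[1],
                ).min()
                if abs(d - 1.5) < 0.1:
                    continue
                if true_label == BACKGROUND:
                    assert fix.kind == "background"
                else:
                    assert fix.kind == "object"
                    assert fix.fixated_object == true_label
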