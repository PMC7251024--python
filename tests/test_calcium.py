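"""ΔF/F, noise floor, response scoring, classification and event counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vivoseq as v
from vivoseq.calcium import DegenerateBaselineError, analyze_trace, invert_dff

FR = 30.0


def make_trace(net, cell_id="c0", bg_level=1.0):
    """Trace pair whose background-subtracted signal equals ``net``."""
    net = np.asarray(net, dtype=float)
    bg = np.full_like(net, bg_level)
    return v.FluorescenceTrace(cell_id=cell_id, f_cell=bg + net, f_background=bg,
                               frame_rate_hz=FR)


def n_frames(protocol):
    total = protocol.onsets_s[-1] + protocol.stim_duration_s + protocol.isi_s
    return int(round(total * FR))


class TestComputeDff:
    def test_constant_trace_is_zero(self, simple_protocol):
        net = np.full(n_frames(simple_protocol), 1.0)
        dff = v.compute_dff(make_trace(net), simple_protocol)
        assert dff.f0 == pytest.approx(1.0)
        assert np.allclose(dff.values, 0.0)

    def test_doubling_gives_unit_dff(self, simple_protocol):
        net = np.full(n_frames(simple_protocol), 2.0)
        sl = simple_protocol.stim_slices()[0]
        net[sl.start + 5] = 4.0  # net doubles from F0 inside the first window
        dff = v.compute_dff(make_trace(net), simple_protocol)
        assert np.max(dff.values[sl]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self, simple_protocol, rng):
        nf = n_frames(simple_protocol)
        f_cell = 5.0 + rng.random(nf)
        f_bg = 1.0 + 0.1 * rng.random(nf)
        trace = v.FluorescenceTrace("c", f_cell, f_bg, FR)
        dff = v.compute_dff(trace, simple_protocol)
        # independent two-line oracle
        net = f_cell - f_bg
        f0 = np.concatenate([net[sl] for sl in simple_protocol.baseline_slices()]).mean()
        assert np.allclose(dff.values, (net - f0) / f0, atol=1e-12)

    def test_round_trip_reconstructs_input(self, simple_protocol, rng):
        nf = n_frames(simple_protocol)
        f_bg = 1.0 + 0.1 * rng.random(nf)
        f_cell = f_bg + 2.0 + rng.random(nf)
        trace = v.FluorescenceTrace("c", f_cell, f_bg, FR)
        dff = v.compute_dff(trace, simple_protocol)
        assert np.allclose(invert_dff(dff, f_bg), f_cell, atol=1e-10)

    def test_nonpositive_baseline_rejected(self, simple_protocol):
        net = np.full(n_frames(simple_protocol), -1.0)
        with pytest.raises(DegenerateBaselineError):
            v.compute_dff(make_trace(net), simple_protocol)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            v.FluorescenceTrace("c", np.ones(10), np.ones(9))


class TestEstimateNoise:
    def test_gaussian_baseline_recovered(self, simple_protocol, rng):
        nf = n_frames(simple_protocol)
        dff = v.DffTrace(rng.normal(0.0, 0.02, nf), f0=1.0)
        est = v.estimate_noise(dff, simple_protocol)
        assert 0.018 <= est <= 0.022

    def test_constant_trace_warns_and_returns_zero(self, simple_protocol):
        dff = v.DffTrace(np.zeros(n_frames(simple_protocol)), f0=1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert v.estimate_noise(dff, simple_protocol) == 0.0

    def test_stimulus_samples_excluded(self, simple_protocol, rng):
        nf = n_frames(simple_protocol)
        base = rng.normal(0.0, 0.02, nf)
        spiked = base.copy()
        sl = simple_protocol.stim_slices()[2]
        spiked[sl] += 5.0  # huge transient confined to a stimulus window
        est_clean = v.estimate_noise(v.DffTrace(base, 1.0), simple_protocol)
        est_spiked = v.estimate_noise(v.DffTrace(spiked, 1.0), simple_protocol)
        assert est_spiked == pytest.approx(est_clean)


class TestScoreRepetitions:
    def test_noiseless_designed_five_of_five(self, simple_protocol):
        traces, protocol, _ = v.gen_calcium_cohort(
            v.CalciumSimParams(n_cells=1, response_design=(5,), noise_sd=0.0, seed=0)
        )
        dff = v.compute_dff(traces[0], protocol)
        assert v.score_repetitions(dff, protocol, 0.0) == [True] * 5

    def test_peak_exactly_twice_noise_is_positive(self, simple_protocol):
        vals = np.zeros(n_frames(simple_protocol))
        sl = simple_protocol.stim_slices()[0]
        vals[sl.start + 3] = 0.04  # exactly 2 x noise: inclusive threshold
        pos = v.score_repetitions(v.DffTrace(vals, 1.0), simple_protocol, 0.02)
        assert pos == [True, False, False, False, False]

    def test_transient_between_windows_not_counted(self, simple_protocol):
        vals = np.zeros(n_frames(simple_protocol))
        # between the end of window 0 and the start of window 1
        vals[int(25 * FR)] = 1.0
        pos = v.score_repetitions(v.DffTrace(vals, 1.0), simple_protocol, 0.02)
        assert pos == [False] * 5

    def test_window_outside_trace_names_repetition(self, simple_protocol):
        vals = np.zeros(int(40 * FR))  # only covers two repetitions
        with pytest.raises(IndexError, match="window"):
            v.score_repetitions(v.DffTrace(vals, 1.0), simple_protocol, 0.02)


class TestClassifyCell:
    @pytest.mark.parametrize(
        "n_pos,label",
        [(0, "NS"), (1, "NS"), (2, "excluded"), (3, "excluded"), (4, "LS"), (5, "LS")],
    )
    def test_three_way_rule(self, n_pos, label):
        positives = [True] * n_pos + [False] * (5 - n_pos)
        assert v.classify_cell(positives) == label

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            v.classify_cell([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.booleans(), min_size=1, max_size=8), st.randoms())
    def test_label_invariant_under_repetition_order(self, positives, rnd):
        shuffled = positives[:]
        rnd.shuffle(shuffled)
        assert v.classify_cell(shuffled) == v.classify_cell(positives)


class TestResponseMagnitude:
    def test_flat_trace_zero(self, simple_protocol):
        vals = np.zeros(n_frames(simple_protocol))
        assert v.response_magnitude(v.DffTrace(vals, 1.0), simple_protocol) == 0.0

    def test_noiseless_transients_recovered(self, simple_protocol):
        vals = np.zeros(n_frames(simple_protocol))
        for sl in simple_protocol.stim_slices():
            vals[sl.start + 10] = 0.5
        mag = v.response_magnitude(v.DffTrace(vals, 1.0), simple_protocol)
        assert mag == pytest.approx(0.5, abs=1e-12)

    def test_matches_windowed_oracle(self, simple_protocol, rng):
        vals = rng.normal(0.0, 0.1, n_frames(simple_protocol))
        mag = v.response_magnitude(v.DffTrace(vals, 1.0), simple_protocol)
        # brute-force oracle over explicit frame windows
        diffs = []
        for onset in simple_protocol.onsets_s:
            post = vals[int(onset * FR): int((onset + 5) * FR) + 1]
            pre = vals[int((onset - 4) * FR): int((onset - 2) * FR) + 1]
            diffs.append(post.max() - pre.mean())
        assert mag == pytest.approx(np.mean(diffs), abs=1e-12)

    def test_incomplete_window_names_repetition(self):
        protocol = v.StimulusProtocol(onsets_s=(2.0,))  # pre-window starts before 0
        with pytest.raises(IndexError, match="repetition 0"):
            v.response_magnitude(v.DffTrace(np.zeros(600), 1.0), protocol)


class TestCountEvents:
    def test_flat_trace(self):
        assert v.count_events(v.DffTrace(np.zeros(300), 1.0), 0.02) == 0

    def test_three_separated_transients(self):
        vals = np.zeros(300)
        vals[[50, 150, 250]] = 1.0
        assert v.count_events(v.DffTrace(vals, 1.0), 0.02) == 3

    def test_merged_double_peak_counts_once(self):
        vals = np.zeros(300)
        # two peaks above 2x noise joined by a bridge above 1x noise
        vals[100:120] = 0.03
        vals[100] = vals[119] = 0.08
        assert v.count_events(v.DffTrace(vals, 1.0), 0.02) == 1

    def test_dip_below_noise_splits_events(self):
        vals = np.zeros(300)
        vals[100] = 0.08
        vals[101:110] = 0.01  # below 1x noise ends the excursion
        vals[110] = 0.08
        assert v.count_events(v.DffTrace(vals, 1.0), 0.02) == 2


class TestCohortRecovery:
    def test_amplitude_scaling_never_decreases_positives(self, simple_protocol):
        traces, protocol, _ = v.gen_calcium_cohort(
            v.CalciumSimParams(n_cells=6, response_design=(0, 1, 2, 3, 4, 5),
                               transient_amplitude_snr=5.0, seed=2)
        )
        for c in (1.0, 1.5, 3.0):
            for tr in traces:
                dff = v.compute_dff(tr, protocol)
                noise = v.estimate_noise(dff, protocol)
                scaled = v.DffTrace(dff.values * c, dff.f0)
                n_scaled = sum(v.score_repetitions(scaled, protocol, noise))
                n_base = sum(v.score_repetitions(dff, protocol, noise))
                assert n_scaled >= n_base

    def test_noisy_snr5_recovery_at_least_95_percent(self):
        design = tuple([0, 1, 2, 3, 4, 5] * 14)[:80]
        traces, protocol, truth = v.gen_calcium_cohort(
            v.CalciumSimParams(n_cells=80, response_design=design,
                               transient_amplitude_snr=5.0, seed=17)
        )
        res = v.classify_cohort(traces, protocol)
        match = np.mean([res.loc[c, "label"] == truth.cell_labels[c] for c in res.index])
        assert match >= 0.95

    def test_fixture_labels_recovered_exactly(self, calcium_fixture):
        traces, protocol, truth = calcium_fixture
        res = v.classify_cohort(traces, protocol)
        for c in res.index:
            assert res.loc[c, "label"] == truth.cell_labels[c]

    def test_analyze_trace_profile_consistency(self, calcium_fixture):
        traces, protocol, _ = calcium_fixture
        prof = analyze_trace(traces[0], protocol)
        assert prof.n_positive == sum(prof.positives)
        assert prof.label == v.classify_cell(prof.positives)
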