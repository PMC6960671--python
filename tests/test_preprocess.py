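"""Filtering, decimation, onset marking, epoching, splits, windowing."""

import numpy as np
import pytest
from scipy import signal

import pepdetect as P
from pepdetect.preprocess import INSTABILITY, REST, TRANSITION

from conftest import SMALL_CAP


def _sine_recording(freq, fs=1000.0, seconds=20.0, amp=10.0):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (3, 1))
    return P.Recording(data=data, channel_labels=("FZ", "FCZ", "CZ"), sampling_rate=fs)


class TestBandpass:
    def test_out_of_band_50hz_is_suppressed(self):
        # long signal + wide margins: the 0.1 Hz edge has a seconds-long
        # start-up transient that must die out before steady state shows
        rec = _sine_recording(50.0, seconds=60.0)
        out = P.bandpass(rec, 0.1, 10.0)
        mid = np.s_[20000:-20000]
        assert np.std(out.data[0][mid]) < 0.01 * np.std(rec.data[0][mid])

    def test_in_band_5hz_passes(self):
        rec = _sine_recording(5.0)
        out = P.bandpass(rec, 0.1, 10.0)
        mid = np.s_[5000:-5000]
        ratio = np.std(out.data[0][mid]) / np.std(rec.data[0][mid])
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_zeros_stay_zeros(self):
        rec = P.Recording(np.zeros((2, 4000)), ("FZ", "FCZ"), 1000.0)
        assert not np.any(P.bandpass(rec).data)

    def test_invalid_band_rejected(self):
        rec = _sine_recording(5.0, seconds=2.0)
        with pytest.raises(P.ConfigurationError):
            P.bandpass(rec, 10.0, 0.1)
        with pytest.raises(P.ConfigurationError):
            P.bandpass(rec, 0.1, 600.0)

    def test_events_preserved(self, tiny_cap_config):
        rec, _, _ = P.generate_session(tiny_cap_config)
        out = P.bandpass(rec)
        assert [e.onset_sample for e in out.events] == [e.onset_sample for e in rec.events]


class TestDownsample:
    def test_length_and_rate_arithmetic(self):
        rec = P.Recording(np.zeros((2, 6000)), ("FZ", "FCZ"), 1000.0)
        out = P.downsample(rec, 50.0)
        assert out.sampling_rate == 50.0
        assert out.n_samples == 300

    def test_event_index_mapping(self):
        rec = P.Recording(
            np.zeros((1, 2000)), ("FZ",), 1000.0,
            events=[P.EventMarker(1000, "left")],
        )
        out = P.downsample(rec, 50.0)
        assert out.events[0].onset_sample == 50

    def test_constant_signal_preserved(self):
        rec = P.Recording(np.full((1, 1000), 3.5), ("FZ",), 1000.0)
        assert np.all(P.downsample(rec, 50.0).data == 3.5)

    def test_non_divisible_rate_rejected(self):
        rec = P.Recording(np.zeros((1, 1000)), ("FZ",), 1000.0)
        with pytest.raises(P.ConfigurationError):
            P.downsample(rec, 48.0)


class TestOnsetMarking:
    def test_constant_force_raises(self):
        ft = P.ForceTrace(np.full(500, 100.0), np.full(500, 100.0), 1000.0)
        with pytest.raises(P.OnsetNotFoundError):
            P.mark_onset_from_force(ft)

    def test_slope_change_located_exactly(self):
        """Piecewise-linear trace with one slope change at k -> onset k."""
        k = 700
        x = np.concatenate([np.full(k, 150.0), 150.0 - 0.5 * np.arange(800)])
        ft = P.ForceTrace(x, np.full(x.size, 150.0), 1000.0)
        assert P.mark_onset_from_force(ft, smooth_width=1, side="left") == k

    def test_matches_exhaustive_argmax_oracle(self):
        """Same answer as brute-force argmax of the smoothed 2nd difference."""
        rng = np.random.default_rng(5)
        width = 11
        for _ in range(50):
            x = 150.0 + np.cumsum(rng.normal(0, 0.5, size=1500))
            ft = P.ForceTrace(x, np.full(x.size, 150.0), 1000.0)
            got = P.mark_onset_from_force(ft, side="left", smooth_width=width)
            pad = width // 2
            sm = np.convolve(np.pad(x, pad, mode="edge"), np.ones(width) / width, "valid")
            oracle = 1 + int(np.argmax(np.abs(np.diff(sm, n=2))))
            assert got == oracle

    def test_within_20ms_of_ground_truth(self, default_config):
        """Marked onset stays within +-20 ms of the generator's onset."""
        fs = default_config.sampling_rate
        for seed in range(100):
            rng = np.random.default_rng(seed)
            onset = int(rng.integers(500, 1500))
            side = "left" if seed % 2 == 0 else "right"
            ft = P.make_force_trace(default_config, onset, onset + 4500, side)
            got = P.mark_onset_from_force(ft)
            assert abs(got - onset) <= 0.020 * fs

    def test_search_window_respected(self, default_config):
        ft = P.make_force_trace(default_config, 1000, 4000, "left")
        got = P.mark_onset_from_force(ft, search_window=(900, 1200))
        assert 900 <= got < 1200


class TestSegment:
    def test_epoch_count_and_length(self, small_epochs):
        assert len(small_epochs) == 20
        assert small_epochs.n_samples == 300  # (-2 .. 4) s at 50 Hz
        assert np.all(small_epochs.offset_ms == -2000.0)

    def test_edge_event_dropped_with_warning(self, caplog):
        rec = P.Recording(
            np.zeros((1, 500)), ("FZ",), 50.0,
            events=[P.EventMarker(10, "left"), P.EventMarker(250, "right")],
        )
        with caplog.at_level("WARNING"):
            es = P.segment(rec, 2.0, 4.0)
        assert len(es) == 1
        assert es.trial_id.tolist() == [1]
        assert "dropping event" in caplog.text

    def test_zero_events_gives_empty_epochset(self):
        rec = P.Recording(np.zeros((1, 500)), ("FZ",), 50.0)
        assert len(P.segment(rec)) == 0

    def test_decimation_commutes_with_epoching(self, tiny_cap_config):
        """Epoch-then-decimate equals decimate-then-epoch, sample for sample."""
        rec, _, _ = P.generate_session(tiny_cap_config)
        # align onsets to the decimation grid so both routes cut identically
        events = [
            P.EventMarker(e.onset_sample - e.onset_sample % 20, e.side)
            for e in rec.events
        ]
        rec = P.Recording(rec.data, rec.channel_labels, rec.sampling_rate, events)
        a = P.segment(P.downsample(rec, 50.0), 2.0, 4.0)
        b = P.segment(rec, 2.0, 4.0)
        np.testing.assert_array_equal(a.epochs, b.epochs[:, :, ::20])

    def test_filter_edge_effects_decay_into_epoch(self, tiny_cap_config):
        """Continuous vs epoch-wise filtering agree away from epoch edges.

        The discrepancy is pure filter edge effect: it must shrink as the
        margin grows and be small (<1 % of signal RMS) 1.5 s inside.
        """
        rec, _, _ = P.generate_session(tiny_cap_config)
        band = (5.0, 15.0)
        whole = P.segment(P.bandpass(rec, *band), 2.0, 4.0)
        raw = P.segment(rec, 2.0, 4.0)
        sos = signal.butter(4, band, btype="bandpass", fs=rec.sampling_rate, output="sos")
        piecewise = signal.sosfiltfilt(sos, raw.epochs, axis=2)
        diff = np.abs(piecewise - whole.epochs)
        errs = [diff[:, :, m:-m].max() for m in (250, 750, 1500)]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01 * np.std(whole.epochs)


class TestSplit:
    def test_default_plan_is_45_5_over_50(self):
        plan = P.make_split(np.arange(50), n_test=5, n_folds=10, seed=1)
        assert plan.n_folds == 10
        for train, test in plan:
            assert train.size == 45 and test.size == 5
            assert np.intersect1d(train, test).size == 0

    def test_zero_test_trials_rejected(self):
        with pytest.raises(P.ConfigurationError):
            P.make_split(np.arange(50), n_test=0)

    def test_plan_is_deterministic(self):
        a = P.make_split(np.arange(50), seed=9)
        b = P.make_split(np.arange(50), seed=9)
        for (tr_a, te_a), (tr_b, te_b) in zip(a, b):
            np.testing.assert_array_equal(te_a, te_b)
            np.testing.assert_array_equal(tr_a, tr_b)


class TestAugmentation:
    def test_instability_starts_follow_half_open_slide(self, small_epochs):
        one = small_epochs.for_trials([0])
        aug = P.augment_training_windows(one, seed=0)
        inst = aug.offset_ms[aug.labels == INSTABILITY]
        np.testing.assert_array_equal(inst, np.arange(-300.0, 100.0, 20.0))
        assert inst.size == 20

    def test_window_counts_scale_with_trials(self, small_epochs):
        aug = P.augment_training_windows(small_epochs, seed=0)
        assert (aug.labels == REST).sum() == 20 * 20
        assert (aug.labels == INSTABILITY).sum() == 20 * 20
        assert aug.n_samples == 25  # 500 ms at 50 Hz

    def test_rest_windows_end_before_onset(self, small_epochs):
        aug = P.augment_training_windows(small_epochs, seed=4)
        rest = aug.offset_ms[aug.labels == REST]
        assert rest.min() >= -2000.0
        assert rest.max() <= -500.0

    def test_large_step_gives_single_window(self, small_epochs):
        one = small_epochs.for_trials([1])
        aug = P.augment_training_windows(one, step=400.0, seed=0)
        inst = aug.offset_ms[aug.labels == INSTABILITY]
        np.testing.assert_array_equal(inst, [-300.0])

    def test_same_seed_same_rest_starts(self, small_epochs):
        a = P.augment_training_windows(small_epochs, seed=21)
        b = P.augment_training_windows(small_epochs, seed=21)
        np.testing.assert_array_equal(
            a.offset_ms[a.labels == REST], b.offset_ms[b.labels == REST]
        )

    def test_out_of_bounds_window_rejected(self, small_epochs):
        with pytest.raises(P.ConfigurationError):
            P.augment_training_windows(small_epochs, slide_stop=4000.0, seed=0)


class TestTestWindows:
    def test_default_grid_is_51_windows_per_trial(self, small_epochs):
        one = small_epochs.for_trials([0])
        win = P.extract_test_windows(one)
        assert len(win) == 51
        assert win.offset_ms[0] == -500.0 and win.offset_ms[-1] == 500.0

    def test_start_equals_stop_gives_one_window(self, small_epochs):
        one = small_epochs.for_trials([0])
        assert len(P.extract_test_windows(one, start=0.0, stop=0.0)) == 1

    def test_five_trials_give_255_windows(self, small_epochs):
        win = P.extract_test_windows(small_epochs.for_trials([0, 1, 2, 3, 4]))
        assert len(win) == 255

    def test_label_convention(self, small_epochs):
        win = P.extract_test_windows(small_epochs.for_trials([0]))
        for start, label in zip(win.offset_ms, win.labels):
            if start >= 0:
                assert label == INSTABILITY
            elif start <= -500.0:
                assert label == REST
            else:
                assert label == TRANSITION

    def test_no_trial_leakage_across_folds(self, small_epochs):
        plan = P.make_split(np.unique(small_epochs.trial_id), n_test=4, n_folds=8, seed=2)
        for train, test in plan:
            tr = P.extract_test_windows(small_epochs.for_trials(train))
            te = P.extract_test_windows(small_epochs.for_trials(test))
            assert np.intersect1d(tr.trial_id, te.trial_id).size == 0
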