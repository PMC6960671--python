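"""xDAWN spatial filtering: oracles, recovery, normalization, invariances."""

import numpy as np
import pytest
from scipy import linalg

import pepdetect as P
from pepdetect.xdawn import rayleigh_quotient


def _planted_recording(gain, course, onsets, n_samples, noise_sd=0.0, seed=0):
    """Continuous signal = known spatial gain x known time course + noise."""
    rng = np.random.default_rng(seed)
    data = noise_sd * rng.standard_normal((gain.size, n_samples))
    for onset in onsets:
        data[:, onset : onset + course.size] += np.outer(gain, course)
    labels = tuple(f"E{i}" for i in range(gain.size))
    return P.Recording(data=data, channel_labels=labels, sampling_rate=50.0)


def _covariances(recording, onsets, window):
    """Evoked/total covariance pair, rebuilt from their definitions."""
    x = recording.data.T
    n = x.shape[0]
    d = np.zeros((n, window))
    for onset in onsets:
        d[onset + np.arange(window), np.arange(window)] += 1.0
    a_hat, *_ = np.linalg.lstsq(d, x, rcond=None)
    s_hat = d @ a_hat
    return (s_hat.T @ s_hat) / n, (x.T @ x) / n


class TestFit:
    def test_recovers_planted_source_direction(self):
        """Filtered epochs reproduce the planted time course up to scale."""
        gain = np.array([1.0, 0.6, 0.3, -0.2, 0.1])
        course = np.sin(np.linspace(0, np.pi, 25)) * np.hanning(25)
        onsets = np.arange(10) * 100 + 30
        rec = _planted_recording(gain, course, onsets, 1200, noise_sd=0.0)
        model = P.fit_xdawn(rec, onsets, window=25)
        filtered = model.filters[:, 0] @ rec.data[:, onsets[0] : onsets[0] + 25]
        c = np.dot(filtered, course) / (
            np.linalg.norm(filtered) * np.linalg.norm(course)
        )
        assert abs(c) > 0.999

    def test_degenerate_onsets_rejected(self):
        rec = P.Recording(np.zeros((3, 100)), ("A", "B", "C"), 50.0)
        with pytest.raises(ValueError):
            P.fit_xdawn(rec, [], window=10)
        with pytest.raises(ValueError):
            P.fit_xdawn(rec, [5], window=10)

    def test_leading_score_matches_dense_generalized_eigensolver(self):
        """Component score equals scipy's dense solver to 1e-8 relative."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            gain = rng.standard_normal(4)
            course = rng.standard_normal(12)
            onsets = np.arange(8) * 40 + 5
            rec = _planted_recording(
                gain, course, onsets, 400, noise_sd=1.0, seed=rng.integers(1 << 30)
            )
            model = P.fit_xdawn(rec, onsets, window=12, n_components=4)
            sig_s, sig_x = _covariances(rec, onsets, 12)
            dense = np.sort(linalg.eigh(sig_s, sig_x, eigvals_only=True))[::-1]
            np.testing.assert_allclose(model.component_scores[0], dense[0], rtol=1e-8)

    def test_random_scan_never_beats_the_solver(self):
        """1e5 random unit vectors stay below the solver's Rayleigh quotient."""
        gain = np.array([1.0, -0.5, 0.25, 0.8])
        course = np.cos(np.linspace(0, 2 * np.pi, 10))
        onsets = np.arange(12) * 30 + 3
        rec = _planted_recording(gain, course, onsets, 400, noise_sd=0.8, seed=4)
        model = P.fit_xdawn(rec, onsets, window=10)
        sig_s, sig_x = _covariances(rec, onsets, 10)
        best = rayleigh_quotient(model.filters[:, 0], sig_s, sig_x)
        rng = np.random.default_rng(0)
        w = rng.standard_normal((100_000, 4))
        scan = np.einsum("ij,jk,ik->i", w, sig_s, w) / np.einsum(
            "ij,jk,ik->i", w, sig_x, w
        )
        assert scan.max() <= best * (1 + 1e-9)
        assert scan.max() > 0.9 * best  # the scan does approach the optimum

    def test_filters_signed_for_negative_extremum(self, small_epochs):
        from pepdetect.evaluate import _epochs_as_continuous

        continuous, onsets = _epochs_as_continuous(small_epochs)
        model = P.fit_xdawn(continuous, onsets, window=25)
        course = model.filters[:, 0] @ model.evoked_estimate
        assert abs(course.min()) >= abs(course.max())

    def test_scale_invariance(self):
        gain = np.array([1.0, 0.4, -0.3])
        course = np.sin(np.linspace(0, np.pi, 8))
        onsets = np.arange(10) * 20 + 2
        rec = _planted_recording(gain, course, onsets, 250, noise_sd=0.5, seed=9)
        big = P.Recording(rec.data * 1e3, rec.channel_labels, rec.sampling_rate)
        m1 = P.fit_xdawn(rec, onsets, window=8)
        m2 = P.fit_xdawn(big, onsets, window=8)
        np.testing.assert_allclose(m1.filters, m2.filters, atol=1e-10)


class TestApply:
    def test_single_channel_filter_picks_that_channel(self, small_epochs):
        fcz = 18  # FCZ row in the default 60-channel cap
        filters = np.zeros((small_epochs.n_channels, 1))
        filters[fcz, 0] = 1.0
        model = P.SpatialFilterModel(
            filters=filters,
            evoked_estimate=np.zeros((small_epochs.n_channels, 25)),
            component_scores=np.array([1.0]),
            window=25,
        )
        win = P.extract_test_windows(small_epochs.for_trials([0]), start=0.0, stop=0.0)
        feats = P.apply_xdawn(model, win)
        np.testing.assert_array_equal(feats[0], win.epochs[0, fcz])

    def test_zero_epoch_maps_to_zero_features(self):
        model = P.SpatialFilterModel(
            filters=np.ones((3, 1)),
            evoked_estimate=np.zeros((3, 5)),
            component_scores=np.array([1.0]),
            window=5,
        )
        es = P.EpochSet(np.zeros((2, 3, 5)), [0, 1], [0.0, 0.0], 50.0)
        assert not np.any(P.apply_xdawn(model, es))

    def test_feature_length_is_components_times_samples(self, small_epochs):
        from pepdetect.evaluate import _epochs_as_continuous

        continuous, onsets = _epochs_as_continuous(small_epochs)
        model = P.fit_xdawn(continuous, onsets, window=25)
        win = P.extract_test_windows(small_epochs.for_trials([0, 1]))
        assert P.apply_xdawn(model, win).shape == (102, 25)

    def test_channel_mismatch_rejected(self):
        model = P.SpatialFilterModel(
            filters=np.ones((4, 1)),
            evoked_estimate=np.zeros((4, 5)),
            component_scores=np.array([1.0]),
            window=5,
        )
        es = P.EpochSet(np.zeros((1, 3, 5)), [0], [0.0], 50.0)
        with pytest.raises(ValueError):
            P.apply_xdawn(model, es)


class TestNormalizer:
    def _model(self, d=4):
        return P.SpatialFilterModel(
            filters=np.ones((2, 1)),
            evoked_estimate=np.zeros((2, d)),
            component_scores=np.array([1.0]),
            window=d,
        )

    def test_standard_normal_features_map_near_identity(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((5000, 3))
        model = P.fit_normalizer(self._model(), feats)
        assert np.allclose(model.norm_mean, 0.0, atol=0.05)
        assert np.allclose(model.norm_sd, 1.0, atol=0.05)

    def test_constant_column_falls_back_to_unit_sd(self):
        feats = np.column_stack([np.full(10, 7.0), np.arange(10.0)])
        model = P.fit_normalizer(self._model(), feats)
        assert model.norm_sd[0] == 1.0
        out = P.apply_normalizer(model, feats)
        assert np.all(out[:, 0] == 0.0)

    def test_train_parameters_applied_to_test(self):
        train = np.array([[5.0 - 2.0], [5.0 + 2.0]])  # mean 5, sd 2
        model = P.fit_normalizer(self._model(1), train)
        assert P.apply_normalizer(model, np.array([[9.0]]))[0, 0] == pytest.approx(2.0)

    def test_normalized_features_invariant_to_input_scale(self):
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((50, 4)) * 3 + 1
        m1 = P.fit_normalizer(self._model(), feats)
        m2 = P.fit_normalizer(self._model(), feats * 1e4)
        np.testing.assert_allclose(
            P.apply_normalizer(m1, feats),
            P.apply_normalizer(m2, feats * 1e4),
            rtol=1e-10, atol=1e-10,
        )


#: mid-size 10-10 cap: enough channels for a noise null-space, cheap to simulate
CAP20 = (
    "FP1", "FPZ", "FP2", "F7", "F3", "FZ", "F4", "F8", "FC5", "FC1", "FCZ",
    "FC2", "FC6", "T7", "C3", "CZ", "C4", "T8", "PZ", "OZ",
)


class TestSnrGain:
    def test_filtered_average_beats_best_single_channel(self):
        """Filtered-average SNR >= best channel SNR across 20 seeded sessions.

        Holds by Rayleigh optimality once the covariances are estimated from
        enough trials; the session size here keeps the estimates well-posed.
        """
        pc = P.PipelineConfig()
        for seed in range(20):
            cfg = P.SimulationConfig(
                channel_labels=CAP20, n_trials=20,
                rest_duration_range=(5.0, 6.0), seed=100 + seed,
            )
            rec, _, _ = P.generate_session(cfg)
            _, epochs = P.preprocess_session(rec, pc.preprocessing)
            from pepdetect.evaluate import _epochs_as_continuous

            continuous, onsets = _epochs_as_continuous(epochs)
            model = P.fit_xdawn(continuous, onsets, window=25)

            onset_idx = 100  # 2 s pre-epoch at 50 Hz
            avg = epochs.epochs[:, :, onset_idx : onset_idx + 25].mean(axis=0)
            # the reference evoked is the noise-free twin session, run
            # through the identical conditioning chain
            rec0, _, _ = P.generate_session(cfg.with_(noise_rms=0.0))
            _, epochs0 = P.preprocess_session(rec0, pc.preprocessing)
            template = epochs0.epochs[:, :, onset_idx : onset_idx + 25].mean(axis=0)

            def snr(est, ref):
                return np.sum(ref**2) / np.sum((est - ref) ** 2)

            per_channel = [snr(avg[c], template[c]) for c in range(len(CAP20))]
            w = model.filters[:, 0]
            assert snr(w @ avg, w @ template) >= max(per_channel)
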