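"""Spectral-estimation and pre-processing tests."""

import numpy as np
import pytest

from cohnet import signal as sig


def _recording(data, fs=1000.0, kinds=None):
    data = np.atleast_2d(data)
    kinds = kinds or ["eeg"] * data.shape[0]
    return sig.RawRecording(
        data, fs, [f"CH{i}" for i in range(data.shape[0])],
        np.asarray(kinds, dtype=object),
    )


def _epochs(data, fs=1000.0, kinds=None):
    data = np.asarray(data)
    kinds = kinds or ["eeg"] * data.shape[0]
    return sig.EpochedRecording(
        data, fs, [f"CH{i}" for i in range(data.shape[0])],
        np.asarray(kinds, dtype=object),
    )


class TestPreprocess:
    def test_clean_recording_keeps_all_epochs(self):
        """A 250 s artifact-free recording yields M = 250 one-second epochs,
        so the sample count obeys N = L * M."""
        rng = np.random.default_rng(0)
        raw = _recording(rng.uniform(-1, 1, (3, 250_000)))   # bounded amplitudes
        ep = sig.preprocess(raw, reject_z=None)
        assert ep.n_epochs == 250
        assert ep.data.shape[2] * ep.n_epochs == 250_000

    def test_rectified_emg_nonnegative_before_demeaning(self):
        rng = np.random.default_rng(1)
        raw = _recording(rng.standard_normal((1, 20_000)), kinds=["emg"])
        filt = sig.filter_raw(raw)
        # rectification happens after filtering; the output is demeaned, so
        # adding the mean back recovers the nonnegative rectified trace
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, (30, 200), btype="bandpass", fs=1000.0, output="sos")
        rect = np.abs(sosfiltfilt(sos, raw.data[0]))
        np.testing.assert_allclose(filt.data[0], rect - rect.mean(), atol=1e-9)
        assert np.all(rect >= 0)

    def test_low_frequency_attenuated_in_emg_band(self):
        """A 1 Hz sine injected into the EMG channel is suppressed by at
        least 40 dB by the 30-200 Hz band-pass."""
        t = np.arange(60_000) / 1000.0
        tone = np.sin(2 * np.pi * 1.0 * t)
        raw = _recording(tone[None, :], kinds=["emg"])
        filt = sig.filter_raw(raw, rectify_emg=False)
        atten = 20 * np.log10(np.std(filt.data[0][5000:-5000]) / np.std(tone))
        assert atten < -40

    def test_high_amplitude_epochs_dropped(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(-1, 1, (2, 40_000))
        data[0, 25_500:25_600] += 50.0      # artifact in epoch 25
        ep = sig.epoch_and_reject(_recording(data))
        assert 25 not in ep.epoch_indices
        assert ep.n_epochs == 39

    def test_band_edges_validated(self):
        raw = _recording(np.zeros((1, 20_000)))
        with pytest.raises(ValueError, match="band edges"):
            sig.filter_raw(raw, bands={"eeg": (0.0, 200.0)})


class TestMultitaperCSD:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 50, 1000))
        csd = sig.multitaper_csd(_epochs(np.concatenate([x, x])), (2, 4))
        np.testing.assert_allclose(sig.coherence(csd, 0, 1), 1.0, atol=1e-10)

    def test_sign_flip_leaves_coherence(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 50, 1000))
        csd = sig.multitaper_csd(_epochs(np.concatenate([x, -x])), (2, 4))
        np.testing.assert_allclose(sig.coherence(csd, 0, 1), 1.0, atol=1e-10)

    def test_hermitian_psd(self):
        rng = np.random.default_rng(5)
        csd = sig.multitaper_csd(_epochs(rng.standard_normal((4, 30, 1000))), (1, 6))
        np.testing.assert_allclose(csd.S, np.conj(np.swapaxes(csd.S, 1, 2)), atol=1e-12)
        diag = np.diagonal(csd.S, axis1=1, axis2=2)
        assert np.all(diag.real > 0)
        np.testing.assert_allclose(diag.imag, 0.0, atol=1e-15)

    def test_common_signal_mixture_matches_closed_form(self):
        """x = s + n1, y = s + n2 with equal variances: the magnitude-squared
        coherence converges to (var_s / (var_s + var_n))^2 = 0.25."""
        rng = np.random.default_rng(6)
        s = rng.standard_normal((250, 1000))
        x = s + rng.standard_normal(s.shape)
        y = s + rng.standard_normal(s.shape)
        csd = sig.multitaper_csd(_epochs(np.stack([x, y])), (2, 4), K=7)
        coh = sig.coherence(csd, 0, 1).mean()
        assert abs(coh - 0.25) < 0.05

    def test_independent_pair_at_bias_level(self):
        vals = []
        for seed in (7, 70, 700, 7000):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((2, 250, 1000))
            csd = sig.multitaper_csd(_epochs(x), (2, 4), K=7)
            vals.append(sig.coherence(csd, 0, 1).mean())
        bias = 1.0 / (7 * 250)
        assert 0.5 * bias < np.mean(vals) < 1.5 * bias

    def test_coherence_invariant_to_channel_rescaling(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal((60, 1000))
        x = s + 0.5 * rng.standard_normal(s.shape)
        c1 = sig.multitaper_csd(_epochs(np.stack([x, s])), (2, 4))
        c2 = sig.multitaper_csd(_epochs(np.stack([1e6 * x, 1e-3 * s])), (2, 4))
        np.testing.assert_allclose(
            sig.coherence(c1, 0, 1), sig.coherence(c2, 0, 1), rtol=1e-10
        )

    def test_zero_autospectrum_reported(self):
        x = np.zeros((2, 30, 1000))
        x[0] = np.random.default_rng(9).standard_normal((30, 1000))
        csd = sig.multitaper_csd(_epochs(x), (2, 4))
        with pytest.raises(ValueError, match="auto-spectrum"):
            sig.coherence(csd, 0, 1)


class TestHandComputableCoherence:
    def test_two_bin_toy_csd(self):
        """C_xx = 4, C_yy = 1, C_xy = 1 + 1i gives |1+i|^2 / 4 = 0.5."""
        S = np.array(
            [[[4.0, 1 + 1j], [1 - 1j, 1.0]], [[4.0, 1 + 1j], [1 - 1j, 1.0]]]
        )
        csd = sig.CrossSpectrum(
            freqs=np.array([2.0, 3.0]), S=S, K=1, M=1, names=["x", "y"]
        )
        np.testing.assert_allclose(sig.coherence(csd, "x", "y"), 0.5)


class TestPooledCoherence:
    def test_single_group_identity(self):
        rng = np.random.default_rng(10)
        s = rng.standard_normal((80, 1000))
        x = s + rng.standard_normal(s.shape)
        csd = sig.multitaper_csd(_epochs(np.stack([x, s])), (2, 4))
        pooled = sig.pooled_coherence([csd], [(0, 1)])
        np.testing.assert_allclose(pooled, sig.coherence(csd, 0, 1), rtol=1e-12)

    def test_two_identical_groups_idempotent(self):
        rng = np.random.default_rng(11)
        s = rng.standard_normal((80, 1000))
        x = s + rng.standard_normal(s.shape)
        csd = sig.multitaper_csd(_epochs(np.stack([x, s])), (2, 4))
        pooled = sig.pooled_coherence([csd, csd], [(0, 1), (0, 1)], weights=[3, 3])
        np.testing.assert_allclose(pooled, sig.coherence(csd, 0, 1), rtol=1e-12)

    def test_opposite_phase_groups_cancel(self):
        cross = np.array([[2 + 0j], [-2 + 0j]])
        auto = np.array([[4.0], [4.0]])
        pooled = sig.pool_coherence(cross, auto, auto, weights=[1, 1])
        np.testing.assert_allclose(pooled, 0.0, atol=1e-15)

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError, match="positive"):
            sig.pool_coherence(
                np.ones((2, 3)), np.ones((2, 3)), np.ones((2, 3)), weights=[1, 0]
            )


class TestTimeFrequencyCoherence:
    @pytest.fixture(scope="class")
    def coupled_pair(self):
        rng = np.random.default_rng(12)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, (2, 4), btype="bandpass", fs=1000.0, output="sos")
        s = sosfiltfilt(sos, rng.standard_normal(60_000))
        s /= s.std()
        x = s + 0.5 * rng.standard_normal(s.size)
        y = s + 0.5 * rng.standard_normal(s.size)
        return x, y

    def test_frequency_spacing_is_one_hertz(self, coupled_pair):
        x, y = coupled_pair
        tfc = sig.tf_coherence(x, y, 1000.0)
        assert np.allclose(np.diff(tfc.freqs), 1.0)

    def test_hop_is_fifty_milliseconds(self, coupled_pair):
        x, y = coupled_pair
        tfc = sig.tf_coherence(x, y, 1000.0)
        assert np.allclose(np.diff(tfc.times), 0.05)

    def test_stationary_pair_has_stable_course(self, coupled_pair):
        x, y = coupled_pair
        tfc = sig.tf_coherence(x, y, 1000.0)
        course = tfc.band_course((2, 4))
        assert course.std() / course.mean() < 0.2

    def test_step_validation(self, coupled_pair):
        x, y = coupled_pair
        with pytest.raises(ValueError, match="step"):
            sig.tf_coherence(x, y, 1000.0, step=2.0)


class TestSegmentSelection:
    def _tfc(self, values, step=1.0):
        values = np.asarray(values, float)[:, None]
        times = np.arange(values.shape[0]) * step + 0.5
        return sig.TimeFrequencyCoherence(
            times=times, freqs=np.array([3.0]), values=values, window=1.0, step=step
        )

    def test_hand_computed_threshold(self):
        """Course [0.1, 0.2, 0.3, 0.8]: mean+std = 0.661, so only the last
        epoch is selected."""
        sel = sig.select_high_coherence_segments(self._tfc([0.1, 0.2, 0.3, 0.8]))
        np.testing.assert_array_equal(sel, [3])

    def test_constant_course_selects_nothing(self):
        with pytest.warns(UserWarning, match="no segments"):
            sel = sig.select_high_coherence_segments(self._tfc([0.4] * 20))
        assert sel.size == 0

    def test_gaussian_course_selects_upper_tail(self):
        rng = np.random.default_rng(13)
        vals = np.clip(0.5 + 0.05 * rng.standard_normal(4000), 0, 1)
        sel = sig.select_high_coherence_segments(self._tfc(vals))
        frac = sel.size / 4000
        assert abs(frac - 0.159) < 0.05


class TestCoherenceProperties:
    """Property-based checks of the coherence estimator's range and
    invariances on arbitrary epoched data."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _random_epochs(seed, n_ch, n_ep):
        rng = np.random.default_rng(seed)
        return _epochs(rng.standard_normal((n_ch, n_ep, 200)))

    @given(seed=st.integers(0, 2**16), n_ch=st.integers(2, 4), n_ep=st.integers(2, 6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_coherence_bounded_and_symmetric(self, seed, n_ch, n_ep):
        ep = self._random_epochs(seed, n_ch, n_ep)
        csd = sig.multitaper_csd(ep, (5, 20), K=3, NW=2)
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                cij = sig.coherence(csd, i, j)
                np.testing.assert_allclose(cij, sig.coherence(csd, j, i), rtol=1e-12)
                assert np.all(cij >= 0) and np.all(cij <= 1 + 1e-12)

    @given(seed=st.integers(0, 2**16), scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pooled_coherence_weight_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        # valid per-group spectra: averages of actual sample products, so the
        # Cauchy-Schwarz bound holds and pooled values stay in [0, 1]
        x = rng.standard_normal((3, 4, 8)) + 1j * rng.standard_normal((3, 4, 8))
        y = rng.standard_normal((3, 4, 8)) + 1j * rng.standard_normal((3, 4, 8))
        cross = (x * y.conj()).mean(-1)
        ax = (np.abs(x) ** 2).mean(-1)
        ay = (np.abs(y) ** 2).mean(-1)
        w = rng.uniform(0.1, 5.0, 3)
        a = sig.pool_coherence(cross, ax, ay, w)
        b = sig.pool_coherence(cross, ax, ay, scale * w)
        np.testing.assert_allclose(a, b, rtol=1e-10)
        assert np.all(a >= 0) and np.all(a <= 1 + 1e-9)
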