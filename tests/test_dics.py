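"""DICS beamformer tests: filters, maps, surrogates, search, reconstruction."""

import numpy as np
import pytest

from cohnet import dics
from cohnet import forward as fwd
from cohnet import signal as sig
from cohnet.pipeline import _noise_amplitudes, _whitened_epochs


@pytest.fixture(scope="module")
def dipole_analysis(head, sensors_meg, single_dipole_recording):
    """Whitened epochs, restricted 5-mm grid, and tapered spectra for the
    single-dipole MEG scenario."""
    task = single_dipole_recording["task"]
    rest = single_dipole_recording["rest"]
    epochs = sig.preprocess(task)
    rest_ep = sig.preprocess(rest, reject_z=None)
    names = [n for n, k in zip(task.names, task.kinds) if k != "emg"]
    amps = _noise_amplitudes(rest_ep, names, (2, 4))
    bbox = np.array([[-0.07, -0.01], [-0.04, 0.02], [0.0, 0.06]])
    grid = fwd.make_voxel_grid(head, spacing=0.005, bbox=bbox)
    lf = fwd.whiten_and_combine(
        fwd.build_leadfield(grid, head, sensors_meg, kinds=("mag", "grad")), amps
    )
    ep_w = _whitened_epochs(epochs, amps, "EMG")
    ts = sig.tapered_fft(ep_w, band=(2, 4), K=7)
    return {"grid": grid, "lf": lf, "ts": ts, "ep": ep_w,
            "true_loc": single_dipole_recording["net"].locations[0],
            "true_q": single_dipole_recording["net"].moments[0]}


class TestFilters:
    def test_unit_gain_constraint(self, dipole_analysis):
        ts, lf = dipole_analysis["ts"], dipole_analysis["lf"]
        Xb, Xr, _ = dics.split_reference(ts, "EMG")
        C_bb, _, _ = dics._csd_terms(Xb, Xr)
        filt = dics.dics_filters(C_bb.mean(0), lf, alpha=0.05)
        filt.check_unit_gain(lf, atol=1e-8)

    def test_full_rank_case_matches_pseudoinverse_oracle(self, head, sensors_small):
        """With alpha = 0 and a well-conditioned CSD the filter must equal the
        brute-force expression (L^T C^-1 L)^-1 L^T C^-1 computed voxel by
        voxel with dense inverses."""
        rng = np.random.default_rng(31)
        grid = fwd.make_voxel_grid(
            head, spacing=0.01,
            bbox=np.array([[-0.03, 0.03], [-0.03, 0.03], [0.02, 0.06]]),
        )
        raw = fwd.build_leadfield(grid, head, sensors_small)  # EEG+MEG: rank 3
        row_scale = np.linalg.norm(raw.gain.reshape(raw.n_sensors, -1), axis=1)
        lf = fwd.whiten_and_combine(raw, row_scale)           # balanced rows
        S = lf.n_sensors
        A = rng.standard_normal((S, 3 * S))
        C = A @ A.T / (3 * S)
        filt = dics.dics_filters(C, lf, alpha=0.0)
        Ci = np.linalg.inv(C)
        for v in (0, len(grid) // 2, len(grid) - 1):
            L = lf.gain[:, v, :]
            W_ref = np.linalg.solve(L.T @ Ci @ L, L.T @ Ci)
            np.testing.assert_allclose(
                filt.W[v], W_ref, atol=1e-10 * np.abs(W_ref).max()
            )

    def test_rank_deficient_csd_raises_without_regularization(self, head, sensors_small):
        grid = fwd.make_voxel_grid(
            head, spacing=0.02,
            bbox=np.array([[-0.02, 0.02], [-0.02, 0.02], [0.02, 0.05]]),
        )
        lf = fwd.build_leadfield(grid, head, sensors_small)
        rank1 = np.outer(np.ones(lf.n_sensors), np.ones(lf.n_sensors))
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            dics.dics_filters(rank1, lf, alpha=0.0)


class TestCoherenceMap:
    def test_localizes_single_dipole_within_one_grid_step(self, dipole_analysis):
        cmap = dics.coherence_map(dipole_analysis["ts"], dipole_analysis["lf"], "EMG")
        err = np.linalg.norm(
            dipole_analysis["grid"].centers[cmap.peak] - dipole_analysis["true_loc"]
        )
        assert err <= 0.005 + 1e-12

    def test_estimated_orientation_close_to_truth(self, dipole_analysis):
        cmap = dics.coherence_map(dipole_analysis["ts"], dipole_analysis["lf"], "EMG")
        u = cmap.orientations[cmap.peak]
        cosang = abs(u @ dipole_analysis["true_q"])
        assert np.degrees(np.arccos(np.clip(cosang, 0, 1))) < 15.0

    def test_map_invariant_to_global_data_rescaling(self, dipole_analysis):
        ts = dipole_analysis["ts"]
        scaled = sig.TaperedSpectra(
            coef=1e3 * ts.coef, freqs=ts.freqs, names=ts.names,
            kinds=ts.kinds, fs=ts.fs, K=ts.K,
        )
        a = dics.coherence_map(ts, dipole_analysis["lf"], "EMG").values
        b = dics.coherence_map(scaled, dipole_analysis["lf"], "EMG").values
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_reconstructed_signal_self_coherence_is_one(self, dipole_analysis):
        """The coherence of an identified area's own signal with itself is 1
        by construction."""
        cmap = dics.coherence_map(dipole_analysis["ts"], dipole_analysis["lf"], "EMG")
        src = dics.IdentifiedSource(
            name="S1", location=dipole_analysis["grid"].centers[cmap.peak],
            peak_index=cmap.peak, member_indices=np.array([cmap.peak]),
            orientation=cmap.orientations[cmap.peak],
            orientation_class="tangential", orientation_angle=0.0,
            peak_coherence=float(cmap.values[cmap.peak]),
        )
        ss = dics.reconstruct_source_signals(
            [src], dipole_analysis["ep"], dipole_analysis["lf"]
        )
        ep = sig.EpochedRecording(
            np.stack([ss.signals[0], ss.signals[0]]), 1000.0, ["a", "b"],
            np.asarray(["eeg", "eeg"], dtype=object),
        )
        coh = sig.coherence(sig.multitaper_csd(ep, (2, 4)), 0, 1)
        np.testing.assert_allclose(coh, 1.0, atol=1e-10)


class TestSurrogates:
    def test_percentile_monotonicity_and_determinism(self, dipole_analysis):
        ts, lf = dipole_analysis["ts"], dipole_analysis["lf"]
        t99 = dics.surrogate_threshold(ts, lf, "EMG", n_perm=50, percentile=99, seed=2)
        t100 = dics.surrogate_threshold(ts, lf, "EMG", n_perm=50, percentile=100, seed=2)
        again = dics.surrogate_threshold(ts, lf, "EMG", n_perm=50, percentile=99, seed=2)
        assert t100 >= t99
        assert again == t99

    def test_coupled_map_exceeds_threshold(self, dipole_analysis):
        ts, lf = dipole_analysis["ts"], dipole_analysis["lf"]
        cmap = dics.coherence_map(ts, lf, "EMG")
        thr = dics.surrogate_threshold(ts, lf, "EMG", n_perm=100, seed=3)
        assert cmap.values.max() > thr

    def test_independent_reference_stays_below_threshold(self, dipole_analysis):
        """Replacing the EMG with independent noise: the map maximum exceeds
        the 99th-percentile surrogate threshold only rarely (calibration is
        checked at ~1 sigma of the binomial around the nominal 1%)."""
        ts = dipole_analysis["ts"]
        lf = dipole_analysis["lf"]
        rng = np.random.default_rng(4)
        hits = 0
        n_runs = 20
        for _ in range(n_runs):
            coef = ts.coef.copy()
            ref = ts.channel_index("EMG")
            shape = coef[ref].shape
            coef[ref] = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
            ts2 = sig.TaperedSpectra(
                coef=coef, freqs=ts.freqs, names=ts.names, kinds=ts.kinds,
                fs=ts.fs, K=ts.K,
            )
            cmap = dics.coherence_map(ts2, lf, "EMG")
            thr = dics.surrogate_threshold(
                ts2, lf, "EMG", n_perm=100, seed=int(rng.integers(2**31))
            )
            hits += cmap.values.max() > thr
        assert hits <= 2

    def test_too_few_permutations_rejected(self, dipole_analysis):
        with pytest.raises(ValueError, match="permutations"):
            dics.surrogate_threshold(
                dipole_analysis["ts"], dipole_analysis["lf"], "EMG", n_perm=5
            )


class TestSequentialSearch:
    def test_finds_and_nulls_single_source(self, head, dipole_analysis):
        ts, lf = dipole_analysis["ts"], dipole_analysis["lf"]
        sources, maps = dics.sequential_source_search(
            ts, lf, head, "EMG", max_sources=4, n_perm=50, seed=5
        )
        assert len(sources) >= 1
        err = np.linalg.norm(sources[0].location - dipole_analysis["true_loc"])
        assert err <= 0.005 + 1e-12
        # after nulling, the map value at the found voxel falls below threshold
        later = maps[1]
        assert later.values[sources[0].peak_index] < later.threshold

    def test_no_coupling_returns_empty(self, head, dipole_analysis):
        ts = dipole_analysis["ts"]
        rng = np.random.default_rng(6)
        coef = ts.coef.copy()
        ref = ts.channel_index("EMG")
        shape = coef[ref].shape
        coef[ref] = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        ts2 = sig.TaperedSpectra(
            coef=coef, freqs=ts.freqs, names=ts.names, kinds=ts.kinds,
            fs=ts.fs, K=ts.K,
        )
        sources, _ = dics.sequential_source_search(
            ts2, dipole_analysis["lf"], head, "EMG", max_sources=4, n_perm=50, seed=7
        )
        assert sources == []

    def test_reconstruction_tracks_true_source(self, head, dipole_analysis,
                                               single_dipole_recording):
        ts, lf = dipole_analysis["ts"], dipole_analysis["lf"]
        sources, _ = dics.sequential_source_search(
            ts, lf, head, "EMG", max_sources=2, n_perm=50, seed=8
        )
        ss = dics.reconstruct_source_signals(sources[:1], dipole_analysis["ep"], lf)
        true = single_dipole_recording["ens"].sources[0]
        kept = dipole_analysis["ep"].epoch_indices
        true_ep = true.reshape(-1, 1000)[kept]
        ep = sig.EpochedRecording(
            np.stack([ss.signals[0], true_ep]), 1000.0, ["rec", "true"],
            np.asarray(["eeg", "eeg"], dtype=object),
        )
        coh = sig.coherence(sig.multitaper_csd(ep, (2, 4)), 0, 1).mean()
        assert coh > 0.8

    def test_single_voxel_pooling_identity(self, dipole_analysis):
        ts, lf, ep = dipole_analysis["ts"], dipole_analysis["lf"], dipole_analysis["ep"]
        cmap = dics.coherence_map(ts, lf, "EMG")
        src = dics.IdentifiedSource(
            name="S1", location=dipole_analysis["grid"].centers[cmap.peak],
            peak_index=cmap.peak, member_indices=np.array([cmap.peak]),
            orientation=cmap.orientations[cmap.peak],
            orientation_class="tangential", orientation_angle=0.0,
            peak_coherence=float(cmap.values[cmap.peak]),
        )
        ss = dics.reconstruct_source_signals([src], ep, lf)
        Xb, Xr, names = dics.split_reference(
            sig.tapered_fft(ep, band=(2, 4), K=7), "EMG"
        )
        C_bb, c_br, c_rr = dics._csd_terms(Xb, Xr)
        filt = dics.dics_filters(C_bb.mean(0), lf, alpha=0.05)
        _, ori = dics._voxel_coherence(filt.W, C_bb, c_br, c_rr)
        w = ori[cmap.peak] @ filt.W[cmap.peak]
        direct = np.einsum("s,set->et", w, ep.data[[ep.channel_index(n) for n in names]])
        np.testing.assert_allclose(np.abs(ss.signals[0]), np.abs(direct), rtol=1e-9)


class TestOrientationClassification:
    def test_tangential_reference_bins(self, head):
        assert dics.classify_angle(90.0) == "radial"
        assert dics.classify_angle(0.0) == "tangential"
        assert dics.classify_angle(60.0) == "tangential"   # boundary closed below
        assert dics.classify_angle(120.0) == "tangential"
        assert dics.classify_angle(61.0) == "radial"

    def test_radial_axis_convention(self, head):
        loc = np.array([0.0, 0.0, 0.05])
        cls, theta = dics.classify_orientation(
            np.array([0.0, 0.0, 1.0]), loc, head, convention="radial_axis"
        )
        assert cls == "radial" and theta < 1e-6
        cls, theta = dics.classify_orientation(
            np.array([1.0, 0.0, 0.0]), loc, head, convention="radial_axis"
        )
        assert cls == "tangential" and abs(theta - 90.0) < 1e-6

    def test_zero_moment_rejected(self, head):
        with pytest.raises(ValueError, match="zero"):
            dics.classify_orientation(np.zeros(3), np.array([0, 0, 0.05]), head)
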