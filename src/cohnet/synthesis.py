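"""Ground-truth generator: coupled narrow-band dipole sources, an EMG
reference, and sensor projections with controllable per-modality SNR.

Sources are lag-coupled band-limited (2-4 Hz) oscillations driven by
independent innovations, mimicking the rhythmic finger-tapping network: a
primary sensorimotor driver, secondary motor and parietal areas, and two
deep sources (thalamus, cerebellum).  The EMG is a 30-200 Hz carrier
amplitude-modulated by a burst envelope phase-locked to the driver, with
2-4 bursts per second; the modulation depth can vary across epochs so that
high-coherence segment selection has structure to find.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .forward import (
    LeadField,
    SensorArray,
    SphericalHeadModel,
    build_leadfield,
    build_sensor_fixture,
)
from .signal import RawRecording

#: finger-tapping reference locations in MNI space (mm)
REFERENCE_MNI = {
    "PSMC": (-56.0, -14.0, 41.0),
    "PMC": (-27.0, 46.0, 32.0),
    "SMA": (-14.0, -4.0, 44.0),
    "PPC": (-46.0, -71.0, 35.0),
    "TH": (-5.0, -16.0, 8.0),
    "CER": (13.0, -76.0, -51.0),
}

#: uniform scale mapping MNI mm into the spherical head frame (meters)
MNI_TO_HEAD_SCALE = 0.75
#: the fitted sphere's center sits below the MNI origin (mm, MNI frame)
MNI_SPHERE_CENTER = (0.0, 0.0, -25.0)


def mni_to_head(
    mni_mm,
    scale: float = MNI_TO_HEAD_SCALE,
    center_mm=MNI_SPHERE_CENTER,
) -> np.ndarray:
    """Map MNI coordinates (mm) into the spherical head frame (m).

    Coordinates are taken relative to the fitted-sphere center (which lies
    below the anterior commissure) and scaled uniformly so the whole atlas
    fits inside the spherical brain shell.
    """
    rel = np.asarray(mni_mm, float) - np.asarray(center_mm, float)
    return scale * rel / 1e3


@dataclass
class TrueNetwork:
    """Named dipoles plus a directed lag-coupling graph.

    Edges are (source_name, target_name, lag_samples, gain); the implied MVAR
    generator must be stable (companion spectral radius < 1).
    """

    names: list[str]
    locations: np.ndarray              # (n, 3) m, head frame
    moments: np.ndarray                # (n, 3) unit dipole orientations
    amplitudes: np.ndarray             # (n,) source strength multipliers
    edges: list[tuple[str, str, int, float]] = field(default_factory=list)
    band: tuple[float, float] = (2.0, 4.0)
    driver: str = "PSMC"

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, float))
        self.moments = np.atleast_2d(np.asarray(self.moments, float))
        self.amplitudes = np.asarray(self.amplitudes, float)
        for s, t, lag, gain in self.edges:
            if s == t:
                raise ValueError(f"self-edge {s}->{t} is not allowed")
            if lag < 1:
                raise ValueError("edge lags must be at least one sample")

    @property
    def n_sources(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _, _ in self.edges}

    def coupling_matrices(self) -> np.ndarray:
        """Lag-indexed coupling matrices G[l, i, j]: x_i(t) += G x_j(t-l)."""
        max_lag = max((lag for _, _, lag, _ in self.edges), default=1)
        G = np.zeros((max_lag, self.n_sources, self.n_sources))
        for s, t, lag, gain in self.edges:
            G[lag - 1, self.index(t), self.index(s)] += gain
        return G

    def spectral_radius(self) -> float:
        """Companion-matrix spectral radius of the pure-delay coupling system."""
        G = self.coupling_matrices()
        p, d = G.shape[0], self.n_sources
        comp = np.zeros((p * d, p * d))
        comp[:d] = G.transpose(1, 0, 2).reshape(d, p * d)
        comp[d:, : (p - 1) * d] = np.eye((p - 1) * d)
        return float(np.abs(np.linalg.eigvals(comp)).max())


def _tangential(u: np.ndarray) -> np.ndarray:
    t = np.cross([0.0, 0.0, 1.0], u)
    n = np.linalg.norm(t)
    if n < 1e-9:
        t, n = np.array([1.0, 0.0, 0.0]), 1.0
    return t / n


def default_network(
    amplitudes: dict[str, float] | None = None,
    radial_fraction: float = 0.5,
) -> TrueNetwork:
    """Six-source finger-tapping network at the reference coordinates.

    Orientations are predominantly tangential (with a configurable radial
    admixture so the EEG sees every source); amplitudes compensate depth
    attenuation for the two deep sources.  The directed graph mirrors the
    physiological pattern: the sensorimotor driver projects to premotor,
    supplementary-motor and parietal areas, premotor and parietal interact
    bidirectionally, and thalamus and cerebellum feed the driver.
    """
    names = list(REFERENCE_MNI)
    locations = np.stack([mni_to_head(REFERENCE_MNI[n]) for n in names])
    # per-source azimuth within the tangent plane: cortical folding makes
    # neighbouring areas' dipoles point in different directions, and parallel
    # moments would make their field patterns collinear (mutual cancellation)
    azimuths = np.deg2rad([0.0, 330.0, 260.0, 60.0, 30.0, 30.0])
    moments = []
    for loc, az in zip(locations, azimuths):
        r = loc / np.linalg.norm(loc)
        t1 = _tangential(r)
        t2 = np.cross(r, t1)
        q = np.cos(az) * t1 + np.sin(az) * t2 + radial_fraction * r
        moments.append(q / np.linalg.norm(q))
    amp = {"PSMC": 1.0, "PMC": 0.9, "SMA": 1.6, "PPC": 0.55, "TH": 6.5, "CER": 1.5}
    amp.update(amplitudes or {})
    # lags in samples at 1 kHz, multiples of 10 ms; gains into a target are
    # scaled against the source amplitude so that no single afferent dominates
    # (keeps inter-source coherence moderate, as the beamformer assumes)
    edges = [
        ("PSMC", "PMC", 20, 0.42),
        ("PSMC", "SMA", 50, 0.80),
        ("PSMC", "PPC", 20, 0.42),
        ("PMC", "PPC", 10, 0.30),
        ("PPC", "PMC", 20, 0.30),
        ("TH", "PSMC", 50, 0.13),
        ("CER", "PSMC", 40, 0.33),
    ]
    return TrueNetwork(
        names=names,
        locations=locations,
        moments=np.stack(moments),
        amplitudes=np.array([amp[n] for n in names]),
        edges=edges,
    )


@dataclass
class SourceEnsemble:
    """Simulated source time series plus the EMG reference."""

    sources: np.ndarray        # (n_sources, N) a.u.
    emg: np.ndarray            # (N,)
    fs: float
    network: TrueNetwork
    seed: int
    depth_profile: np.ndarray | None = None   # per-epoch EMG modulation depth

    @property
    def n_samples(self) -> int:
        return self.sources.shape[1]


def _band_noise(rng, shape, band, fs, order=4):
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def simulate_source_network(
    net: TrueNetwork,
    n_epochs: int = 250,
    seed: int = 0,
    fs: float = 1000.0,
    epoch_length: float = 1.0,
    background: float = 0.05,
) -> SourceEnsemble:
    """Simulate the coupled band-limited source network.

    Each source is driven by its own white innovation stream filtered to the
    oscillation band and scaled by the source amplitude; directed couplings
    are pure lagged gains realizing exactly the graph's edges (solved in the
    frequency domain; edge padding removes circular wrap-around).  A weak
    broadband background keeps the ensemble full rank.
    """
    if n_epochs < 10:
        raise ValueError("need at least 10 epochs")
    rho = net.spectral_radius()
    if rho >= 1.0:
        raise ValueError(
            f"unstable source network: companion spectral radius {rho:.3f} >= 1"
        )
    rng = np.random.default_rng(seed)
    N = int(round(n_epochs * epoch_length * fs))
    pad = int(4 * fs)
    d = net.n_sources
    u = _band_noise(rng, (d, N + 2 * pad), net.band, fs)
    u *= net.amplitudes[:, None]

    G = net.coupling_matrices()                    # (L, d, d)
    U = np.fft.rfft(u, axis=1)
    k = np.arange(U.shape[1])
    lags = np.arange(1, G.shape[0] + 1)
    # transfer (I - sum_l G_l z^-l)^-1 per rfft bin
    z = np.exp(-2j * np.pi * np.outer(k, lags) / (N + 2 * pad))   # (F, L)
    A = np.eye(d)[None] - np.einsum("fl,lij->fij", z, G)
    X = np.linalg.solve(A, U.T[:, :, None])[:, :, 0].T
    x = np.fft.irfft(X, n=N + 2 * pad, axis=1)[:, pad : pad + N]
    x = x + background * x.std(axis=1, keepdims=True) * rng.standard_normal((d, N))
    return SourceEnsemble(sources=x, emg=np.zeros(N), fs=fs, network=net, seed=seed)


def simulate_emg(
    driver: np.ndarray,
    burst_rate_hz: float = 3.0,
    modulation_depth=0.9,
    seed: int = 0,
    fs: float = 1000.0,
    burst_width: float = 0.1,
    carrier_band: tuple[float, float] = (30.0, 200.0),
) -> np.ndarray:
    """Surface-EMG surrogate: band-limited carrier noise with driver-locked bursts.

    Bursts (Hann-shaped, ``burst_width`` s) are placed at the positive peaks
    of the band-limited driver, so the burst rate follows the driver's 2-4 Hz
    rhythm; when no driver is given, a regular train at ``burst_rate_hz`` is
    used.  ``modulation_depth`` in [0, 1] may be a scalar or a per-sample
    profile; after rectification the envelope's rhythm shows up as a spectral
    peak at the burst rate.  Returned unrectified.
    """
    if not (0 < burst_rate_hz <= 10):
        raise ValueError("burst rate must lie in (0, 10] Hz")
    depth = np.asarray(modulation_depth, float)
    if np.any(depth < 0) or np.any(depth > 1):
        raise ValueError("modulation depth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if driver is not None:
        # one burst per driver cycle, amplitude linear in the driver: the
        # envelope is the half-wave rectified (normalized) driver
        driver = np.asarray(driver, float)
        N = driver.size
        train = np.clip(driver / (np.sqrt(2.0) * driver.std()), 0.0, None)
    else:
        N = int(10 * fs)
        period = int(round(fs / burst_rate_hz))
        peaks = np.arange(period // 2, N, period)
        train = np.zeros(N)
        w = int(round(burst_width * fs))
        burst = sps.windows.hann(2 * w + 1)
        for p in peaks:
            lo, hi = max(0, p - w), min(N, p + w + 1)
            train[lo:hi] = np.maximum(train[lo:hi], burst[lo - (p - w) : hi - (p - w)])
    env = (1.0 - depth) + depth * train
    carrier = _band_noise(rng, (N,), carrier_band, fs)
    return carrier * env


def project_and_add_noise(
    ensemble: SourceEnsemble,
    leadfield: LeadField,
    sensors: SensorArray,
    snr: dict[str, float] | None = None,
    seed: int = 0,
    band: tuple[float, float] | None = None,
    background_task: np.ndarray | None = None,
    background_rest: np.ndarray | None = None,
) -> tuple[RawRecording, RawRecording]:
    """Project sources to the sensors and add noise at target band SNR.

    ``leadfield`` must hold the gains at the true source locations (one voxel
    per source, in network order).  The noise per channel kind consists of an
    optional structured background (sensor-space projection of ongoing,
    task-unrelated brain activity, present in both task and rest) plus white
    sensor noise scaled so that the kind's mean realized band SNR (network
    band power over total noise band power in the oscillation band) matches
    the target; ``snr['meg']`` covers magnetometers and gradiometers.  Also
    returns a matched rest (noise-only) recording with identical noise
    statistics for noise-amplitude estimation.  A noise scale of zero
    (``snr=inf`` and no background) returns the projection exactly.
    """
    snr = {"eeg": 2.0, "meg": 8.0, **(snr or {})}
    net = ensemble.network
    if leadfield.n_voxels != net.n_sources:
        raise ValueError(
            f"lead field has {leadfield.n_voxels} voxels but the ensemble has "
            f"{net.n_sources} sources"
        )
    rng = np.random.default_rng(seed)
    gains = np.einsum("svk,vk->sv", leadfield.gain, net.moments)   # (S, n_src)
    clean = gains @ ensemble.sources                                # (S, N)

    fs = ensemble.fs
    band = band or net.band

    def _band_psd(x):
        freqs, psd = sps.welch(x, fs=fs, nperseg=int(fs), axis=1)
        sel = (freqs >= band[0]) & (freqs <= band[1])
        return psd[:, sel].mean(axis=1)

    sig_band = _band_psd(clean)                                     # per-channel band PSD
    noise_band_unit = 2.0 / fs                                      # white sigma=1 band PSD

    kinds = np.asarray([k for k in leadfield.kinds], dtype=object)
    task = clean.copy()
    rest = np.zeros_like(clean)
    bg_band = np.zeros(clean.shape[0])
    if background_task is not None:
        task += background_task
        rest += background_rest if background_rest is not None else background_task
        bg_band = _band_psd(background_rest if background_rest is not None else background_task)
    for kind in np.unique(kinds):
        m = kinds == kind
        target = snr["eeg"] if kind == "eeg" else snr["meg"]
        if not np.isfinite(target):
            continue
        if target <= 0:
            raise ValueError("target SNR must be positive")
        budget = sig_band[m].mean() / target - bg_band[m].mean()
        if budget <= 0:
            warnings.warn(
                f"{kind}: background alone exceeds the noise budget for "
                f"target SNR {target}; adding minimal white noise"
            )
            budget = 0.01 * sig_band[m].mean() / target
        sigma = np.sqrt(budget / noise_band_unit)
        task[m] += sigma * rng.standard_normal(task[m].shape)
        rest[m] += sigma * rng.standard_normal(task[m].shape)

    emg_rest = _band_noise(rng, (ensemble.emg.size,), (30.0, 200.0), fs)
    data = np.vstack([task, ensemble.emg])
    rest_data = np.vstack([rest, emg_rest])
    names = list(leadfield.names) + ["EMG"]
    all_kinds = np.concatenate([kinds, np.asarray(["emg"], dtype=object)])
    return (
        RawRecording(data, fs, names, all_kinds, sensors),
        RawRecording(rest_data, fs, list(names), all_kinds.copy(), sensors),
    )


def simulate_background(
    head: SphericalHeadModel,
    sensors: SensorArray,
    n_samples: int,
    n_dipoles: int = 60,
    amplitude: float = 1.0,
    seed: int = 0,
    fs: float = 1000.0,
    band: tuple[float, float] = (2.0, 4.0),
    radial: bool = True,
    radius_range: tuple[float, float] = (0.01, 0.075),
    kinds=("eeg", "mag", "grad"),
) -> np.ndarray:
    """Sensor-space projection of ongoing task-unrelated cortical activity.

    Independent band-limited dipoles scattered through the brain volume.
    With ``radial=True`` (the default) the dipoles are radially oriented --
    the population that dominates the EEG background but is exactly silent
    for a spherical-conductor MEG -- so the structured background raises the
    EEG noise floor across source space, deep locations included, while
    leaving MEG untouched.
    """
    rng = np.random.default_rng(seed)
    lo, hi = radius_range
    r = hi * rng.uniform((lo / hi) ** 3, 1.0, n_dipoles) ** (1.0 / 3.0)
    u = rng.standard_normal((n_dipoles, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    locs = head.center_arr + r[:, None] * u
    if radial:
        moments = u
    else:
        moments = rng.standard_normal((n_dipoles, 3))
        moments /= np.linalg.norm(moments, axis=1, keepdims=True)
    lf = build_leadfield(locs, head, sensors, kinds=kinds)
    g = np.einsum("svk,vk->sv", lf.gain, moments)
    series = amplitude * _band_noise(rng, (n_dipoles, n_samples), band, fs)
    return g @ series


# ---------------------------------------------------------------------------
# the calibrated study scenario


@dataclass
class Scenario:
    """A fully simulated study: head, sensors, truth, task and rest data."""

    head: SphericalHeadModel
    sensors: SensorArray
    network: TrueNetwork
    ensemble: SourceEnsemble
    task: RawRecording
    rest: RawRecording
    seed: int


def depth_profile_bimodal(
    n_epochs: int,
    seed: int,
    high: float = 0.95,
    low: float = 0.1,
    frac_high: float = 0.4,
) -> np.ndarray:
    """Per-epoch EMG modulation depth: a high-coupling minority of epochs."""
    rng = np.random.default_rng(seed)
    n_high = int(round(frac_high * n_epochs))
    depth = np.full(n_epochs, low)
    depth[rng.choice(n_epochs, n_high, replace=False)] = high
    return depth


def depth_profile_blocks(
    n_epochs: int,
    seed: int,
    high: float = 0.95,
    low: float = 0.1,
    frac_high: float = 0.4,
    block_len: int = 20,
) -> np.ndarray:
    """Blocky per-epoch EMG modulation depth: vigor drifts on a ~20 s scale.

    Contiguous high-coupling blocks emulate periods of vigorous tapping, the
    temporal structure that high-coherence segment selection exploits.
    """
    rng = np.random.default_rng(seed)
    n_blocks = max(1, int(np.ceil(n_epochs / block_len)))
    n_high = int(round(frac_high * n_blocks))
    states = np.zeros(n_blocks, bool)
    states[rng.choice(n_blocks, n_high, replace=False)] = True
    depth = np.where(np.repeat(states, block_len)[:n_epochs], high, low)
    return depth


def reference_study(
    seed: int = 0,
    n_epochs: int = 250,
    n_eeg: int = 96,
    n_mag: int = 51,
    n_grad: int = 51,
    snr: dict[str, float] | None = None,
    network: TrueNetwork | None = None,
    nonstationary: bool = True,
    background_amplitude: float = 0.5,
    deep_background_amplitude: float = 4.5,
    n_background: int = 60,
    fs: float = 1000.0,
) -> Scenario:
    """The default calibrated study: six coupled sources, EMG, MEG+EEG sensors.

    MEG scalp SNR is set higher than EEG (default 8 vs 2), and a radial
    cortical background (silent for MEG) structures the EEG noise floor.
    With ``nonstationary=True`` the EMG burst depth is bimodal across epochs,
    so corticomuscular coupling concentrates in a minority of high-depth
    epochs.
    """
    rng = np.random.default_rng(seed)
    s_net, s_emg, s_noise, s_fix, s_bg1, s_bg2 = rng.integers(2**31, size=6)
    head = SphericalHeadModel()
    sensors = build_sensor_fixture(n_eeg, n_mag, n_grad, head, seed=int(s_fix))
    net = network or default_network()
    ens = simulate_source_network(net, n_epochs=n_epochs, seed=int(s_net), fs=fs)
    if nonstationary:
        depth = depth_profile_blocks(n_epochs, int(s_emg), frac_high=0.3, block_len=40, low=0.02)
    else:
        depth = np.full(n_epochs, 0.9)
    per_sample = np.repeat(depth, int(round(fs)))
    ens.depth_profile = depth
    ens.emg = simulate_emg(
        ens.sources[net.index(net.driver)],
        modulation_depth=per_sample,
        seed=int(s_emg),
        fs=fs,
    )
    lf = build_leadfield(net.locations, head, sensors)
    bg_task = bg_rest = None
    if background_amplitude > 0 and n_background > 0:
        def _bg(s):
            shell = simulate_background(
                head, sensors, ens.n_samples, n_dipoles=n_background,
                amplitude=background_amplitude, seed=s, fs=fs, band=net.band,
                radius_range=(0.045, 0.075),
            )
            deep = simulate_background(
                head, sensors, ens.n_samples, n_dipoles=max(1, n_background // 2),
                amplitude=deep_background_amplitude, seed=s + 1, fs=fs,
                band=net.band, radius_range=(0.005, 0.035),
            )
            return shell + deep
        bg_task = _bg(int(s_bg1))
        bg_rest = _bg(int(s_bg2))
    task, rest = project_and_add_noise(
        ens, lf, sensors, snr={"eeg": 1.0, "meg": 14.0, **(snr or {})},
        seed=int(s_noise), background_task=bg_task, background_rest=bg_rest,
    )
    return Scenario(
        head=head, sensors=sensors, network=net, ensemble=ens,
        task=task, rest=rest, seed=seed,
    )


def truth_dict(net: TrueNetwork) -> dict:
    """JSON-serializable ground truth (locations in mm, edge list)."""
    return {
        "names": list(net.names),
        "locations_mm": (1e3 * net.locations).tolist(),
        "moments": net.moments.tolist(),
        "amplitudes": net.amplitudes.tolist(),
        "edges": [
            {"source": s, "target": t, "lag_samples": int(l), "gain": float(g)}
            for s, t, l, g in net.edges
        ],
        "band_hz": list(net.band),
        "driver": net.driver,
    }
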