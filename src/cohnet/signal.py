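"""Pre-processing and spectral estimation.

Zero-phase band-pass filtering per modality, EMG full-wave rectification,
segmentation into 1-s epochs with amplitude-based artifact rejection,
Slepian multitaper cross-spectral densities, coherence and pooled coherence,
sliding-window time-frequency coherence, and selection of high-coherence
time segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss

from .forward import SensorArray

DEFAULT_BANDS = {
    "eeg": (0.05, 200.0),
    "mag": (0.05, 200.0),
    "grad": (0.05, 200.0),
    "emg": (30.0, 200.0),
}


@dataclass
class RawRecording:
    """Continuous multichannel recording (channels x samples)."""

    data: np.ndarray
    fs: float
    names: list[str]
    kinds: np.ndarray
    sensors: SensorArray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        self.kinds = np.asarray(self.kinds, dtype=object)

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class EpochedRecording:
    """Epoched recording: channels x epochs x samples, with channel metadata."""

    data: np.ndarray
    fs: float
    names: list[str]
    kinds: np.ndarray
    sensors: SensorArray | None = None
    epoch_indices: np.ndarray | None = None   # indices into the original segmentation
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be channels x epochs x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoched data contains non-finite values")
        self.kinds = np.asarray(self.kinds, dtype=object)
        if self.epoch_indices is None:
            self.epoch_indices = np.arange(self.data.shape[1])

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_length(self) -> float:
        return self.data.shape[2] / self.fs

    def channel_index(self, name: str) -> int:
        return self.names.index(name)

    def pick(self, mask) -> "EpochedRecording":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return EpochedRecording(
            data=self.data[idx],
            fs=self.fs,
            names=[self.names[i] for i in idx],
            kinds=self.kinds[idx],
            sensors=self.sensors,
            epoch_indices=self.epoch_indices,
            log=list(self.log),
        )

    def select_epochs(self, epochs) -> "EpochedRecording":
        epochs = np.asarray(epochs, int)
        return EpochedRecording(
            data=self.data[:, epochs],
            fs=self.fs,
            names=list(self.names),
            kinds=self.kinds,
            sensors=self.sensors,
            epoch_indices=self.epoch_indices[epochs],
            log=list(self.log) + [f"selected {epochs.size} epochs"],
        )


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    nyq = fs / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band edges ({lo}, {hi}) Hz must lie inside (0, {nyq}) Hz")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def filter_raw(
    raw: RawRecording,
    bands: dict[str, tuple[float, float]] | None = None,
    rectify_emg: bool = True,
    average_ref_eeg: bool = True,
) -> RawRecording:
    """Zero-phase band-pass per modality; EMG full-wave rectified after filtering.

    The rectified EMG is demeaned (rectification otherwise injects a DC
    offset), and EEG channels are re-referenced to their common average so
    data and lead field share the same reference.
    """
    bands = {**DEFAULT_BANDS, **(bands or {})}
    out = raw.data.copy()
    for kind in np.unique(raw.kinds):
        m = raw.kinds == kind
        lo, hi = bands[str(kind)]
        out[m] = sps.sosfiltfilt(_bandpass_sos(lo, hi, raw.fs), out[m], axis=1)
    emg = raw.kinds == "emg"
    if rectify_emg and emg.any():
        out[emg] = np.abs(out[emg])
        out[emg] -= out[emg].mean(axis=1, keepdims=True)
    eeg = raw.kinds == "eeg"
    if average_ref_eeg and eeg.any():
        out[eeg] -= out[eeg].mean(axis=0, keepdims=True)
    return RawRecording(out, raw.fs, list(raw.names), raw.kinds, raw.sensors)


def epoch_and_reject(
    raw: RawRecording,
    epoch_length: float = 1.0,
    reject_z: float | None = 5.0,
    reject_kinds=("eeg", "mag", "grad"),
) -> EpochedRecording:
    """Segment into fixed-length epochs, dropping high-amplitude epochs.

    An epoch is rejected when any brain channel reaches a peak amplitude whose
    robust z-score (relative to the channel's median absolute deviation over
    the whole recording) exceeds ``reject_z`` -- a deterministic stand-in for
    visual artifact screening.  EMG is excluded: its bursts are signal.
    """
    samples = int(round(epoch_length * raw.fs))
    n_epochs = raw.data.shape[1] // samples
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    x = raw.data[:, : n_epochs * samples].reshape(raw.data.shape[0], n_epochs, samples)
    keep = np.ones(n_epochs, bool)
    if reject_z is not None:
        m = np.isin(raw.kinds, list(reject_kinds))
        if m.any():
            med = np.median(raw.data[m], axis=1, keepdims=True)
            mad = np.median(np.abs(raw.data[m] - med), axis=1, keepdims=True)
            scale = np.maximum(1.4826 * mad, 1e-30)
            z = np.abs(x[m] - med[:, :, None]) / scale[:, :, None]
            keep = z.max(axis=(0, 2)) <= reject_z
    log = [
        f"epoched into {n_epochs} x {epoch_length:g} s segments",
        f"artifact rejection kept {int(keep.sum())}/{n_epochs} epochs",
    ]
    return EpochedRecording(
        data=x[:, keep],
        fs=raw.fs,
        names=list(raw.names),
        kinds=raw.kinds,
        sensors=raw.sensors,
        epoch_indices=np.flatnonzero(keep),
        log=log,
    )


def preprocess(
    raw: RawRecording,
    bands: dict | None = None,
    epoch_length: float = 1.0,
    reject_z: float | None = 5.0,
    rectify_emg: bool = True,
) -> EpochedRecording:
    """Filter, rectify EMG, epoch, and reject artifacts in one step."""
    if raw.duration < 10.0:
        raise ValueError("raw recording must be at least 10 s long")
    return epoch_and_reject(
        filter_raw(raw, bands, rectify_emg=rectify_emg),
        epoch_length=epoch_length,
        reject_z=reject_z,
    )


# ---------------------------------------------------------------------------
# multitaper spectral estimation


@dataclass
class TaperedSpectra:
    """Per-epoch, per-taper Fourier coefficients at the analysis bins.

    The elementary quantity behind every spectral estimate here; keeping it
    explicit makes epoch-permutation surrogates cheap.
    """

    coef: np.ndarray          # (channels, epochs, K, bins) complex
    freqs: np.ndarray
    names: list[str]
    kinds: np.ndarray
    fs: float
    K: int

    @property
    def n_epochs(self) -> int:
        return self.coef.shape[1]

    def channel_index(self, name: str) -> int:
        return self.names.index(name)

    def csd(self) -> "CrossSpectrum":
        S = np.einsum("iekf,jekf->fij", self.coef, self.coef.conj())
        S /= self.coef.shape[1] * self.coef.shape[2]
        return CrossSpectrum(
            freqs=self.freqs, S=S, K=self.K, M=self.n_epochs,
            names=list(self.names), kinds=self.kinds,
        )


@dataclass
class CrossSpectrum:
    """Channels x channels complex cross-spectral matrix per frequency bin."""

    freqs: np.ndarray
    S: np.ndarray             # (bins, C, C) complex, Hermitian
    K: int
    M: int
    names: list[str]
    kinds: np.ndarray | None = None

    def __post_init__(self) -> None:
        herm = np.abs(self.S - np.conj(np.swapaxes(self.S, 1, 2))).max()
        scale = max(np.abs(self.S).max(), 1e-300)
        if herm / scale > 1e-8:
            raise ValueError("cross-spectral matrices must be Hermitian")
        d = np.diagonal(self.S, axis1=1, axis2=2)
        if np.any(d.real < -1e-12 * scale):
            raise ValueError("auto-spectra must be non-negative")

    def channel_index(self, name: str) -> int:
        return self.names.index(name)

    def to_table(self, x, y):
        """Tabular export of one pair's coherence: (frequency, value)."""
        import pandas as pd

        return pd.DataFrame(
            {"frequency_hz": self.freqs, "coherence": coherence(self, x, y)}
        )


def tapered_fft(
    epochs: EpochedRecording,
    band: tuple[float, float] = (2.0, 4.0),
    K: int = 7,
    NW: float = 4.0,
    channels=None,
) -> TaperedSpectra:
    """Slepian-tapered Fourier coefficients at the bins inside ``band``.

    Frequency resolution is 1/epoch_length; tapers are unit-energy DPSS with
    time-bandwidth NW.
    """
    if K < 1:
        raise ValueError("at least one taper is required")
    x = epochs.data
    names, kinds = list(epochs.names), epochs.kinds
    if channels is not None:
        idx = [epochs.channel_index(c) if isinstance(c, str) else int(c) for c in channels]
        x = x[idx]
        names = [names[i] for i in idx]
        kinds = kinds[idx]
    T = x.shape[2]
    df = epochs.fs / T
    if band[1] >= epochs.fs / 2 or band[0] <= 0:
        raise ValueError(f"band {band} outside (0, Nyquist)")
    if band[1] - band[0] < df / 2 and not np.isclose(band[0] % df, 0):
        raise ValueError("epoch too short for the requested frequency resolution")
    tapers = dpss(T, NW, Kmax=K)                       # (K, T), unit energy
    freqs = np.fft.rfftfreq(T, 1 / epochs.fs)
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band}")
    coef = np.fft.rfft(x[:, :, None, :] * tapers[None, None, :, :], axis=-1)[..., sel]
    coef *= np.sqrt(2.0 / epochs.fs)
    return TaperedSpectra(
        coef=coef, freqs=freqs[sel], names=names, kinds=kinds, fs=epochs.fs, K=K
    )


def multitaper_csd(
    epochs: EpochedRecording,
    band: tuple[float, float] = (2.0, 4.0),
    K: int = 7,
    NW: float = 4.0,
    channels=None,
) -> CrossSpectrum:
    """Multitaper cross-spectral density averaged over tapers and epochs."""
    return tapered_fft(epochs, band=band, K=K, NW=NW, channels=channels).csd()


def coherence(csd: CrossSpectrum, x, y) -> np.ndarray:
    """Magnitude-squared coherence |C_xy|^2 / (C_xx C_yy) per frequency bin."""
    i = csd.channel_index(x) if isinstance(x, str) else int(x)
    j = csd.channel_index(y) if isinstance(y, str) else int(y)
    sxx = csd.S[:, i, i].real
    syy = csd.S[:, j, j].real
    bad = np.flatnonzero((sxx <= 0) | (syy <= 0))
    if bad.size:
        raise ValueError(
            f"zero auto-spectrum at bin(s) {csd.freqs[bad].tolist()} Hz for pair ({x}, {y})"
        )
    return np.abs(csd.S[:, i, j]) ** 2 / (sxx * syy)


def pool_coherence(
    cross: np.ndarray, auto_x: np.ndarray, auto_y: np.ndarray, weights=None
) -> np.ndarray:
    """Pooled coherence over groups (first axis): |sum w C_xy|^2 / (sum w C_xx * sum w C_yy)."""
    cross = np.atleast_2d(cross)
    auto_x = np.atleast_2d(auto_x).real
    auto_y = np.atleast_2d(auto_y).real
    if weights is None:
        weights = np.ones(cross.shape[0])
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("pooling weights must be positive")
    w = w[:, None]
    num = np.abs((w * cross).sum(axis=0)) ** 2
    den = (w * auto_x).sum(axis=0) * (w * auto_y).sum(axis=0)
    return num / den


def pooled_coherence(csds, pairs, weights=None) -> np.ndarray:
    """Pooled coherence across groups of cross-spectra.

    ``csds`` is a list of CrossSpectrum sharing a frequency grid; ``pairs`` is
    one (x, y) pair per group, or a single pair applied to all groups.
    Default weights are the epoch-taper products K*M of each group.
    """
    if isinstance(csds, CrossSpectrum):
        csds = [csds] * len(pairs)
    if isinstance(pairs, tuple) and len(pairs) == 2 and not isinstance(pairs[0], tuple):
        pairs = [pairs] * len(csds)
    if len(csds) != len(pairs):
        raise ValueError("need one channel pair per cross-spectrum group")
    f0 = csds[0].freqs
    for c in csds[1:]:
        if not np.allclose(c.freqs, f0):
            raise ValueError("groups must share the frequency grid")
    cross, ax, ay = [], [], []
    for c, (x, y) in zip(csds, pairs):
        i = c.channel_index(x) if isinstance(x, str) else int(x)
        j = c.channel_index(y) if isinstance(y, str) else int(y)
        cross.append(c.S[:, i, j])
        ax.append(c.S[:, i, i].real)
        ay.append(c.S[:, j, j].real)
    if weights is None:
        weights = [c.K * c.M for c in csds]
    return pool_coherence(np.array(cross), np.array(ax), np.array(ay), weights)


# ---------------------------------------------------------------------------
# time-frequency coherence


@dataclass
class TimeFrequencyCoherence:
    """Sliding-window coherence: values (times x frequencies) in [0, 1]."""

    times: np.ndarray        # window centers (s)
    freqs: np.ndarray
    values: np.ndarray       # (n_windows, n_freqs)
    window: float
    step: float
    pooled: bool = False

    def __post_init__(self) -> None:
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("coherence values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def band_course(self, band: tuple[float, float]) -> np.ndarray:
        sel = (self.freqs >= band[0] - 1e-9) & (self.freqs <= band[1] + 1e-9)
        return self.values[:, sel].mean(axis=1)

    def to_table(self):
        """Long-format export: (time, frequency, coherence) rows."""
        import pandas as pd

        t, f = np.meshgrid(self.times, self.freqs, indexing="ij")
        return pd.DataFrame(
            {"time_s": t.ravel(), "frequency_hz": f.ravel(),
             "coherence": self.values.ravel()}
        )


def _sliding_tapered(x, fs, freqs, window, step, K, NW):
    T = int(round(window * fs))
    hop = int(round(step * fs))
    if hop < 1 or hop > T:
        raise ValueError("step must be positive and no longer than the window")
    if x.shape[-1] < T:
        raise ValueError("signal shorter than one analysis window")
    tapers = dpss(T, NW, Kmax=K)
    t = np.arange(T) / fs
    # kernel: (K * F, T) -- project each windowed segment on taper x tone
    tones = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])
    kernel = (tapers[:, None, :] * tones[None, :, :]).reshape(K * len(freqs), T)
    segs = np.lib.stride_tricks.sliding_window_view(x, T, axis=-1)[..., ::hop, :]
    coef = segs @ kernel.T                       # (..., n_win, K*F)
    coef = coef.reshape(segs.shape[:-1] + (K, len(freqs)))
    times = (np.arange(segs.shape[-2]) * hop + T / 2) / fs
    return times, coef


def tf_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float] = (2.0, 4.0),
    window: float = 1.0,
    step: float = 0.05,
    K: int = 7,
    NW: float = 4.0,
) -> TimeFrequencyCoherence:
    """Sliding multitaper coherence between two continuous signals.

    Frequency bin spacing is 1/window; successive estimates are ``step``
    seconds apart (the window overlap is window - step).
    """
    return pooled_tf_coherence(
        np.atleast_2d(x), y, fs, band=band, window=window, step=step, K=K, NW=NW
    )


def pooled_tf_coherence(
    X: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float] = (2.0, 4.0),
    window: float = 1.0,
    step: float = 0.05,
    K: int = 7,
    NW: float = 4.0,
    weights=None,
    align_polarity: bool = True,
) -> TimeFrequencyCoherence:
    """Time-frequency coherence pooled over channel-reference pairs.

    Rows of ``X`` are channels, each paired with the common reference ``y``.
    With ``align_polarity`` each channel is sign-flipped so that its overall
    band cross-spectrum with the reference has a positive real part --
    without this, sensors sitting on opposite lobes of a dipolar field
    pattern cancel in the pooled numerator.
    """
    X = np.atleast_2d(np.asarray(X, float))
    df = 1.0 / window
    freqs = np.arange(np.ceil(band[0] / df) * df, band[1] + df / 2, df)
    times, cx = _sliding_tapered(X, fs, freqs, window, step, K, NW)
    _, cy = _sliding_tapered(np.asarray(y, float), fs, freqs, window, step, K, NW)
    cross = np.einsum("pwkf,wkf->pwf", cx, cy.conj()) / K
    if align_polarity and X.shape[0] > 1:
        sign = np.where(cross.sum(axis=(1, 2)).real >= 0, 1.0, -1.0)
        cross *= sign[:, None, None]
    ax = np.einsum("pwkf,pwkf->pwf", cx, cx.conj()).real / K
    ay = np.einsum("wkf,wkf->wf", cy, cy.conj()).real / K
    vals = pool_coherence(
        cross.reshape(X.shape[0], -1),
        ax.reshape(X.shape[0], -1),
        np.broadcast_to(ay, cross.shape[1:]).reshape(1, -1).repeat(X.shape[0], 0),
        weights,
    ).reshape(cross.shape[1:])
    return TimeFrequencyCoherence(
        times=times, freqs=freqs, values=vals, window=window, step=step,
        pooled=X.shape[0] > 1,
    )


def select_high_coherence_segments(
    tfc: TimeFrequencyCoherence,
    band: tuple[float, float] = (2.0, 4.0),
    epoch_length: float = 1.0,
    smooth: float = 0.0,
) -> np.ndarray:
    """Indices of epochs whose band coherence strictly exceeds mean + 1 std.

    The threshold is mean + 1 sample standard deviation (ddof=1) of the
    band-averaged time course; each window contributes to the epoch containing
    its center.  ``smooth`` (seconds) optionally applies a moving average to
    the time course before thresholding -- a variance-reduction step useful
    when coupling strength drifts on a multi-second scale.  Returns a
    (possibly empty) sorted array of epoch indices.
    """
    course = tfc.band_course(band)
    if course.size < 2:
        raise ValueError("need at least two time points to select segments")
    if smooth > 0:
        w = max(1, int(round(smooth / tfc.step)))
        kernel = np.ones(w) / w
        course = np.convolve(course, kernel, mode="same")
    thresh = course.mean() + course.std(ddof=1)
    ep = np.floor(tfc.times / epoch_length).astype(int)
    selected = sorted(
        int(e) for e in np.unique(ep) if course[ep == e].mean() > thresh
    )
    if not selected:
        warnings.warn("no segments exceed the mean+std coherence threshold")
    return np.asarray(selected, int)
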