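"""Scalp- and source-level SNR, paired EEG/MEG sensor selection, and
Euclidean distances of found sources to named reference coordinates.

SNR is the unitless ratio of band power (2-4 Hz by default) during the task
to band power during a rest recording, per channel or per reconstructed
source signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .forward import SensorArray
from .signal import EpochedRecording
from .synthesis import MNI_TO_HEAD_SCALE, REFERENCE_MNI, mni_to_head


@dataclass
class SNRReport:
    """Per-channel (or per-source) band-power SNR and its selection mean."""

    labels: list[str]
    snr: np.ndarray
    modality: str
    selection: str
    band: tuple[float, float]

    def __post_init__(self) -> None:
        self.snr = np.asarray(self.snr, float)
        if np.any(self.snr <= 0):
            raise ValueError("SNR values must be positive")

    @property
    def mean(self) -> float:
        return float(self.snr.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "modality": self.modality,
                "channel_or_source": self.labels,
                "snr": self.snr,
                "selection": self.selection,
            }
        )

    def in_db(self) -> np.ndarray:
        return 10.0 * np.log10(self.snr)


@dataclass
class ReferenceAtlas:
    """Named reference source locations (MNI mm) and their head-frame map."""

    mni_mm: dict[str, tuple[float, float, float]]
    scale: float = MNI_TO_HEAD_SCALE

    def __post_init__(self) -> None:
        if len(set(self.mni_mm)) != len(self.mni_mm):
            raise ValueError("reference names must be unique")

    @property
    def names(self) -> list[str]:
        return list(self.mni_mm)

    def head_location(self, name: str) -> np.ndarray:
        """Head-frame location in meters."""
        return mni_to_head(self.mni_mm[name], self.scale)


def default_atlas() -> ReferenceAtlas:
    return ReferenceAtlas(dict(REFERENCE_MNI))


# ---------------------------------------------------------------------------
# sensor pairing


def pair_sensors(
    sensors: SensorArray,
    center: str | None = None,
    sphere_radius: float = 0.04,
    max_pair_dist: float = 0.02,
    n_pairs: int | None = None,
    scalp_radius: float | None = None,
) -> pd.DataFrame:
    """EEG electrodes around the C3-analog paired with their nearest MEG sensor.

    EEG candidates lie within ``sphere_radius`` (Euclidean) of the center
    electrode; each is matched to the nearest MEG sensor after radial
    projection of the helmet positions onto the scalp sphere (the helmet
    stand-off would otherwise make every raw distance exceed the pairing
    limit), keeping pairs at most ``max_pair_dist`` apart.  ``n_pairs`` caps
    the selection at the electrodes closest to the center.  Returns a frame
    with columns (eeg, meg, pair_distance_mm, center_distance_mm).
    """
    center = center or sensors.c3_name
    if center is None or center not in sensors.names:
        raise ValueError("center electrode not found in the sensor array")
    empty = pd.DataFrame(columns=["eeg", "meg", "pair_distance_mm", "center_distance_mm"])
    c = sensors.positions[sensors.index(center)]
    eeg = sensors.mask("eeg")
    meg = sensors.mask({"mag", "grad"})
    if scalp_radius is None:
        scalp_radius = float(np.linalg.norm(sensors.positions[eeg], axis=1).mean())
    d_center = np.linalg.norm(sensors.positions - c, axis=1)
    cand = np.flatnonzero(eeg & (d_center < sphere_radius))
    if cand.size == 0:
        warn("no EEG electrodes inside the selection sphere")
        return empty
    cand = cand[np.argsort(d_center[cand])]
    if n_pairs is not None:
        cand = cand[:n_pairs]
    meg_idx = np.flatnonzero(meg)
    if meg_idx.size == 0:
        warn("no MEG sensors available for pairing")
        return empty
    meg_pos = sensors.positions[meg_idx]
    meg_proj = meg_pos * (
        scalp_radius / np.linalg.norm(meg_pos, axis=1, keepdims=True)
    )
    rows = []
    for i in cand:
        dd = np.linalg.norm(meg_proj - sensors.positions[i], axis=1)
        j = int(np.argmin(dd))
        if dd[j] <= max_pair_dist:
            rows.append(
                {
                    "eeg": sensors.names[i],
                    "meg": sensors.names[meg_idx[j]],
                    "pair_distance_mm": 1e3 * dd[j],
                    "center_distance_mm": 1e3 * d_center[i],
                }
            )
    return pd.DataFrame(rows) if rows else empty


# ---------------------------------------------------------------------------
# SNR


def band_power(
    data: np.ndarray,
    fs: float,
    band: tuple[float, float],
    K: int = 7,
    NW: float = 4.0,
    mode: str = "band_mean",
) -> np.ndarray:
    """Multitaper band power per channel of (channels, epochs, samples) data.

    ``band_mean`` averages the power spectral density over the band's bins;
    ``peak_bin`` takes the maximum bin instead.
    """
    x = np.asarray(data, float)
    if x.ndim == 2:
        x = x[:, None, :]
    T = x.shape[-1]
    tapers = dpss(T, NW, Kmax=K)
    freqs = np.fft.rfftfreq(T, 1 / fs)
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    coef = np.fft.rfft(x[:, :, None, :] * tapers[None, None, :, :], axis=-1)[..., sel]
    psd = (2.0 / fs) * (np.abs(coef) ** 2).mean(axis=(1, 2))
    if mode == "band_mean":
        return psd.mean(axis=1)
    if mode == "peak_bin":
        return psd.max(axis=1)
    raise ValueError(f"unknown band power mode {mode!r}")


def scalp_snr(
    task: EpochedRecording,
    rest: EpochedRecording,
    band: tuple[float, float] = (2.0, 4.0),
    channels=None,
    mode: str = "band_mean",
    selection: str = "all",
) -> SNRReport:
    """Per-channel band-power SNR: task power over rest power at 2-4 Hz."""
    if task.names != rest.names or task.fs != rest.fs:
        raise ValueError("task and rest recordings must share channels and rate")
    if channels is None:
        idx = [i for i, k in enumerate(task.kinds) if k != "emg"]
    else:
        idx = [task.channel_index(c) if isinstance(c, str) else int(c) for c in channels]
    pt = band_power(task.data[idx], task.fs, band, mode=mode)
    pr = band_power(rest.data[idx], rest.fs, band, mode=mode)
    if np.any(pr <= 0):
        raise ValueError("rest band power vanishes for some channel")
    kinds = {str(task.kinds[i]) for i in idx}
    return SNRReport(
        labels=[task.names[i] for i in idx],
        snr=pt / pr,
        modality="+".join(sorted(kinds)),
        selection=selection,
        band=band,
    )


def source_snr(
    task_signals: np.ndarray,
    rest_signals: np.ndarray,
    fs: float,
    band: tuple[float, float] = (2.0, 4.0),
    labels: list[str] | None = None,
    mode: str = "band_mean",
    selection: str = "sources",
) -> SNRReport:
    """Band-power SNR of reconstructed (pooled) source signals."""
    pt = band_power(task_signals, fs, band, mode=mode)
    pr = band_power(rest_signals, fs, band, mode=mode)
    if np.any(pr <= 0):
        raise ValueError("rest band power vanishes for some source")
    labels = labels or [f"S{i + 1}" for i in range(pt.size)]
    return SNRReport(
        labels=labels, snr=pt / pr, modality="source", selection=selection, band=band
    )


# ---------------------------------------------------------------------------
# distances to the reference atlas


def distance_to_reference(
    found: dict[str, np.ndarray],
    atlas: ReferenceAtlas | None = None,
) -> dict[str, float]:
    """Euclidean distance (mm) from each named found source to its reference.

    ``found`` maps reference names to head-frame locations in meters.
    """
    atlas = atlas or default_atlas()
    out = {}
    for name, loc in found.items():
        if name not in atlas.mni_mm:
            raise KeyError(f"unknown source name {name!r}")
        out[name] = 1e3 * float(
            np.linalg.norm(np.asarray(loc, float) - atlas.head_location(name))
        )
    return out


def match_sources_to_atlas(
    sources,
    atlas: ReferenceAtlas | None = None,
    max_distance_mm: float | None = None,
) -> dict[str, object]:
    """Greedy nearest-neighbor assignment of found sources to atlas names.

    Pairs are assigned in increasing order of distance; each name and each
    source is used at most once; pairs beyond ``max_distance_mm`` are dropped.
    """
    atlas = atlas or default_atlas()
    if not sources:
        return {}
    names = atlas.names
    D = np.array(
        [
            [1e3 * np.linalg.norm(s.location - atlas.head_location(n)) for n in names]
            for s in sources
        ]
    )
    matched: dict[str, object] = {}
    used_src: set[int] = set()
    for flat in np.argsort(D, axis=None):
        i, j = np.unravel_index(flat, D.shape)
        if i in used_src or names[j] in matched:
            continue
        if max_distance_mm is not None and D[i, j] > max_distance_mm:
            break
        matched[names[j]] = sources[i]
        used_src.add(i)
    return matched
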