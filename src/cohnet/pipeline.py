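"""End-to-end pipeline: preprocessing, noise whitening, DICS source search,
source-signal reconstruction, SNR reports, and directed connectivity.

Every stage draws its randomness from the one root seed in the
configuration; two runs with the same inputs and seed produce identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import connectivity as conn
from . import dics, signal, snr_stats
from .config import PipelineConfig
from .forward import LeadField, SphericalHeadModel, build_leadfield, make_voxel_grid, whiten_and_combine
from .signal import EpochedRecording, RawRecording


@dataclass
class PipelineResult:
    """Everything the pipeline produces for one recording and configuration."""

    config: PipelineConfig
    sources: list
    maps: list
    matched: dict[str, object]            # atlas name -> IdentifiedSource
    distances_mm: dict[str, float]
    source_signals: object | None
    connectivity: object | None
    edges: list[tuple[str, str]]
    scalp_snr: dict[str, snr_stats.SNRReport]
    source_snr: snr_stats.SNRReport | None
    selected_epochs: np.ndarray | None
    log: list[str] = field(default_factory=list)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def source_names(self) -> list[str]:
        inv = {id(s): n for n, s in self.matched.items()}
        return [inv.get(id(s), s.name) for s in self.sources]


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(2**31, size=n)]


def _noise_amplitudes(rest: EpochedRecording, names, band) -> dict[str, float]:
    idx = [rest.channel_index(n) for n in names]
    power = snr_stats.band_power(rest.data[idx], rest.fs, band)
    return {n: float(np.sqrt(p)) for n, p in zip(names, power)}


def _whitened_epochs(epochs: EpochedRecording, amps: dict[str, float], emg: str):
    names = list(amps) + [emg]
    idx = [epochs.channel_index(n) for n in names]
    data = epochs.data[idx].copy()
    scale = np.array([amps[n] for n in list(amps)] + [1.0])
    data /= scale[:, None, None]
    return EpochedRecording(
        data=data, fs=epochs.fs, names=names,
        kinds=epochs.kinds[idx], sensors=epochs.sensors,
        epoch_indices=epochs.epoch_indices, log=list(epochs.log),
    )


def _tf_selection_channels(task: RawRecording, cfg: PipelineConfig) -> list[str]:
    """Channels for the pooled time-frequency coherence: the paired EEG/MEG
    sensors around the C3-analog (both modalities pool into one estimate);
    falls back to the modality's sensors nearest to C3."""
    sensors = task.sensors
    c3 = sensors.positions[sensors.index(sensors.c3_name)]
    out: list[str] = []
    for group in (("eeg",), ("mag", "grad")):
        cands = [
            (np.linalg.norm(sensors.positions[sensors.index(n)] - c3), n)
            for n, k in zip(task.names, task.kinds)
            if k in group
        ]
        cands.sort()
        out += [n for _, n in cands[: cfg.n_pairs]]
    return out


def run_pipeline(
    task: RawRecording,
    rest: RawRecording,
    head: SphericalHeadModel,
    config: PipelineConfig | None = None,
    leadfield: LeadField | None = None,
) -> PipelineResult:
    """Run the full coherent-source analysis on one task/rest pair."""
    cfg = (config or PipelineConfig()).validate()
    log: list[str] = [f"modality={cfg.modality} band={cfg.band} seed={cfg.seed}"]
    seed_perm, seed_boot, *_ = _stage_seeds(cfg.seed)
    sensors = task.sensors
    if sensors is None:
        raise ValueError("task recording carries no sensor array")

    # --- pre-processing ------------------------------------------------
    try:
        filtered = signal.filter_raw(task)
        epochs = signal.epoch_and_reject(
            filtered, epoch_length=cfg.epoch_length, reject_z=cfg.reject_z
        )
        rest_epochs = signal.epoch_and_reject(
            signal.filter_raw(rest), epoch_length=cfg.epoch_length, reject_z=None
        )
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"pre-processing failed: {e}") from e
    log += epochs.log

    keep = [n for n, k in zip(task.names, task.kinds) if k in cfg.kinds]
    if not keep:
        raise RuntimeError(f"no channels for modality {cfg.modality!r}")

    # --- lead field and whitening --------------------------------------
    try:
        if leadfield is None:
            grid = make_voxel_grid(head, spacing=cfg.grid_spacing_mm / 1e3)
            leadfield = build_leadfield(grid, head, sensors, kinds=cfg.kinds)
        amps = _noise_amplitudes(rest_epochs, list(leadfield.names), cfg.band)
        lf_w = whiten_and_combine(leadfield, amps)
        epochs_w = _whitened_epochs(epochs, amps, "EMG")
        rest_w = _whitened_epochs(rest_epochs, amps, "EMG")
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"forward/whitening stage failed: {e}") from e
    log.append(f"lead field: {lf_w.n_sensors} channels x {lf_w.n_voxels} voxels")

    # --- optional high-coherence segment selection ---------------------
    selected = None
    if cfg.segment_selection:
        chans = _tf_selection_channels(task, cfg)
        X = filtered.data[[filtered.channel_index(c) for c in chans]]
        y = filtered.data[filtered.channel_index("EMG")]
        tfc = signal.pooled_tf_coherence(
            X, y, task.fs, band=cfg.band, K=cfg.n_tapers, NW=cfg.taper_nw
        )
        selected = signal.select_high_coherence_segments(
            tfc, band=cfg.band, epoch_length=cfg.epoch_length,
            smooth=cfg.selection_smooth_s,
        )
        pos = {int(e): i for i, e in enumerate(epochs_w.epoch_indices)}
        rows = [pos[int(e)] for e in selected if int(e) in pos]
        log.append(
            f"segment selection kept {len(rows)} of {epochs_w.n_epochs} epochs"
        )
        if len(rows) >= 20:
            epochs_w = epochs_w.select_epochs(rows)
        else:
            log.append("segment selection yielded <20 epochs; keeping all")

    # --- DICS source search --------------------------------------------
    try:
        ts = signal.tapered_fft(epochs_w, band=cfg.band, K=cfg.n_tapers, NW=cfg.taper_nw)
        sources, maps = dics.sequential_source_search(
            ts, lf_w, head, reference="EMG",
            max_sources=cfg.max_sources, n_perm=cfg.n_perm,
            percentile=cfg.surrogate_percentile, seed=seed_perm, alpha=cfg.alpha,
            orientation_convention=cfg.orientation_convention,
        )
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"DICS source search failed: {e}") from e
    log.append(f"sequential search found {len(sources)} sources")

    atlas = snr_stats.default_atlas()
    matched = snr_stats.match_sources_to_atlas(
        sources, atlas, max_distance_mm=max(25.0, 2.5 * cfg.grid_spacing_mm)
    )
    distances = {
        name: 1e3 * float(np.linalg.norm(src.location - atlas.head_location(name)))
        for name, src in matched.items()
    }

    # --- source signals and SNR ----------------------------------------
    sig_set = None
    source_report = None
    if sources:
        sig_set = dics.reconstruct_source_signals(
            sources, epochs_w, lf_w, reference="EMG",
            alpha=cfg.alpha, band=cfg.band, K=cfg.n_tapers,
        )
        rest_idx = [rest_w.channel_index(n) for n in sig_set.channel_names]
        rest_sigs = np.einsum("ks,set->ket", sig_set.sensor_weights, rest_w.data[rest_idx])
        inv = {id(s): n for n, s in matched.items()}
        labels = [inv.get(id(s), s.name) for s in sources]
        source_report = snr_stats.source_snr(
            sig_set.signals, rest_sigs, epochs_w.fs, band=cfg.band,
            labels=labels, selection="selected" if selected is not None else "all",
        )

    pairs = snr_stats.pair_sensors(
        sensors,
        sphere_radius=cfg.pair_sphere_mm / 1e3,
        max_pair_dist=cfg.pair_max_dist_mm / 1e3,
        n_pairs=cfg.n_pairs,
    )
    scalp = {}
    if len(pairs):
        scalp["eeg"] = snr_stats.scalp_snr(
            epochs, rest_epochs, band=cfg.band,
            channels=list(pairs["eeg"]), selection="paired-C3",
        )
        scalp["meg"] = snr_stats.scalp_snr(
            epochs, rest_epochs, band=cfg.band,
            channels=list(pairs["meg"]), selection="paired-C3",
        )

    # --- directed connectivity -----------------------------------------
    rp = None
    edges: list[tuple[str, str]] = []
    if sig_set is not None and sig_set.n_sources >= 2:
        try:
            sigs, cfs = conn.resample_signals(
                sig_set.signals, epochs_w.fs, cfg.connectivity_fs
            )
            rp = conn.analyze_connectivity(
                sigs, cfs, band=cfg.band, p_max=cfg.p_max,
                n_boot=cfg.n_boot, percentile=cfg.bootstrap_percentile,
                seed=seed_boot, names=labels, time_reversal=cfg.time_reversal,
            )
            edges = rp.edges(confirmed_only=cfg.time_reversal)
            log.append(f"connectivity: MVAR order {rp.order}, {len(edges)} edges")
        except Exception as e:  # noqa: BLE001
            raise RuntimeError(f"connectivity stage failed: {e}") from e

    return PipelineResult(
        config=cfg, sources=sources, maps=maps, matched=matched,
        distances_mm=distances, source_signals=sig_set, connectivity=rp,
        edges=edges, scalp_snr=scalp, source_snr=source_report,
        selected_epochs=selected, log=log,
    )
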