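"""Dynamic imaging of coherent sources (DICS).

Frequency-domain beamforming on the band-limited cross-spectral density:
unit-gain spatial filters per voxel, voxel-wise coherence maps against a
reference signal (EMG), epoch-permutation surrogate thresholds, sequential
search for weaker sources by nulling already-found ones, reconstruction of
pooled source signals, and dipole-orientation classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField, SphericalHeadModel, VoxelGrid
from .signal import EpochedRecording, TaperedSpectra, tapered_fft


@dataclass
class SpatialFilterSet:
    """Unit-gain beamformer weights, one 3 x sensors matrix per voxel."""

    W: np.ndarray                # (V, 3, S)
    grid: VoxelGrid
    band: tuple[float, float]
    alpha: float
    names: list[str]

    def check_unit_gain(self, leadfield: LeadField, atol: float = 1e-8) -> None:
        """W L must be the identity on the retained orientation subspace,
        i.e. an orthogonal projector (the full identity when L has rank 3)."""
        WG = np.einsum("vos,svk->vok", self.W, leadfield.gain)
        sym = np.abs(WG - WG.transpose(0, 2, 1)).max()
        idem = np.abs(WG @ WG - WG).max()
        if max(sym, idem) > atol:
            raise AssertionError(
                f"unit-gain constraint violated: projector error {max(sym, idem):.2e}"
            )


@dataclass
class CoherenceMap:
    """Voxel-wise coherence to the reference, with surrogate threshold."""

    grid: VoxelGrid
    values: np.ndarray           # (V,) in [0, 1]
    orientations: np.ndarray     # (V, 3) dominant dipole orientation per voxel
    band: tuple[float, float]
    threshold: float | None = None
    nulled: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("coherence map values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)
        if self.threshold is not None and not (0 <= self.threshold <= 1):
            raise ValueError("surrogate threshold must lie in [0, 1]")

    @property
    def peak(self) -> int:
        return int(np.argmax(self.values))

    def to_table(self):
        """Plain voxel table (x_mm, y_mm, z_mm, coherence)."""
        import pandas as pd

        mm = 1e3 * self.grid.centers
        return pd.DataFrame(
            {"x_mm": mm[:, 0], "y_mm": mm[:, 1], "z_mm": mm[:, 2],
             "coherence": self.values}
        )


@dataclass
class IdentifiedSource:
    """A local coherence maximum and its above-threshold cluster."""

    name: str
    location: np.ndarray         # (3,) m
    peak_index: int
    member_indices: np.ndarray
    orientation: np.ndarray      # unit vector
    orientation_class: str
    orientation_angle: float     # deg
    peak_coherence: float

    def __post_init__(self) -> None:
        if self.peak_index not in self.member_indices:
            raise ValueError("peak voxel must belong to the member cluster")
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("orientation must be a unit vector")


@dataclass
class SourceSignalSet:
    """Pooled reconstructed time series per identified source."""

    signals: np.ndarray          # (n_sources, epochs, samples)
    sources: list[IdentifiedSource]
    weights: list[np.ndarray]
    sensor_weights: np.ndarray | None = None   # (n_sources, S) pooled filter rows
    channel_names: list[str] | None = None

    @property
    def n_sources(self) -> int:
        return self.signals.shape[0]

    def stacked(self) -> np.ndarray:
        """(n_sources, epochs, samples) view for the connectivity stage."""
        return self.signals


# ---------------------------------------------------------------------------
# filters


def _regularized(C_real: np.ndarray, alpha: float) -> np.ndarray:
    """Re C averaged over the band plus alpha * (mean eigenvalue) * I."""
    S = C_real.shape[0]
    lam = np.trace(C_real) / S
    if alpha < 0:
        raise ValueError("regularization fraction must be non-negative")
    if alpha == 0:
        if np.linalg.cond(C_real) > 1e12:
            raise np.linalg.LinAlgError(
                "band CSD is rank deficient; increase the regularization "
                "fraction alpha above zero"
            )
        return C_real
    return C_real + alpha * lam * np.eye(S)


def dics_filters(
    csd_band: np.ndarray,
    leadfield: LeadField,
    alpha: float = 0.05,
    band: tuple[float, float] = (2.0, 4.0),
) -> SpatialFilterSet:
    """Unit-gain DICS filters W = (L^T C~^-1 L)^-1 L^T C~^-1 for every voxel.

    ``csd_band`` is the brain-channel CSD averaged over the analysis band
    (complex or real); only its real part enters the filter.
    """
    C = _regularized(np.real(csd_band), alpha)
    Ci = np.linalg.inv(C)
    L = leadfield.gain                                   # (S, V, 3)
    CiL = np.einsum("st,tvk->svk", Ci, L)
    A = np.einsum("svk,svl->vkl", L, CiL)                # (V, 3, 3)
    # rank-aware inverse: spherical MEG gains span only the tangential plane,
    # so A can be rank 2; unit gain then holds on the retained subspace
    vals, vecs = np.linalg.eigh(0.5 * (A + A.transpose(0, 2, 1)))
    inv_vals = np.where(vals > 1e-10 * vals[:, -1:], 1.0 / np.maximum(vals, 1e-300), 0.0)
    A_pinv = np.einsum("vij,vj,vkj->vik", vecs, inv_vals, vecs)
    W = np.einsum("vkl,svl->vks", A_pinv, CiL)           # (V, 3, S)
    return SpatialFilterSet(
        W=W, grid=leadfield.grid, band=band, alpha=alpha, names=list(leadfield.names)
    )


def dics_filter(
    csd_band: np.ndarray, leadfield: LeadField, voxel: int, alpha: float = 0.05
) -> np.ndarray:
    """The 3 x sensors spatial filter of a single voxel."""
    fs = dics_filters(csd_band, leadfield, alpha=alpha)
    return fs.W[voxel]


# ---------------------------------------------------------------------------
# coherence maps


def split_reference(ts: TaperedSpectra, reference: str | int):
    """Split tapered spectra into brain coefficients and the reference row."""
    ref = ts.channel_index(reference) if isinstance(reference, str) else int(reference)
    brain = [i for i in range(ts.coef.shape[0]) if i != ref]
    return ts.coef[brain], ts.coef[ref], [ts.names[i] for i in brain]


def _csd_terms(Xb: np.ndarray, Xr: np.ndarray):
    """Band CSD pieces from tapered coefficients: C_bb(f), c_br(f), c_rr(f)."""
    norm = Xb.shape[1] * Xb.shape[2]
    C_bb = np.einsum("iekf,jekf->fij", Xb, Xb.conj()) / norm
    c_br = np.einsum("iekf,ekf->fi", Xb, Xr.conj()) / norm
    c_rr = np.einsum("ekf,ekf->f", Xr, Xr.conj()).real / norm
    return C_bb, c_br, c_rr


def _voxel_coherence(W, C_bb, c_br, c_rr, orientations=None):
    """Band-mean coherence per voxel for orientation-fixed filters.

    The dipole orientation per voxel is the dominant eigenvector of the real
    part of the band-averaged 3x3 source CSD (unless supplied).
    """
    if np.any(c_rr <= 0):
        raise ValueError("reference auto-spectrum vanishes inside the band")
    # per-bin 3x3 source CSD: W C_bb(f) W^H
    T = np.einsum("vos,fst->vfot", W, C_bb)
    P = np.einsum("vfot,vpt->vfop", T, W.conj())         # (V, F, 3, 3)
    if orientations is None:
        Pbar = np.real(P.mean(axis=1))
        Pbar = 0.5 * (Pbar + np.swapaxes(Pbar, 1, 2))
        vals, vecs = np.linalg.eigh(Pbar)
        orientations = vecs[:, :, -1]                    # (V, 3)
    cross = np.einsum("vo,vos,fs->vf", orientations, W, c_br)
    power = np.einsum("vo,vfop,vp->vf", orientations, P, orientations).real
    coh = np.abs(cross) ** 2 / (np.maximum(power, 1e-300) * c_rr[None, :])
    return coh.mean(axis=1), orientations


def coherence_map(
    ts: TaperedSpectra,
    leadfield: LeadField,
    reference: str | int = "EMG",
    alpha: float = 0.05,
    band: tuple[float, float] | None = None,
) -> CoherenceMap:
    """Voxel-wise band coherence between beamformed sources and the reference."""
    Xb, Xr, _ = split_reference(ts, reference)
    C_bb, c_br, c_rr = _csd_terms(Xb, Xr)
    band = band or (float(ts.freqs[0]), float(ts.freqs[-1]))
    filt = dics_filters(C_bb.mean(axis=0), leadfield, alpha=alpha, band=band)
    coh, ori = _voxel_coherence(filt.W, C_bb, c_br, c_rr)
    return CoherenceMap(
        grid=leadfield.grid, values=coh, orientations=ori, band=band
    )


def surrogate_threshold(
    ts: TaperedSpectra,
    leadfield: LeadField,
    reference: str | int = "EMG",
    n_perm: int = 100,
    percentile: float = 99.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo permutation threshold for the coherence-map maximum.

    The reference channel's epochs are shuffled relative to the brain
    channels ``n_perm`` times; the threshold is the requested percentile of
    the per-permutation map maxima.  Filters and orientations depend only on
    the brain CSD and are reused across permutations.
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    if ts.n_epochs < 20:
        raise ValueError("need at least 20 epochs for the surrogate threshold")
    rng = np.random.default_rng(seed)
    Xb, Xr, _ = split_reference(ts, reference)
    C_bb, c_br, c_rr = _csd_terms(Xb, Xr)
    filt = dics_filters(C_bb.mean(axis=0), leadfield, alpha=alpha)
    _, ori = _voxel_coherence(filt.W, C_bb, c_br, c_rr)
    maxima = _permutation_maxima(Xb, Xr, filt.W, ori, c_rr, n_perm, rng)
    return float(np.percentile(maxima, percentile))


def _cluster(grid: VoxelGrid, above: np.ndarray, peak: int) -> np.ndarray:
    """Above-threshold voxels 6-connected to the peak."""
    idx = {tuple(g): i for i, g in enumerate(grid.ijk)}
    seen = {peak}
    frontier = [peak]
    offsets = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    while frontier:
        v = frontier.pop()
        for off in offsets:
            w = idx.get(tuple(grid.ijk[v] + off))
            if w is not None and w not in seen and above[w]:
                seen.add(w)
                frontier.append(w)
    return np.array(sorted(seen), int)


def sequential_source_search(
    ts: TaperedSpectra,
    leadfield: LeadField,
    head: SphericalHeadModel,
    reference: str | int = "EMG",
    max_sources: int = 8,
    n_perm: int = 100,
    percentile: float = 99.0,
    seed: int = 0,
    alpha: float = 0.05,
    orientation_convention: str = "tangential_reference",
    null_mode: str = "neighborhood",
) -> tuple[list[IdentifiedSource], list[CoherenceMap]]:
    """Find coherent sources one by one, nulling each before the next pass.

    Each iteration builds the coherence map and its surrogate threshold on the
    current (projected) data; if the map maximum stays below the threshold the
    search stops.  Otherwise the peak and its 6-connected above-threshold
    cluster are recorded and the data and lead field are projected onto the
    orthogonal complement of the found source's oriented gain subspace,
    treating it as noise.  ``null_mode`` picks that subspace: the peak
    voxel's oriented gain column ("peak"), the oriented gains of the peak and
    its adjacent grid voxels ("neighborhood", default -- robust to the true
    source sitting between grid points), or the whole cluster ("cluster").
    """
    if max_sources < 1:
        raise ValueError("max_sources must be at least one")
    if null_mode not in ("peak", "neighborhood", "cluster"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    rng = np.random.default_rng(seed)
    Xb, Xr, names = split_reference(ts, reference)
    Xb = Xb.copy()
    L = leadfield.gain.copy()
    found: list[IdentifiedSource] = []
    maps: list[CoherenceMap] = []
    merge_radius = 1.6 * leadfield.grid.spacing
    for it in range(max_sources + 4):
        if len(found) >= max_sources:
            break
        C_bb, c_br, c_rr = _csd_terms(Xb, Xr)
        filt = dics_filters(C_bb.mean(axis=0), leadfield_like(leadfield, L), alpha=alpha)
        coh, ori = _voxel_coherence(filt.W, C_bb, c_br, c_rr)
        thr = _threshold_from_spectra(
            Xb, Xr, filt.W, ori, c_rr, n_perm, percentile, rng
        )
        cmap = CoherenceMap(
            grid=leadfield.grid, values=coh, orientations=ori, band=filt.band,
            threshold=thr, nulled=[s.name for s in found],
        )
        maps.append(cmap)
        peak = cmap.peak
        if coh[peak] <= thr:
            break
        members = _cluster(leadfield.grid, coh > thr, peak)
        u = ori[peak]
        # a residual sidelobe of an already-nulled source: suppress it and
        # continue instead of recording a duplicate
        duplicate = any(
            np.linalg.norm(leadfield.grid.centers[peak] - s.location) <= merge_radius
            for s in found
        )
        cls, ang = classify_orientation(u, leadfield.grid.centers[peak], head,
                                        convention=orientation_convention)
        if not duplicate:
            found.append(
                IdentifiedSource(
                    name=f"S{len(found) + 1}",
                    location=leadfield.grid.centers[peak],
                    peak_index=peak,
                    member_indices=members,
                    orientation=u,
                    orientation_class=cls,
                    orientation_angle=ang,
                    peak_coherence=float(coh[peak]),
                )
            )
        if null_mode == "peak":
            null_vox = np.array([peak])
        elif null_mode == "cluster":
            null_vox = members
        else:
            # deep gain patterns are spatially smooth and broad: a full
            # neighborhood null there would swallow the patterns of shallow
            # sources above, so deep peaks are nulled with the peak column only
            depth = np.linalg.norm(leadfield.grid.centers[peak] - head.center_arr)
            if depth < 0.5 * head.brain_radius:
                null_vox = np.array([peak])
            else:
                adj = np.abs(
                    leadfield.grid.ijk - leadfield.grid.ijk[peak]
                ).sum(axis=1) <= 1
                null_vox = np.flatnonzero(adj)
        G = np.einsum("svk,vk->sv", L[:, null_vox, :], ori[null_vox])   # (S, m)
        Q, R = np.linalg.qr(G)
        rank = int((np.abs(np.diag(R)) > 1e-12 * max(np.abs(R).max(), 1e-300)).sum())
        Q = Q[:, :rank]
        if rank == 0:
            break
        Xb -= np.einsum("sr,rekf->sekf", Q, np.einsum("sr,sekf->rekf", Q, Xb))
        L -= np.einsum("sr,rvk->svk", Q, np.einsum("sr,svk->rvk", Q, L))
    return found, maps


def leadfield_like(lf: LeadField, gain: np.ndarray) -> LeadField:
    return LeadField(gain=gain, grid=lf.grid, names=list(lf.names), kinds=lf.kinds,
                     whitening=lf.whitening)


def _permutation_maxima(Xb, Xr, W, ori, c_rr, n_perm, rng) -> np.ndarray:
    """Map maxima under epoch permutation of the reference channel.

    The brain CSD -- hence filters, orientations, and voxel power -- is
    invariant under the permutation, so only the voxel-reference cross term
    is recomputed; all permutations are batched into one matrix product per
    frequency bin.
    """
    S, E, K, F = Xb.shape
    norm = E * K
    WX = np.einsum("vo,vos,sekf->vekf", ori, W, Xb)          # oriented voxel spectra
    power = (np.abs(WX) ** 2).sum(axis=(1, 2)) / norm        # (V, F)
    denom = np.maximum(power, 1e-300) * c_rr[None, :]
    perms = np.stack([rng.permutation(E) for _ in range(n_perm)])
    coh = np.zeros((WX.shape[0], n_perm))
    for f in range(F):
        A = WX[..., f].reshape(-1, E * K)                    # (V, E K)
        B = np.conj(Xr[perms][..., f]).reshape(n_perm, E * K).T
        cross = (A @ B) / norm                               # (V, n_perm)
        coh += np.abs(cross) ** 2 / denom[:, f : f + 1]
    coh /= F
    return coh.max(axis=0)


def _threshold_from_spectra(Xb, Xr, W, ori, c_rr, n_perm, percentile, rng):
    maxima = _permutation_maxima(Xb, Xr, W, ori, c_rr, n_perm, rng)
    return float(np.percentile(maxima, percentile))


# ---------------------------------------------------------------------------
# source-signal reconstruction


def reconstruct_source_signals(
    sources: list[IdentifiedSource],
    epochs: EpochedRecording,
    leadfield: LeadField,
    reference: str | int = "EMG",
    alpha: float = 0.05,
    band: tuple[float, float] = (2.0, 4.0),
    K: int = 7,
) -> SourceSignalSet:
    """Pooled 1-D source signal per identified source.

    Every member voxel of a source is projected through its orientation-fixed
    unit-gain filter (built on the original band CSD); member-voxel signals
    are sign-aligned to the peak voxel and combined with spectral pooling
    weights proportional to the squared voxel-reference coherence, so the
    cluster core dominates and noise-amplified fringe voxels barely enter.
    """
    if not sources:
        return SourceSignalSet(signals=np.zeros((0, epochs.n_epochs, epochs.data.shape[2])),
                               sources=[], weights=[])
    ts = tapered_fft(epochs, band=band, K=K)
    Xb, Xr, names = split_reference(ts, reference)
    C_bb, c_br, c_rr = _csd_terms(Xb, Xr)
    filt = dics_filters(C_bb.mean(axis=0), leadfield, alpha=alpha, band=band)
    _, ori = _voxel_coherence(filt.W, C_bb, c_br, c_rr)
    brain_idx = [epochs.channel_index(nm) for nm in names]
    data = epochs.data[brain_idx]                             # (S, E, T)
    Cbar = C_bb.mean(axis=0)

    coh_all, _ = _voxel_coherence(filt.W, C_bb, c_br, c_rr, orientations=ori)

    signals, weights, rows = [], [], []
    for src in sources:
        members = src.member_indices
        w_rows = np.einsum("vo,vos->vs", ori[members], filt.W[members])   # (m, S)
        # sign alignment relative to the peak voxel
        w_peak = ori[src.peak_index] @ filt.W[src.peak_index]
        cross = w_rows @ Cbar @ w_peak.conj()
        sign = np.where(np.real(cross) >= 0, 1.0, -1.0)
        wgt = coh_all[members] ** 2
        wgt = wgt / wgt.sum() if wgt.sum() > 0 else np.full(len(members), 1 / len(members))
        row = np.einsum("v,vs->s", wgt * sign, w_rows)
        signals.append(np.einsum("s,set->et", row, data))
        weights.append(wgt)
        rows.append(row)
    return SourceSignalSet(
        signals=np.stack(signals), sources=sources, weights=weights,
        sensor_weights=np.stack(rows), channel_names=names,
    )


# ---------------------------------------------------------------------------
# orientation classification


def classify_orientation(
    moment: np.ndarray,
    location: np.ndarray,
    head: SphericalHeadModel,
    convention: str = "tangential_reference",
) -> tuple[str, float]:
    """Classify a dipole orientation as radial or tangential.

    ``tangential_reference`` (default) measures the angle theta in [0, 180]
    deg between the moment and a fixed tangential reference axis at the
    source location; orientations at 60 < theta < 120 deg are labelled
    "radial" and the rest "tangential" (boundaries belong to the tangential
    bins).  ``radial_axis`` measures theta from the local radial direction
    and labels radial when theta < 30 or theta > 150 deg (the same cone).
    """
    q = np.asarray(moment, float)
    n = np.linalg.norm(q)
    if n < 1e-30:
        raise ValueError("zero-length dipole moment")
    q = q / n
    r = np.asarray(location, float) - head.center_arr
    rn = np.linalg.norm(r)
    rhat = r / rn if rn > 1e-12 else np.array([0.0, 0.0, 1.0])
    if convention == "tangential_reference":
        axis = np.cross([0.0, 0.0, 1.0], rhat)
        if np.linalg.norm(axis) < 1e-9:
            axis = np.array([1.0, 0.0, 0.0])
        axis /= np.linalg.norm(axis)
        theta = float(np.degrees(np.arccos(np.clip(q @ axis, -1, 1))))
        cls = "radial" if 60.0 < theta < 120.0 else "tangential"
    elif convention == "radial_axis":
        theta = float(np.degrees(np.arccos(np.clip(q @ rhat, -1, 1))))
        cls = "radial" if theta < 30.0 or theta > 150.0 else "tangential"
    else:
        raise ValueError(f"unknown orientation convention {convention!r}")
    return cls, theta


def classify_angle(theta: float) -> str:
    """Bin an angle (deg) by the radial/tangential convention used here."""
    return "radial" if 60.0 < theta < 120.0 else "tangential"
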