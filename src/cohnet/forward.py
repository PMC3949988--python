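"""Analytic spherical-head forward models for EEG and MEG.

The conductor is a set of concentric spheres (brain, skull, scalp).  MEG
fields are computed with the closed-form expression for a dipole in a
spherically symmetric conductor (the magnetic field outside such a conductor
is independent of the radial conductivity profile, and radial dipoles are
magnetically silent).  EEG potentials use the concentric-shell series
solution, truncated at a configurable harmonic degree, with the average
reference applied across electrodes.

Units: positions in meters, dipole moments in A*m, conductivities in S/m,
magnetometer gains in T, gradiometer gains in T/m, EEG gains in V.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

MU0 = 4e-7 * np.pi

# direction of the C3-analog electrode: left, superior-lateral
_C3_DIRECTION = np.array([-0.71, -0.08, 0.70])


@dataclass(frozen=True)
class SphericalHeadModel:
    """Concentric-sphere conductor: brain < skull < scalp."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii: tuple[float, ...] = (0.08, 0.085, 0.092)
    conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, float)
        c = np.asarray(self.conductivities, float)
        if r.size != c.size:
            raise ValueError("one conductivity per shell is required")
        if np.any(np.diff(r) <= 0):
            raise ValueError(f"shell radii must be strictly increasing, got {self.radii}")
        if np.any(c <= 0):
            raise ValueError(f"conductivities must be positive, got {self.conductivities}")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, float)

    def to_dict(self) -> dict:
        return {
            "coordinate_frame": "head: RAS-like, x right, y anterior, z superior, origin at sphere center",
            "center_mm": (1e3 * self.center_arr).tolist(),
            "radii_mm": (1e3 * np.asarray(self.radii)).tolist(),
            "conductivities_S_per_m": list(self.conductivities),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SphericalHeadModel":
        return cls(
            center=tuple(np.asarray(d["center_mm"], float) / 1e3),
            radii=tuple(np.asarray(d["radii_mm"], float) / 1e3),
            conductivities=tuple(d["conductivities_S_per_m"]),
        )


@dataclass
class Dipole:
    """Current dipole strictly inside the brain shell."""

    location: np.ndarray
    moment: np.ndarray
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, float)
        self.moment = np.asarray(self.moment, float)


@dataclass
class SensorArray:
    """EEG electrodes plus MEG magnetometers and planar gradiometers.

    ``orientations`` hold MEG coil normals (radial); ``baseline_dirs`` hold the
    tangential two-point difference direction for gradiometer channels.
    """

    positions: np.ndarray          # (n, 3) m
    orientations: np.ndarray       # (n, 3) unit coil normals (zeros for EEG)
    kinds: np.ndarray              # (n,) str: eeg | mag | grad
    names: list[str]
    c3_name: str | None = None
    baseline_dirs: np.ndarray | None = None   # (n, 3), zeros except grad
    baseline_m: float = 0.0168

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, float))
        self.kinds = np.asarray(self.kinds, dtype=object)
        if len(set(self.names)) != len(self.names):
            raise ValueError("sensor names must be unique")
        if self.baseline_dirs is None:
            self.baseline_dirs = np.zeros_like(self.positions)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def mask(self, kinds) -> np.ndarray:
        kinds = {kinds} if isinstance(kinds, str) else set(kinds)
        return np.array([k in kinds for k in self.kinds])

    def subset(self, idx) -> "SensorArray":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        names = [self.names[i] for i in idx]
        return SensorArray(
            positions=self.positions[idx],
            orientations=self.orientations[idx],
            kinds=self.kinds[idx],
            names=names,
            c3_name=self.c3_name if self.c3_name in names else None,
            baseline_dirs=self.baseline_dirs[idx],
            baseline_m=self.baseline_m,
        )

    def to_dict(self) -> dict:
        return {
            "coordinate_frame": "head: RAS-like, x right, y anterior, z superior, origin at sphere center",
            "positions_mm": (1e3 * self.positions).tolist(),
            "orientations": self.orientations.tolist(),
            "kinds": [str(k) for k in self.kinds],
            "names": list(self.names),
            "c3_name": self.c3_name,
            "baseline_dirs": self.baseline_dirs.tolist(),
            "baseline_mm": 1e3 * self.baseline_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorArray":
        return cls(
            positions=np.asarray(d["positions_mm"], float) / 1e3,
            orientations=np.asarray(d["orientations"], float),
            kinds=np.asarray(d["kinds"], dtype=object),
            names=list(d["names"]),
            c3_name=d.get("c3_name"),
            baseline_dirs=np.asarray(d["baseline_dirs"], float),
            baseline_m=d["baseline_mm"] / 1e3,
        )


@dataclass
class VoxelGrid:
    """Regular grid of candidate source locations inside the brain shell."""

    centers: np.ndarray        # (V, 3) m
    spacing: float             # m
    ijk: np.ndarray            # (V, 3) integer grid indices (for connectivity)
    origin: np.ndarray         # corner of the bounding box (m)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")

    def __len__(self) -> int:
        return self.centers.shape[0]

    def nearest(self, location) -> int:
        d = np.linalg.norm(self.centers - np.asarray(location, float), axis=1)
        return int(np.argmin(d))


def make_voxel_grid(
    head: SphericalHeadModel,
    spacing: float = 0.005,
    bbox: np.ndarray | None = None,
    margin: float = 0.003,
) -> VoxelGrid:
    """Regular grid of voxel centers strictly inside the brain shell.

    ``bbox`` restricts the grid to ``[[xmin, xmax], [ymin, ymax], [zmin, zmax]]``
    (meters, head frame), e.g. for a reduced search volume.
    """
    rb = head.brain_radius - margin
    c = head.center_arr
    if bbox is None:
        bbox = np.array([[-rb, rb]] * 3) + c[:, None]
    bbox = np.asarray(bbox, float)
    axes = [np.arange(bbox[k, 0], bbox[k, 1] + spacing / 2, spacing) for k in range(3)]
    ii, jj, kk = np.meshgrid(*(np.arange(len(a)) for a in axes), indexing="ij")
    pts = np.stack(
        [axes[0][ii.ravel()], axes[1][jj.ravel()], axes[2][kk.ravel()]], axis=1
    )
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    inside = np.linalg.norm(pts - c, axis=1) <= rb
    if not inside.any():
        raise ValueError("voxel grid is empty: bounding box outside the brain shell")
    origin = np.array([a[0] for a in axes])
    return VoxelGrid(centers=pts[inside], spacing=spacing, ijk=ijk[inside], origin=origin)


@dataclass
class LeadField:
    """Gain tensor: sensors x voxels x 3 dipole orientations."""

    gain: np.ndarray            # (S, V, 3)
    grid: VoxelGrid | None
    names: list[str]
    kinds: np.ndarray
    whitening: np.ndarray | None = None   # per-channel noise amplitudes used

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite entries")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[1]


# ---------------------------------------------------------------------------
# sensor fixtures


def _fibonacci_cap(n: int, z_min: float, rng: np.random.Generator) -> np.ndarray:
    """n quasi-uniform unit vectors on the spherical cap z >= z_min."""
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i + rng.uniform(0, 2 * np.pi)   # seeded azimuthal offset
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def _tangential_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the tangent plane of each unit normal."""
    ref = np.where(np.abs(normal[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    t1 = np.cross(ref, normal)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normal, t1)
    return t1, t2


def build_sensor_fixture(
    n_eeg: int,
    n_mag: int,
    n_grad: int,
    head: SphericalHeadModel | None = None,
    seed: int = 0,
    helmet_offset: float = 0.02,
    baseline: float = 0.0168,
) -> SensorArray:
    """Quasi-uniform EEG electrodes on the scalp and MEG sensors on a helmet.

    EEG electrodes cover the scalp cap z/R > -0.15 at the scalp radius; MEG
    sensors sit on a helmet surface ``helmet_offset`` above the scalp with
    radial coil normals.  Gradiometers get a seeded random tangential
    two-point baseline.  The EEG electrode nearest to the left
    superior-lateral direction is flagged as the C3-analog.  Deterministic for
    a given seed.
    """
    if n_eeg < 0 or n_mag < 0 or n_grad < 0:
        raise ValueError("channel counts must be non-negative")
    if n_eeg + n_mag + n_grad == 0:
        raise ValueError("at least one channel is required")
    head = head or SphericalHeadModel()
    rng = np.random.default_rng(seed)
    c = head.center_arr

    positions, orientations, kinds, names, baselines = [], [], [], [], []
    c3_name = None
    if n_eeg:
        u = _fibonacci_cap(n_eeg, -0.15, rng)
        pos = c + head.scalp_radius * u
        positions.append(pos)
        orientations.append(np.zeros((n_eeg, 3)))
        baselines.append(np.zeros((n_eeg, 3)))
        kinds += ["eeg"] * n_eeg
        names += [f"EEG{i:03d}" for i in range(n_eeg)]
        c3_name = names[int(np.argmax(u @ (_C3_DIRECTION / np.linalg.norm(_C3_DIRECTION))))]
    if n_mag:
        u = _fibonacci_cap(n_mag, -0.10, rng)
        positions.append(c + (head.scalp_radius + helmet_offset) * u)
        orientations.append(u)
        baselines.append(np.zeros((n_mag, 3)))
        kinds += ["mag"] * n_mag
        names += [f"MAG{i:03d}" for i in range(n_mag)]
    if n_grad:
        u = _fibonacci_cap(n_grad, -0.10, rng)
        positions.append(c + (head.scalp_radius + helmet_offset) * u)
        orientations.append(u)
        t1, t2 = _tangential_basis(u)
        ang = rng.uniform(0, 2 * np.pi, n_grad)
        baselines.append(np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2)
        kinds += ["grad"] * n_grad
        names += [f"GRAD{i:03d}" for i in range(n_grad)]

    return SensorArray(
        positions=np.concatenate(positions),
        orientations=np.concatenate(orientations),
        kinds=np.asarray(kinds, dtype=object),
        names=names,
        c3_name=c3_name,
        baseline_dirs=np.concatenate(baselines),
        baseline_m=baseline,
    )


# ---------------------------------------------------------------------------
# MEG forward model


def _check_sources(locations: np.ndarray, head: SphericalHeadModel) -> np.ndarray:
    locations = np.atleast_2d(np.asarray(locations, float))
    r = np.linalg.norm(locations - head.center_arr, axis=1)
    if np.any(r >= head.brain_radius):
        raise ValueError("all dipoles must lie strictly inside the brain shell")
    return locations


def _source_locations(sources) -> np.ndarray:
    if isinstance(sources, VoxelGrid):
        return sources.centers
    if isinstance(sources, Dipole):
        return np.atleast_2d(sources.location)
    if isinstance(sources, (list, tuple)) and sources and isinstance(sources[0], Dipole):
        return np.stack([d.location for d in sources])
    return np.atleast_2d(np.asarray(sources, float))


def _sphere_field_kernel(points: np.ndarray, locations: np.ndarray) -> np.ndarray:
    """Per (point, source) 3x3 matrix M with B = M @ q for a spherical conductor.

    Closed-form field of a dipole in a spherically symmetric volume conductor
    centered at the origin; independent of the conductivity profile.
    """
    r = points[:, None, :]                  # (P, 1, 3)
    r0 = locations[None, :, :]              # (1, V, 3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)      # (P, V)
    R = np.linalg.norm(points, axis=-1)[:, None]
    rr0 = np.sum(r * r0, axis=-1)
    F = a * (R * a + R**2 - rr0)
    ar = np.sum(a_vec * r, axis=-1)
    gF = (
        (a**2 / R + ar / a + 2 * a + 2 * R)[..., None] * r
        - (a + 2 * R + ar / a)[..., None] * r0
    )
    # B = mu0/(4 pi F^2) * (F (q x r0) - ((q x r0) . r) gradF)
    #   = mu0/(4 pi F^2) * (F I - outer(gF, r)) @ (-[r0]x) @ q
    cross = np.zeros(r0.shape[:2] + (3, 3))
    x0, y0, z0 = locations[:, 0], locations[:, 1], locations[:, 2]
    # matrix of q -> q x r0
    cross[0, :, 0, 1] = z0
    cross[0, :, 0, 2] = -y0
    cross[0, :, 1, 0] = -z0
    cross[0, :, 1, 2] = x0
    cross[0, :, 2, 0] = y0
    cross[0, :, 2, 1] = -x0
    M = F[..., None, None] * np.eye(3) - gF[..., :, None] * r[..., None, :]
    M = M @ cross
    return MU0 / (4 * np.pi) * M / (F**2)[..., None, None]


def meg_leadfield(sources, head: SphericalHeadModel, sensors: SensorArray) -> LeadField:
    """MEG gains (magnetometers in T, planar gradiometers in T/m).

    Radial dipoles produce exactly zero field; conductivities never enter.
    Raises for dipoles at the sphere center, where the radial direction is
    undefined and the source is magnetically silent.
    """
    grid = sources if isinstance(sources, VoxelGrid) else None
    locations = _check_sources(_source_locations(sources), head)
    c = head.center_arr
    rel = locations - c
    if np.any(np.linalg.norm(rel, axis=1) < 1e-4):
        raise ValueError(
            "dipole at the sphere center: radial direction undefined and the "
            "source is magnetically silent"
        )
    meg_mask = sensors.mask({"mag", "grad"})
    sub = sensors.subset(meg_mask)
    gains = np.zeros((len(sub), locations.shape[0], 3))
    is_mag = sub.kinds == "mag"
    if is_mag.any():
        M = _sphere_field_kernel(sub.positions[is_mag] - c, rel)
        gains[is_mag] = np.einsum("pvik,pi->pvk", M, sub.orientations[is_mag])
    is_grad = sub.kinds == "grad"
    if is_grad.any():
        half = 0.5 * sub.baseline_m * sub.baseline_dirs[is_grad]
        p = sub.positions[is_grad] - c
        Mp = _sphere_field_kernel(p + half, rel)
        Mm = _sphere_field_kernel(p - half, rel)
        dB = np.einsum("pvik,pi->pvk", Mp - Mm, sub.orientations[is_grad])
        gains[is_grad] = dB / sub.baseline_m
    return LeadField(gain=gains, grid=grid, names=sub.names, kinds=sub.kinds)


# ---------------------------------------------------------------------------
# EEG forward model


def shell_factors(head: SphericalHeadModel, n_terms: int = 60) -> np.ndarray:
    """Per-degree transfer factors f_n of the concentric-shell conductor.

    The scalp-surface potential of a dipole at eccentricity x = b/R is
    V = 1/(4 pi sigma_1 R^2) * sum_n f_n x^(n-1)
        [ n q_r P_n(c) + P_n'(c) (q_t . r_hat) ],
    where c is the cosine between sensor and dipole directions.  For a
    homogeneous sphere f_n = (2n+1)/n exactly.
    """
    radii = np.asarray(head.radii, float) / head.scalp_radius
    cond = np.asarray(head.conductivities, float)
    K = radii.size
    n_all = np.arange(1, n_terms + 1, dtype=float)
    if K == 1:   # homogeneous sphere: closed form
        return (2 * n_all + 1) / n_all
    f = np.empty(n_terms)
    for n in range(1, n_terms + 1):
        # unknowns: A_1, then (A_j, B_j) for j = 2..K; source term B_1 = 1
        m = 2 * K - 1
        A = np.zeros((m, m))
        b = np.zeros(m)

        def a_col(j):   # column index of A_j
            return 0 if j == 0 else 2 * j - 1

        def b_col(j):   # column index of B_j (j >= 1)
            return 2 * j

        for j in range(K - 1):   # interface between shells j and j+1 at radii[j]
            rho = radii[j]
            row_v, row_f = 2 * j, 2 * j + 1
            # potential continuity
            A[row_v, a_col(j)] += rho**n
            if j > 0:
                A[row_v, b_col(j)] += rho ** -(n + 1)
            else:
                b[row_v] -= rho ** -(n + 1)
            A[row_v, a_col(j + 1)] -= rho**n
            A[row_v, b_col(j + 1)] -= rho ** -(n + 1)
            # radial current continuity
            A[row_f, a_col(j)] += cond[j] * n * rho ** (n - 1)
            if j > 0:
                A[row_f, b_col(j)] -= cond[j] * (n + 1) * rho ** -(n + 2)
            else:
                b[row_f] += cond[j] * (n + 1) * rho ** -(n + 2)
            A[row_f, a_col(j + 1)] -= cond[j + 1] * n * rho ** (n - 1)
            A[row_f, b_col(j + 1)] += cond[j + 1] * (n + 1) * rho ** -(n + 2)
        # insulating outer boundary at rho = 1
        A[m - 1, a_col(K - 1)] = n
        A[m - 1, b_col(K - 1)] = -(n + 1)
        sol = np.linalg.solve(A, b)
        f[n - 1] = sol[a_col(K - 1)] + sol[b_col(K - 1)]
    return f


def eeg_leadfield(
    sources,
    head: SphericalHeadModel,
    sensors: SensorArray,
    n_terms: int = 60,
) -> LeadField:
    """Average-referenced EEG gains (V per unit dipole moment).

    Concentric-shell series truncated at ``n_terms`` harmonic degrees.
    """
    grid = sources if isinstance(sources, VoxelGrid) else None
    locations = _check_sources(_source_locations(sources), head)
    sub = sensors.subset(sensors.mask("eeg"))
    if len(sub) == 0:
        raise ValueError("no EEG channels in the sensor array")
    c = head.center_arr
    R = head.scalp_radius
    rhat = (sub.positions - c) / R                     # (S, 3) unit, on scalp
    rel = locations - c
    bnorm = np.linalg.norm(rel, axis=1)                # (V,)
    bhat = np.where(bnorm[:, None] > 1e-12, rel / np.maximum(bnorm, 1e-12)[:, None], [0, 0, 1.0])
    x = bnorm / R
    cosg = bhat @ rhat.T                               # (V, S)

    f = shell_factors(head, n_terms)
    # accumulate sum_n f_n x^(n-1) * {n P_n(c)} and {P_n'(c)}
    A = np.zeros_like(cosg)
    B = np.zeros_like(cosg)
    P_nm1 = np.ones_like(cosg)        # P_0
    P_n = cosg.copy()                 # P_1
    dP_nm1 = np.zeros_like(cosg)      # P_0'
    dP_n = np.ones_like(cosg)         # P_1'
    xp = np.ones_like(x)              # x^(n-1)
    for n in range(1, n_terms + 1):
        w = f[n - 1] * xp[:, None]
        A += w * n * P_n
        B += w * dP_n
        xp = xp * x
        if n < n_terms:
            P_np1 = ((2 * n + 1) * cosg * P_n - n * P_nm1) / (n + 1)
            dP_np1 = dP_nm1 + (2 * n + 1) * P_n
            P_nm1, P_n = P_n, P_np1
            dP_nm1, dP_n = dP_n, dP_np1

    pref = 1.0 / (4 * np.pi * head.conductivities[0] * R**2)
    gains = np.empty((len(sub), locations.shape[0], 3))
    for k in range(3):
        # q_r = bhat_k ; (q_t . rhat) = rhat_k - bhat_k * cos(gamma)
        term = bhat[:, k : k + 1] * A + (rhat[None, :, k] - bhat[:, k : k + 1] * cosg) * B
        gains[:, :, k] = pref * term.T
    gains -= gains.mean(axis=0, keepdims=True)         # average reference
    return LeadField(gain=gains, grid=grid, names=sub.names, kinds=sub.kinds)


def build_leadfield(
    sources,
    head: SphericalHeadModel,
    sensors: SensorArray,
    kinds=("eeg", "mag", "grad"),
    n_terms: int = 60,
) -> LeadField:
    """Combined lead field, rows in sensor-array order restricted to ``kinds``."""
    kinds = {kinds} if isinstance(kinds, str) else set(kinds)
    grid = sources if isinstance(sources, VoxelGrid) else None
    locations = _source_locations(sources)
    parts: dict[str, tuple[np.ndarray, list[str]]] = {}
    if "eeg" in kinds and sensors.mask("eeg").any():
        lf = eeg_leadfield(locations, head, sensors, n_terms=n_terms)
        parts.update({nm: lf.gain[i] for i, nm in enumerate(lf.names)})
    if kinds & {"mag", "grad"} and sensors.mask({"mag", "grad"}).any():
        lf = meg_leadfield(locations, head, sensors)
        parts.update(
            {nm: lf.gain[i] for i, nm in enumerate(lf.names) if lf.kinds[i] in kinds}
        )
    order = [i for i, nm in enumerate(sensors.names) if nm in parts]
    if not order:
        raise ValueError(f"no channels of kinds {sorted(kinds)} in the sensor array")
    gain = np.stack([parts[sensors.names[i]] for i in order])
    return LeadField(
        gain=gain,
        grid=grid,
        names=[sensors.names[i] for i in order],
        kinds=sensors.kinds[order],
    )


def whiten_and_combine(leadfields, noise_amplitudes) -> LeadField:
    """Divide each channel row by its noise amplitude and stack modalities.

    ``noise_amplitudes`` maps channel name -> band noise amplitude (> 0),
    or is an array aligned with the concatenated channel order.  The same
    whitening must be applied to the sensor data before beamforming.
    """
    if isinstance(leadfields, LeadField):
        leadfields = [leadfields]
    names = [nm for lf in leadfields for nm in lf.names]
    kinds = np.concatenate([lf.kinds for lf in leadfields])
    gain = np.concatenate([lf.gain for lf in leadfields], axis=0)
    if isinstance(noise_amplitudes, dict):
        missing = [nm for nm in names if nm not in noise_amplitudes]
        if missing:
            raise ValueError(f"missing noise amplitudes for channels {missing[:5]}")
        amps = np.array([noise_amplitudes[nm] for nm in names], float)
    else:
        amps = np.asarray(noise_amplitudes, float)
        if amps.shape != (len(names),):
            raise ValueError(
                f"expected {len(names)} noise amplitudes, got shape {amps.shape}"
            )
    if np.any(amps <= 0):
        raise ValueError("noise amplitudes must be positive")
    return LeadField(
        gain=gain / amps[:, None, None],
        grid=leadfields[0].grid,
        names=names,
        kinds=kinds,
        whitening=amps,
    )
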