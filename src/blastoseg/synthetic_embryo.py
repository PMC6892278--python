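"""Synthetic 3D embryo volumes with exact ground truth.

Blastomeres are modelled as Voronoi regions of repulsion-relaxed seed
points inside a spherical embryo: crude biology, but exactly what a
segmentation/shape pipeline needs — known boundaries, known volumes, known
moments.  Channels emulate the statistical structure of light-sheet data:

* membrane — a Gaussian-profile bright ridge along every inter-cell and
  cell–medium boundary over a uniform background,
* nuclei — Gaussian blobs at cell centroids,
* polarity — apical caps painted on the contact-free surface patches of
  outer cells, scaled per cell by an inheritance fraction.

Optional volume-preserving z-compression (the xy plane expands to
compensate) produces ellipsoidal embryos of known aspect ratio, and
Gaussian (plus optional Poisson) noise is added last.  Identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imageio import CentroidTable, VoxelGrid3D

import pandas as pd


class PackingError(ValueError):
    """Requested geometry does not fit the volume or the cell count."""


@dataclass(frozen=True)
class SyntheticEmbryoSpec:
    """Study conditions for one synthetic embryo.

    Intensities are arbitrary units; the 10:1 membrane-peak:background
    contrast and 5%-of-peak noise emulate well-exposed light-sheet data.
    """

    n_cells: int = 16
    embryo_radius_um: float = 25.0
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    margin_um: float = 6.0
    membrane_thickness_um: float = 1.0   # Gaussian sigma of the ridge profile
    membrane_peak: float = 100.0
    background: float = 10.0
    nucleus_radius_um: float = 3.0
    nucleus_peak: float = 150.0
    cap_half_angle_deg: float = 50.0
    cap_intensity: float = 100.0
    inheritance_fractions: dict[int, float] | None = None  # cell_id -> [0,1]
    compression_factor: float = 1.0       # resulting embryo aspect ratio
    noise_sigma: float = 5.0
    poisson: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.compression_factor < 1:
            raise ValueError("compression_factor must be >= 1")
        per_cell = (4.0 / 3.0) * np.pi * self.embryo_radius_um**3 / self.n_cells
        if per_cell < 3.0**3:
            raise PackingError(
                f"{self.n_cells} cells in a {self.embryo_radius_um} μm embryo leaves "
                f"{per_cell:.0f} μm³ per cell; below the 27 μm³ floor"
            )


@dataclass
class GroundTruth:
    labels: VoxelGrid3D                  # 0 background, 1..N cells
    embryo_mask: np.ndarray
    centroids: dict[int, np.ndarray]     # cell_id -> (z, y, x) μm
    volumes: dict[int, float]            # μm³ (voxel count × voxel volume)
    outer_cells: set[int]
    inheritance_fractions: dict[int, float] = field(default_factory=dict)
    embryo_aspect_ratio: float = 1.0
    cavity_mask: np.ndarray | None = None
    cavity_volume_um3: float = 0.0
    theta_true_deg: float | None = None
    e_short_true: np.ndarray | None = None
    division_axis_true: np.ndarray | None = None
    ratio_true: float | None = None

    def centroid_table(self, frame: int = 0) -> CentroidTable:
        rows = [
            {
                "cell_id": cid,
                "frame": frame,
                "z_um": c[0],
                "y_um": c[1],
                "x_um": c[2],
                "parent_id": pd.NA,
            }
            for cid, c in sorted(self.centroids.items())
        ]
        return CentroidTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# geometry helpers


def _compression_scales(factor: float) -> tuple[float, float]:
    """(c_z, c_xy): z contracts by 1/c_z, xy expands by c_xy; volume kept,
    resulting aspect ratio = c_z·c_xy = factor."""
    return factor ** (2.0 / 3.0), factor ** (1.0 / 3.0)


def _derive_shape(spec: SyntheticEmbryoSpec) -> tuple[int, int, int]:
    c_z, c_xy = _compression_scales(spec.compression_factor)
    half = np.array(
        [
            spec.embryo_radius_um / c_z + spec.margin_um,
            spec.embryo_radius_um * c_xy + spec.margin_um,
            spec.embryo_radius_um * c_xy + spec.margin_um,
        ]
    )
    return tuple(int(np.ceil(2 * h / s)) for h, s in zip(half, spec.spacing))


def _relax_seeds(
    rng, n: int, r_lo: float, r_hi: float, iters: int = 120, forbidden=None
) -> np.ndarray:
    """Repulsion-relaxed points in the spherical shell [r_lo, r_hi].

    `forbidden` is an optional list of (center, radius) spheres the seeds are
    pushed out of after every relaxation step.
    """
    if n == 1 and not forbidden:
        return np.zeros((1, 3))
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    radii = (r_lo + (r_hi - r_lo) * rng.uniform(size=n)) if r_hi > r_lo else np.full(n, r_hi)
    pts *= radii[:, None]
    target = 2.0 * r_hi / n ** (1.0 / 3.0)
    for _ in range(iters):
        d = pts[:, None, :] - pts[None, :, :]
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        push = np.where(dist < target, (target - dist) / target, 0.0)
        step = (d / dist[..., None] * push[..., None]).sum(axis=1) * 0.2 * target
        pts = pts + step
        r = np.linalg.norm(pts, axis=1)
        pts = np.where(r[:, None] > r_hi, pts / r[:, None] * r_hi, pts)
        if r_lo > 0:
            r = np.linalg.norm(pts, axis=1)
            low = r < max(r_lo, 1e-9)
            if low.any():
                safe = np.where(r[low, None] > 1e-9, pts[low] / r[low, None], [[1.0, 0, 0]])
                pts[low] = safe * r_lo
        for c, rad in forbidden or []:
            d = pts - np.asarray(c)
            dist = np.linalg.norm(d, axis=1)
            inside_sph = dist < rad
            if inside_sph.any():
                dirs = np.where(
                    dist[inside_sph, None] > 1e-9,
                    d[inside_sph] / dist[inside_sph, None],
                    [[1.0, 0, 0]],
                )
                pts[inside_sph] = np.asarray(c) + dirs * rad
    return pts


def _uncompressed_coords(shape, spacing, factor: float):
    """Physical voxel-center offsets from the volume center, mapped back to
    the uncompressed frame (open grids for broadcasting)."""
    c_z, c_xy = _compression_scales(factor)
    axes = []
    for ax, (n, s, scale) in enumerate(
        zip(shape, spacing, (c_z, 1.0 / c_xy, 1.0 / c_xy))
    ):
        q = (np.arange(n) + 0.5) * s - n * s / 2.0
        u = q * scale
        shp = [1, 1, 1]
        shp[ax] = n
        axes.append(u.reshape(shp))
    return axes


def _boundary_mask(regions: np.ndarray) -> np.ndarray:
    """Voxels whose region id differs from any face neighbour."""
    b = np.zeros(regions.shape, dtype=bool)
    for ax in range(3):
        d = np.diff(regions, axis=ax) != 0
        pad_lo = [(0, 0)] * 3
        pad_lo[ax] = (1, 0)
        pad_hi = [(0, 0)] * 3
        pad_hi[ax] = (0, 1)
        b |= np.pad(d, pad_lo)
        b |= np.pad(d, pad_hi)
    return b


def _ridge_image(boundary: np.ndarray, spacing, sigma_um: float, peak: float, bg: float):
    d = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    return bg + peak * np.exp(-(d**2) / (2.0 * sigma_um**2))


def _sheet_paint_scale(sigma_um: float, spacing) -> float:
    """Compensation so a one-voxel-thick painted sheet blurred with σ keeps
    roughly its painted peak at the sheet mid-plane."""
    h = min(spacing)
    return max(1.0, sigma_um * np.sqrt(2.0 * np.pi) / h)


def _apply_noise(img: np.ndarray, spec: SyntheticEmbryoSpec, rng) -> np.ndarray:
    out = img
    if spec.poisson:
        out = rng.poisson(np.maximum(out, 0)).astype(float)
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# generators


def generate_embryo(
    spec: SyntheticEmbryoSpec,
) -> tuple[VoxelGrid3D, VoxelGrid3D, VoxelGrid3D, GroundTruth]:
    """(membrane, nuclear, polarity, ground truth) for one embryo."""
    return _generate(spec, cavity_radii_um=[], cavity_centers_um=[])


def generate_blastocyst(
    spec: SyntheticEmbryoSpec,
    cavity_radius_um: float | list[float],
    cavity_centers_um: list[tuple[float, float, float]] | None = None,
) -> tuple[VoxelGrid3D, VoxelGrid3D, VoxelGrid3D, GroundTruth]:
    """Embryo with one or more signal-free cavities.

    By default a single cavity sits at the embryo center; `cavity_centers_um`
    gives offsets from the center (uncompressed frame, μm) for each radius.
    """
    radii = np.atleast_1d(np.asarray(cavity_radius_um, dtype=float))
    if np.any(radii < 0):
        raise ValueError("cavity radius must be >= 0")
    if cavity_centers_um is None:
        cavity_centers_um = [(0.0, 0.0, 0.0)] * len(radii)
    if len(cavity_centers_um) != len(radii):
        raise ValueError("one center per cavity radius required")
    for r, c in zip(radii, cavity_centers_um):
        if r > 0 and np.linalg.norm(c) + r > spec.embryo_radius_um - 6.0:
            raise PackingError(
                f"cavity (r={r}, center offset {c}) leaves no room for a cell "
                f"shell inside a {spec.embryo_radius_um} μm embryo"
            )
    return _generate(
        spec,
        cavity_radii_um=[float(r) for r in radii if r > 0],
        cavity_centers_um=[c for r, c in zip(radii, cavity_centers_um) if r > 0],
    )


def _generate(
    spec: SyntheticEmbryoSpec,
    cavity_radii_um: list[float],
    cavity_centers_um: list[tuple[float, float, float]],
):
    rng = np.random.default_rng(spec.rng_seed)
    shape = _derive_shape(spec)
    R = spec.embryo_radius_um
    uz, uy, ux = _uncompressed_coords(shape, spec.spacing, spec.compression_factor)
    r2 = uz**2 + uy**2 + ux**2
    inside = r2 <= R**2

    cavity_mask = None
    if cavity_radii_um:
        cavity_mask = np.zeros(shape, dtype=bool)
        for r_c, c_c in zip(cavity_radii_um, cavity_centers_um):
            cavity_mask |= (
                (uz - c_c[0]) ** 2 + (uy - c_c[1]) ** 2 + (ux - c_c[2]) ** 2
            ) <= r_c**2
        # seeds anywhere in the embryo, pushed out of every cavity + margin
        forb = [
            (np.asarray(c, float), r + 3.0)
            for r, c in zip(cavity_radii_um, cavity_centers_um)
        ]
        seeds = _relax_seeds(rng, spec.n_cells, 0.0, 0.85 * R, forbidden=forb)
    else:
        seeds = _relax_seeds(rng, spec.n_cells, 0.0, 0.72 * R)

    # regions: 0 background, 1..N cells, N+1 cavity
    best = np.full(shape, np.inf)
    regions = np.zeros(shape, dtype=np.uint16)
    for k, s in enumerate(seeds, start=1):
        d2 = (uz - s[0]) ** 2 + (uy - s[1]) ** 2 + (ux - s[2]) ** 2
        closer = d2 < best
        best = np.where(closer, d2, best)
        regions[closer] = k
    regions[~inside] = 0
    if cavity_mask is not None:
        regions[cavity_mask] = spec.n_cells + 1

    boundary = _boundary_mask(regions)
    membrane = _ridge_image(
        boundary, spec.spacing, spec.membrane_thickness_um, spec.membrane_peak, spec.background
    )

    labels = regions.copy()
    labels[labels == spec.n_cells + 1] = 0  # cavity is not a cell label

    centroids: dict[int, np.ndarray] = {}
    volumes: dict[int, float] = {}
    vv = float(np.prod(spec.spacing))
    for k in range(1, spec.n_cells + 1):
        idx = np.argwhere(labels == k)
        if idx.size == 0:
            raise PackingError(f"cell {k} rasterized to zero voxels; embryo too crowded")
        centroids[k] = (idx.mean(axis=0) + 0.5) * np.asarray(spec.spacing)
        volumes[k] = idx.shape[0] * vv

    nuclear = np.full(shape, spec.background, dtype=float)
    sig_n = spec.nucleus_radius_um / 2.0
    qz = (np.arange(shape[0]) + 0.5) * spec.spacing[0]
    qy = (np.arange(shape[1]) + 0.5) * spec.spacing[1]
    qx = (np.arange(shape[2]) + 0.5) * spec.spacing[2]
    for k, c in centroids.items():
        d2 = (
            (qz[:, None, None] - c[0]) ** 2
            + (qy[None, :, None] - c[1]) ** 2
            + (qx[None, None, :] - c[2]) ** 2
        )
        nuclear += spec.nucleus_peak * np.exp(-d2 / (2.0 * sig_n**2))

    # outer cells and apical caps on their contact-free surface patches
    bg_adjacent = ndimage.binary_dilation(
        regions == 0, ndimage.generate_binary_structure(3, 1)
    )
    outer_cells = {
        int(k) for k in range(1, spec.n_cells + 1) if (bg_adjacent & (labels == k)).any()
    }
    fractions = dict(spec.inheritance_fractions or {})
    for k in outer_cells:
        fractions.setdefault(k, 1.0)

    polarity_paint = np.zeros(shape, dtype=float)
    center_um = np.array([n * s / 2.0 for n, s in zip(shape, spec.spacing)])
    cos_cap = np.cos(np.radians(spec.cap_half_angle_deg))
    vz = qz[:, None, None] - center_um[0]
    vy = qy[None, :, None] - center_um[1]
    vx = qx[None, None, :] - center_um[2]
    vnorm = np.sqrt(vz**2 + vy**2 + vx**2) + 1e-12
    paint_scale = _sheet_paint_scale(spec.membrane_thickness_um, spec.spacing)
    for k in sorted(outer_cells):
        frac = float(np.clip(fractions.get(k, 1.0), 0.0, 1.0))
        if frac <= 0:
            continue
        radial = centroids[k] - center_um
        rn = np.linalg.norm(radial)
        if rn < 1e-9:
            continue
        radial = radial / rn
        cosang = (vz * radial[0] + vy * radial[1] + vx * radial[2]) / vnorm
        cap = (labels == k) & bg_adjacent & (cosang >= cos_cap)
        polarity_paint[cap] = spec.cap_intensity * frac * paint_scale
    sig_vox = [spec.membrane_thickness_um / s for s in spec.spacing]
    polarity = spec.background + ndimage.gaussian_filter(polarity_paint, sig_vox, mode="nearest")

    membrane = _apply_noise(membrane, spec, rng)
    nuclear = _apply_noise(nuclear, spec, rng)
    polarity = _apply_noise(polarity, spec, rng)

    # the embryo mask is the physical hull: cells plus any cavity interior
    truth = GroundTruth(
        labels=VoxelGrid3D(labels, spec.spacing),
        embryo_mask=inside,
        centroids=centroids,
        volumes=volumes,
        outer_cells=outer_cells,
        inheritance_fractions=fractions,
        embryo_aspect_ratio=float(spec.compression_factor),
        cavity_mask=cavity_mask,
        cavity_volume_um3=float(cavity_mask.sum()) * vv if cavity_mask is not None else 0.0,
    )
    return (
        VoxelGrid3D(membrane, spec.spacing),
        VoxelGrid3D(nuclear, spec.spacing),
        VoxelGrid3D(polarity, spec.spacing),
        truth,
    )


def generate_division(
    spec: SyntheticEmbryoSpec,
    theta_true: float,
    ratio_true: float,
    *,
    mother_axes_um: tuple[float, float, float] | None = None,
) -> tuple[list[dict[str, VoxelGrid3D]], list[GroundTruth]]:
    """Mother frame followed by a two-daughter frame with a planted division
    angle and polarity inheritance ratio.

    The mother is a triaxial ellipsoid whose shortest axis points along a
    seeded random direction u; the daughters separate along v with
    |u·v| = sin(θ_true), so the recovered division angle is θ_true.  The
    apical cap splits with total-intensity ratio `ratio_true` (dimmer over
    brighter).  Returns per-frame channel dicts and ground truths.
    """
    if not 0.0 <= theta_true <= 90.0:
        raise ValueError("theta_true must lie in [0, 90] degrees")
    if not 0.0 <= ratio_true <= 1.0:
        raise ValueError("ratio_true must lie in [0, 1]")
    rng = np.random.default_rng(spec.rng_seed)
    R = spec.embryo_radius_um
    a = np.array(mother_axes_um) if mother_axes_um else R * np.array([0.85, 0.70, 0.50])
    if np.max(a) > R:
        raise PackingError("mother ellipsoid exceeds the embryo radius")

    # orthonormal frame: e_long, e_mid, u (= shortest axis)
    basis = _random_frame(rng)
    e_long, e_mid, u = basis
    # daughter separation axis at the planted angle
    w = e_long  # perpendicular to u
    alpha = np.radians(90.0 - theta_true)
    v = np.cos(alpha) * u + np.sin(alpha) * w
    v /= np.linalg.norm(v)

    shape = _derive_shape(replace(spec, compression_factor=1.0))
    spacing = spec.spacing
    center = np.array([n * s / 2.0 for n, s in zip(shape, spacing)])
    qz = (np.arange(shape[0]) + 0.5) * spacing[0] - center[0]
    qy = (np.arange(shape[1]) + 0.5) * spacing[1] - center[1]
    qx = (np.arange(shape[2]) + 0.5) * spacing[2] - center[2]
    P = np.stack(
        np.meshgrid(qz, qy, qx, indexing="ij"), axis=-1
    )  # (Z,Y,X,3) offsets, μm

    # --- frame 0: mother ellipsoid
    M = np.stack(basis)  # rows: principal directions for semi-axes a
    proj = P @ M.T
    inside_m = ((proj / a) ** 2).sum(axis=-1) <= 1.0
    labels0 = inside_m.astype(np.uint16)
    truth0 = _division_truth(labels0, spacing, spec, frame_outer={1: 1.0})
    truth0.e_short_true = u
    truth0.theta_true_deg = float(theta_true)
    frames0 = _division_channels(labels0, spec, rng)

    # --- frame 1: two daughters along v
    r_d = float(np.prod(a) / 2.0) ** (1.0 / 3.0)
    sep = 0.95 * r_d
    c1, c2 = -sep * v, sep * v
    d1 = ((P - c1) ** 2).sum(axis=-1)
    d2 = ((P - c2) ** 2).sum(axis=-1)
    in1 = d1 <= r_d**2
    in2 = d2 <= r_d**2
    labels1 = np.zeros(shape, dtype=np.uint16)
    labels1[in1 & (d1 <= d2)] = 1
    labels1[in2 & (d2 < d1)] = 2
    # polarity caps: same geometry on both daughters (outer poles along ±v),
    # intensities scaled so the total-signal ratio is ratio_true
    fractions = {1: 1.0, 2: float(ratio_true)}
    truth1 = _division_truth(labels1, spacing, spec, frame_outer=fractions)
    truth1.theta_true_deg = float(theta_true)
    truth1.e_short_true = u
    truth1.division_axis_true = v
    truth1.ratio_true = float(ratio_true)
    frames1 = _division_channels(
        labels1, spec, rng, cap_axes={1: -v, 2: v}, cap_fractions=fractions
    )
    return [frames0, frames1], [truth0, truth1]


def _random_frame(rng) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 2] = -Q[:, 2]
    return Q.T


def _division_truth(labels, spacing, spec, frame_outer) -> GroundTruth:
    vv = float(np.prod(spacing))
    centroids = {}
    volumes = {}
    for k in np.unique(labels):
        if k == 0:
            continue
        idx = np.argwhere(labels == k)
        centroids[int(k)] = (idx.mean(axis=0) + 0.5) * np.asarray(spacing)
        volumes[int(k)] = idx.shape[0] * vv
    return GroundTruth(
        labels=VoxelGrid3D(labels, spacing),
        embryo_mask=labels > 0,
        centroids=centroids,
        volumes=volumes,
        outer_cells=set(centroids),
        inheritance_fractions=dict(frame_outer),
    )


def _division_channels(
    labels, spec: SyntheticEmbryoSpec, rng, cap_axes=None, cap_fractions=None
) -> dict[str, VoxelGrid3D]:
    spacing = spec.spacing
    boundary = _boundary_mask(labels)
    membrane = _ridge_image(
        boundary, spacing, spec.membrane_thickness_um, spec.membrane_peak, spec.background
    )
    shape = labels.shape
    polarity_paint = np.zeros(shape, dtype=float)
    if cap_axes:
        bg_adjacent = ndimage.binary_dilation(
            labels == 0, ndimage.generate_binary_structure(3, 1)
        )
        paint_scale = _sheet_paint_scale(spec.membrane_thickness_um, spacing)
        cos_cap = np.cos(np.radians(spec.cap_half_angle_deg))
        for k, axis in cap_axes.items():
            frac = float(np.clip((cap_fractions or {}).get(k, 1.0), 0.0, 1.0))
            if frac <= 0:
                continue
            idx = np.argwhere(labels == k)
            cen = (idx.mean(axis=0) + 0.5) * np.asarray(spacing)
            coords = (idx + 0.5) * np.asarray(spacing) - cen
            cn = np.linalg.norm(coords, axis=1) + 1e-12
            cosang = (coords @ np.asarray(axis)) / cn
            surf = bg_adjacent[tuple(idx.T)]
            sel = idx[surf & (cosang >= cos_cap)]
            polarity_paint[tuple(sel.T)] = spec.cap_intensity * frac * paint_scale
    sig_vox = [spec.membrane_thickness_um / s for s in spacing]
    polarity = spec.background + ndimage.gaussian_filter(polarity_paint, sig_vox, mode="nearest")
    nuclear = np.full(shape, spec.background, dtype=float)
    out = {
        "membrane": VoxelGrid3D(_apply_noise(membrane, spec, rng), spacing),
        "nuclear": VoxelGrid3D(_apply_noise(nuclear, spec, rng), spacing),
        "polarity": VoxelGrid3D(_apply_noise(polarity, spec, rng), spacing),
    }
    return out
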