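"""Per-cell and whole-embryo geometry from label volumes.

For a voxel region treated as a uniform body of unit density (mass = V),
the inertia tensor about the centroid is

    I = Σ_voxels ( |d|² 𝟙 − d dᵀ ) · v_vox            [μm⁵]

with d the voxel offset from the centroid in μm and v_vox the voxel volume.
The equivalent radii are the semi-axes of the uniform ellipsoid with the
same volume and principal moments (I1 ≤ I2 ≤ I3):

    r1 = sqrt(5/2·(I2+I3−I1)/V),  r2 = sqrt(5/2·(I3+I1−I2)/V),
    r3 = sqrt(5/2·(I1+I2−I3)/V),

so a solid ball of radius R gives r1 = r2 = r3 = R exactly, and the aspect
ratio is r1/r3 ≥ 1 (longest over shortest axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageio import VoxelGrid3D


class DegenerateRegionError(ValueError):
    """Voxel set too small or too flat for a meaningful inertia ellipsoid."""


@dataclass
class CellShapeRecord:
    cell_id: int
    frame: int
    volume: float                   # μm³
    centroid: np.ndarray            # (z, y, x) μm
    inertia: np.ndarray             # 3×3, μm⁵
    moments: np.ndarray             # (I1, I2, I3) ascending
    axes: np.ndarray                # rows e_long, e_mid, e_short (for I1, I2, I3)
    radii: np.ndarray               # (r1, r2, r3) descending, μm
    aspect_ratio: float
    degenerate_axes: bool = False   # near-equal principal moments
    touches_border: bool = False

    @property
    def e_long(self) -> np.ndarray:
        return self.axes[0]

    @property
    def e_short(self) -> np.ndarray:
        return self.axes[2]


def _region_coords(labels: VoxelGrid3D, cell_id: int) -> np.ndarray:
    idx = np.argwhere(labels.data == cell_id)
    if idx.size == 0:
        raise KeyError(f"cell id {cell_id} not present in label volume")
    return idx


def cell_volume(labels: VoxelGrid3D, cell_id: int) -> float:
    """Region volume in μm³: voxel count × voxel volume."""
    n = int(np.count_nonzero(labels.data == cell_id))
    if n == 0:
        raise KeyError(f"cell id {cell_id} not present in label volume")
    return n * labels.voxel_volume


def region_centroid(labels: VoxelGrid3D, cell_id: int) -> np.ndarray:
    """Centroid of a label in μm (z, y, x), voxel centers at (i+0.5)·spacing."""
    idx = _region_coords(labels, cell_id)
    return (idx.mean(axis=0) + 0.5) * np.asarray(labels.spacing)


def inertia_tensor(labels: VoxelGrid3D, cell_id: int) -> np.ndarray:
    """Unit-density inertia tensor about the region centroid, μm⁵ scale."""
    idx = _region_coords(labels, cell_id)
    if idx.shape[0] < 4:
        raise DegenerateRegionError(
            f"cell {cell_id}: {idx.shape[0]} voxel(s) cannot define an inertia ellipsoid"
        )
    d = (idx - idx.mean(axis=0)) * np.asarray(labels.spacing)
    if np.linalg.matrix_rank(d, tol=1e-9) < 3:
        raise DegenerateRegionError(f"cell {cell_id}: voxels are coplanar")
    vv = labels.voxel_volume
    r2 = np.einsum("ni,ni->n", d, d)
    tensor = (r2.sum() * np.eye(3) - d.T @ d) * vv
    return 0.5 * (tensor + tensor.T)


def principal_decomposition(tensor: np.ndarray, *, gap_tol: float = 1e-6):
    """Ascending principal moments and orthonormal axes of a symmetric tensor.

    Axis signs are fixed so each eigenvector has a non-negative component on
    its first nonzero coordinate, making downstream angles reproducible.
    Returns (moments, axes_rows, degenerate_flag); the flag marks a relative
    eigenvalue gap below `gap_tol` (axes then arbitrary within the subspace).
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T, atol=1e-8 * max(1, abs(tensor).max())):
        raise ValueError("inertia tensor must be symmetric 3×3")
    moments, vecs = np.linalg.eigh(tensor)
    axes = vecs.T.copy()
    for i in range(3):
        v = axes[i]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            axes[i] = -v
    scale = max(abs(moments).max(), 1e-300)
    gaps = np.diff(moments) / scale
    degenerate = bool(np.any(gaps < gap_tol))
    return moments, axes, degenerate


def equivalent_radii(moments, V: float) -> np.ndarray:
    """Semi-axes (r1 ≥ r2 ≥ r3, μm) of the equivalent uniform ellipsoid."""
    if V <= 0:
        raise ValueError("volume must be positive")
    I1, I2, I3 = np.sort(np.asarray(moments, dtype=float))
    radicands = 2.5 * np.array([I2 + I3 - I1, I3 + I1 - I2, I1 + I2 - I3]) / V
    if np.any(radicands <= 0):
        raise DegenerateRegionError(
            f"non-ellipsoidal moment triple {moments}: negative radicand {radicands}"
        )
    return np.sqrt(radicands)


def aspect_ratio(radii) -> float:
    """Longest over shortest equivalent radius, ≥ 1."""
    r = np.sort(np.asarray(radii, dtype=float))[::-1]
    return float(r[0] / r[2])


def shape_record(labels: VoxelGrid3D, cell_id: int, frame: int = 0) -> CellShapeRecord:
    """Full shape measurement of one label."""
    V = cell_volume(labels, cell_id)
    cen = region_centroid(labels, cell_id)
    tensor = inertia_tensor(labels, cell_id)
    moments, axes, degen = principal_decomposition(tensor)
    radii = equivalent_radii(moments, V)
    idx = _region_coords(labels, cell_id)
    touches = bool(
        np.any(idx == 0) or np.any(idx == np.asarray(labels.shape) - 1)
    )
    return CellShapeRecord(
        cell_id=int(cell_id),
        frame=int(frame),
        volume=V,
        centroid=cen,
        inertia=tensor,
        moments=moments,
        axes=axes,
        radii=radii,
        aspect_ratio=aspect_ratio(radii),
        degenerate_axes=degen,
        touches_border=touches,
    )


def embryo_aspect_ratio(embryo_mask: VoxelGrid3D) -> float:
    """Aspect ratio of the whole embryo mask treated as a single region."""
    mask = np.asarray(embryo_mask.data) > 0
    grid = VoxelGrid3D(mask.astype(np.uint8), embryo_mask.spacing)
    rec = shape_record(grid, 1)
    return rec.aspect_ratio


def measure_labels(
    labels: VoxelGrid3D,
    frame: int = 0,
    *,
    exclude_border: bool = True,
    exclude_ids: set[int] | None = None,
) -> pd.DataFrame:
    """One CellShapeRecord row per label (background 0 skipped).

    Cells straddling the volume border are flagged and, by default, excluded
    from the returned table.
    """
    rows = []
    exclude_ids = exclude_ids or set()
    for cid in np.unique(labels.data):
        if cid == 0 or int(cid) in exclude_ids:
            continue
        try:
            rec = shape_record(labels, int(cid), frame)
        except DegenerateRegionError:
            continue
        if exclude_border and rec.touches_border:
            continue
        rows.append(
            {
                "cell_id": rec.cell_id,
                "frame": rec.frame,
                "volume_um3": rec.volume,
                "z_um": rec.centroid[0],
                "y_um": rec.centroid[1],
                "x_um": rec.centroid[2],
                "I1": rec.moments[0],
                "I2": rec.moments[1],
                "I3": rec.moments[2],
                "r1_um": rec.radii[0],
                "r2_um": rec.radii[1],
                "r3_um": rec.radii[2],
                "aspect_ratio": rec.aspect_ratio,
                "e_long_z": rec.axes[0][0],
                "e_long_y": rec.axes[0][1],
                "e_long_x": rec.axes[0][2],
                "e_short_z": rec.axes[2][0],
                "e_short_y": rec.axes[2][1],
                "e_short_x": rec.axes[2][2],
                "degenerate_axes": rec.degenerate_axes,
            }
        )
    return pd.DataFrame(rows)
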