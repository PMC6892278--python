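"""Volume and table IO, bit-depth conversion, resampling, and pre-smoothing.

All volumes are carried as :class:`VoxelGrid3D`: a 3D scalar array in fixed
``(z, y, x)`` axis order with physical voxel spacing in micrometres.  All
coordinates in centroid tables are physical (μm), never voxel indices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)

CENTROID_COLUMNS = ["cell_id", "frame", "z_um", "y_um", "x_um", "parent_id"]


@dataclass(frozen=True)
class VoxelGrid3D:
    """A 3D scalar field with physical voxel spacing.

    Parameters
    ----------
    data :
        3D array, axis order ``(z, y, x)``.
    spacing :
        Voxel edge lengths ``(dz, dy, dx)`` in μm; all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {data.ndim} dimensions")
        if min(data.shape) < 1:
            raise ValueError(f"degenerate shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent per axis in μm."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def with_data(self, data: np.ndarray) -> "VoxelGrid3D":
        return replace(self, data=data)


@dataclass
class CentroidTable:
    """Nucleus centroid table: one row per (cell, frame), coordinates in μm."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CENTROID_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in CENTROID_COLUMNS[:-1] if c not in self.df.columns]
        if missing:
            raise ValueError(f"centroid table missing columns {missing}")
        if "parent_id" not in self.df.columns:
            self.df = self.df.assign(parent_id=pd.NA)
        dup = self.df.duplicated(subset=["cell_id", "frame"])
        if dup.any():
            raise ValueError(f"duplicate (cell_id, frame) rows: {self.df[dup].cell_id.tolist()}")
        known = set(self.df.cell_id)
        parents = set(self.df.parent_id.dropna())
        orphan = parents - known
        if orphan:
            raise ValueError(f"parent_id values reference unknown cells: {sorted(orphan)}")

    @classmethod
    def read_csv(cls, path: str | Path) -> "CentroidTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def at_frame(self, frame: int) -> pd.DataFrame:
        return self.df[self.df.frame == frame]

    def points(self, frame: int) -> np.ndarray:
        """(n, 3) array of (z, y, x) μm coordinates at a frame, ordered by cell_id."""
        sub = self.at_frame(frame).sort_values("cell_id")
        return sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)


def read_volume(path: str | Path, spacing: tuple[float, float, float]) -> VoxelGrid3D:
    """Read a multi-page TIFF (one page per z slice) or HDF5 volume.

    For HDF5, the first dataset found is used unless the file carries a
    ``data`` dataset; a stored ``spacing`` attribute wins over the argument.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read volume: {path} does not exist")
    if path.suffix.lower() in {".h5", ".hdf5", ".h5f"}:
        with h5py.File(path, "r") as f:
            name = "data" if "data" in f else next(iter(f.keys()))
            dset = f[name]
            data = dset[()]
            if "spacing" in dset.attrs:
                spacing = tuple(float(s) for s in dset.attrs["spacing"])
    else:
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - tifffile error text varies
            raise IOError(f"cannot read volume {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} holds a {data.ndim}D image; a 3D z-stack is required")
    return VoxelGrid3D(data, spacing)


def write_volume(grid: VoxelGrid3D, path: str | Path) -> None:
    """Write a grid as multi-page TIFF or as an HDF5 dataset with spacing attrs."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5", ".h5f"}:
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=grid.data)
            dset.attrs["spacing"] = np.asarray(grid.spacing, dtype=float)
            dset.attrs["axis_order"] = "zyx"
    else:
        tifffile.imwrite(path, grid.data)


def resample_isotropic(grid: VoxelGrid3D, target: float, *, order: int = 1) -> VoxelGrid3D:
    """Resample an intensity grid to isotropic voxels of edge ``target`` μm.

    Trilinear interpolation; the physical extent is preserved to within one
    voxel per axis.  Label images must go through :func:`resample_labels`.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if target > min(grid.extent):
        raise ValueError(
            f"target {target} μm exceeds the smallest extent {min(grid.extent):.3g} μm; "
            "output would be degenerate"
        )
    zoom = [s / target for s in grid.spacing]
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return grid
    out = ndimage.zoom(np.asarray(grid.data, dtype=float), zoom, order=order,
                       mode="nearest", grid_mode=True)
    return VoxelGrid3D(out, (target, target, target))


def resample_labels(labels: VoxelGrid3D, target: float) -> VoxelGrid3D:
    """Nearest-neighbour resampling of a label image; never invents labels."""
    out = resample_isotropic(labels, target, order=0)
    return VoxelGrid3D(np.asarray(out.data).astype(labels.data.dtype), out.spacing)


def to_8bit(grid: VoxelGrid3D, lo: float = 0.1, hi: float = 99.9) -> VoxelGrid3D:
    """Linear rescale of the [P_lo, P_hi] percentile window to [0, 255].

    Clipped and rounded half-up to uint8.  A constant image maps to zeros with
    a warning (not an error), since no window exists.
    """
    if not lo < hi:
        raise ValueError(f"lo percentile {lo} must be below hi {hi}")
    data = np.asarray(grid.data, dtype=float)
    vlo, vhi = np.percentile(data, [lo, hi])
    if vhi <= vlo:
        # fall back to the full range before declaring the image constant
        vlo, vhi = float(data.min()), float(data.max())
    if vhi <= vlo:
        warnings.warn("constant image: 8-bit conversion yields all zeros", stacklevel=2)
        logger.warning("to_8bit: constant image, output is all zeros")
        return VoxelGrid3D(np.zeros(grid.shape, dtype=np.uint8), grid.spacing)
    scaled = np.clip((data - vlo) / (vhi - vlo) * 255.0, 0, 255)
    return VoxelGrid3D(np.floor(scaled + 0.5).astype(np.uint8), grid.spacing)


def _pm_conductance(gmag2: np.ndarray, conductance: float) -> np.ndarray:
    return np.exp(-gmag2 / (conductance**2))


def anisotropic_diffusion(
    grid: VoxelGrid3D,
    iterations: int = 5,
    conductance: float = 1.0,
    step: float = 0.0625,
) -> VoxelGrid3D:
    """Perona-Malik gradient anisotropic diffusion with reflective boundaries.

    Edge-stopping conductance ``c = exp(-(|∇I|/K)²)`` on face-centred
    gradients; explicit update, stability bound ``step ≤ 1/(2·ndim)`` in voxel
    units.  ``iterations == 0`` returns the input unchanged.  Mean intensity
    is conserved (the scheme is in divergence form with zero-flux borders).
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if step <= 0 or step > 1.0 / 6.0 + 1e-12:
        raise ValueError(f"step {step} violates the 3D stability bound (0, 1/6]")
    if conductance <= 0:
        raise ValueError("conductance must be positive")
    if iterations == 0:
        return grid
    u = np.asarray(grid.data, dtype=float).copy()
    for _ in range(iterations):
        div = np.zeros_like(u)
        for ax in range(3):
            fwd = np.diff(u, axis=ax)  # flux across interior faces
            c = _pm_conductance(fwd**2, conductance)
            flux = c * fwd
            pad = [(0, 0)] * 3
            pad[ax] = (1, 1)
            flux = np.pad(flux, pad)  # zero flux through the volume border
            div += np.diff(flux, axis=ax)
        u = u + step * div
    return VoxelGrid3D(u, grid.spacing)
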