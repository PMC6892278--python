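"""Edge-detector fields and membrane-probability maps for the level set.

The edge detector is the standard Perona-Malik form

    g = 1 / (1 + K · |∇(G_σ * I_n)|²),

where ``I_n`` is the input linearly rescaled to [0, 1] and the gradient is
taken by central differences in physical (μm) units.  ``g ≈ 1`` in flat
regions, ``g → 0`` at membranes; every term of the subjective-surface
equation carries a factor of ``g`` or ``∇g``, so the front freezes on edges.

Membrane probability maps can be computed (gradient- or ridge-based) or
imported from a voxel-classifier export (HDF5 ``exported_data`` or TIFF).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

from .imageio import VoxelGrid3D, read_volume


@dataclass(frozen=True)
class EdgeMap:
    """Edge-stopping field g in (0, 1] on the source grid."""

    g: np.ndarray
    spacing: tuple[float, float, float]
    sigma: float
    K: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.g.shape


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel membrane-ness in [0, 1]."""

    p: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str  # "computed" | "imported"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.min() < 0 or p.max() > 1:
            raise ValueError(
                f"probability values outside [0,1]: range [{p.min():.4g}, {p.max():.4g}]"
            )
        object.__setattr__(self, "p", p)

    def as_grid(self) -> VoxelGrid3D:
        return VoxelGrid3D(self.p, self.spacing)


def _normalize01(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def _physical_gradient(data: np.ndarray, spacing: tuple[float, float, float]) -> list[np.ndarray]:
    return list(np.gradient(data, *spacing))


def _smooth(data: np.ndarray, sigma_um: float, spacing) -> np.ndarray:
    if sigma_um <= 0:
        return np.asarray(data, dtype=float)
    sig_vox = [sigma_um / s for s in spacing]
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sig_vox, mode="nearest")


def edge_detector(grid: VoxelGrid3D, sigma: float = 1.0, K: float = 100.0) -> EdgeMap:
    """Compute g = 1/(1 + K|∇(G_σ*I_n)|²) with I_n the [0,1]-rescaled input.

    Invariant to affine intensity rescaling of the input by construction of
    I_n; a constant image gives g ≡ 1.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    smoothed = _smooth(_normalize01(grid.data), sigma, grid.spacing)
    grads = _physical_gradient(smoothed, grid.spacing)
    gmag2 = sum(gr**2 for gr in grads)
    g = 1.0 / (1.0 + K * gmag2)
    return EdgeMap(g=g, spacing=grid.spacing, sigma=sigma, K=K)


def edge_from_probability(prob: ProbabilityMap, sigma: float = 1.0, K: float = 100.0) -> EdgeMap:
    """Edge field computed directly from a membrane-probability map."""
    return edge_detector(prob.as_grid(), sigma=sigma, K=K)


def membrane_probability(
    grid: VoxelGrid3D | None = None,
    method: str = "ridge",
    *,
    sigma: float = 1.0,
    path: str | Path | None = None,
) -> ProbabilityMap:
    """Produce a membrane-ness map.

    method="gradient": normalized smoothed gradient magnitude.
    method="ridge":    normalized planar-ridge response — the positive part of
                       the largest eigenvalue of the Hessian of the smoothed
                       image.  A bright thin sheet has one large positive
                       second derivative across the sheet, so this responds at
                       membrane mid-planes rather than their flanks.
    method="import":   load an externally classified map (HDF5 dataset
                       ``exported_data`` with a trailing channel axis squeezed,
                       or TIFF) and pass it through after range validation.
    """
    if method == "import":
        if path is None:
            raise ValueError("method='import' requires a path")
        p = _load_external_map(path)
        if grid is not None:
            if p.shape != grid.shape:
                raise ValueError(
                    f"imported map shape {p.shape} does not match volume shape {grid.shape}"
                )
            spacing = grid.spacing
        else:
            spacing = (1.0, 1.0, 1.0)
        return ProbabilityMap(p=p, spacing=spacing, provenance="imported")
    if grid is None:
        raise ValueError(f"method='{method}' requires a volume")
    smoothed = _smooth(_normalize01(grid.data), sigma, grid.spacing)
    if method == "gradient":
        resp = np.sqrt(sum(gr**2 for gr in _physical_gradient(smoothed, grid.spacing)))
    elif method == "ridge":
        # largest Hessian eigenvalue of the *inverted* curvature: membranes are
        # bright sheets, i.e. strongly negative second derivative across the
        # sheet of the intensity; take the positive part of -λ_min ≡ λ_max(-H).
        H = _hessian(smoothed, grid.spacing)
        eigvals = np.linalg.eigvalsh(-H)  # ascending; last = largest of -H
        resp = np.maximum(eigvals[..., -1], 0.0)
    else:
        raise ValueError(f"unknown method '{method}'")
    return ProbabilityMap(p=_normalize01(resp), spacing=grid.spacing, provenance="computed")


def _hessian(data: np.ndarray, spacing) -> np.ndarray:
    grads = _physical_gradient(data, spacing)
    H = np.empty(data.shape + (3, 3), dtype=float)
    for i in range(3):
        gi = _physical_gradient(grads[i], spacing)
        for j in range(3):
            H[..., i, j] = gi[j]
    # symmetrize against finite-difference asymmetry
    return 0.5 * (H + np.swapaxes(H, -1, -2))


def _load_external_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            name = "exported_data" if "exported_data" in f else next(iter(f.keys()))
            p = f[name][()]
        p = np.asarray(p, dtype=float)
        if p.ndim == 4:
            # channel axis: keep the membrane channel (last axis, channel 0 by
            # convention) after squeezing singletons
            p = np.squeeze(p)
            if p.ndim == 4:
                p = p[..., 0]
    else:
        p = np.asarray(read_volume(path, (1, 1, 1)).data, dtype=float)
    if p.ndim != 3:
        raise ValueError(f"imported probability map is {p.ndim}D, expected 3D")
    return p
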