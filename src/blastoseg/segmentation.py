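"""Embryo-surface, cell, membrane-shell, and cavity segmentation.

Four procedures compose the sparse-field subjective-surface solver with
classical morphology:

* ``segment_embryo_surface`` — binarize the membrane channel into an
  approximative surface strictly containing the embryo, evolve the front
  inward until it stops at the cell–medium interface, then erode 1–2 voxels
  onto the membrane signal.
* ``segment_cells`` — grow one front per nucleus seed outward on the
  membrane-probability edge field, dilate each converged region onto the
  membrane, resolve contested voxels by minimum distance to the converged
  fronts, and clip everything to the embryo mask (which is kept exactly as
  segmented above).  The result is an exact partition of the embryo mask.
* ``extract_membrane_shell`` — the voxel annulus between a cell's boundary
  b1 and its dilation b2, where membrane-bound signal is summed.
* ``segment_cavity`` — blur + invert the membrane image at 1 μm isotropic,
  threshold within the embryo, and keep interior components above a volume
  floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .edges import EdgeMap, ProbabilityMap, edge_from_probability
from .imageio import CentroidTable, VoxelGrid3D, resample_isotropic, resample_labels
from dataclasses import replace

from .sparse_levelset import (
    ConvergenceReport,
    GsubsurfParams,
    LevelSetField,
    _FACE,
    evolve,
    init_from_mask,
    init_from_seed,
    stable_tau,
    zero_set_mask,
)

CAVITY_LABEL_OFFSET = 1  # cavity gets max(cell labels) + 1

SURFACE_FLOW_DEFAULTS = dict(w_a=1.0, w_d=0.3, delta=-0.8, max_iters=500,
                             convergence_window=20)
CELL_FLOW_DEFAULTS = dict(w_a=1.0, w_d=0.3, delta=0.8, max_iters=500,
                          convergence_window=20)


class ThresholdError(ValueError):
    """Binarization failed to isolate an embryo."""


class BoundaryContactError(ValueError):
    """Embryo touches the volume border; surface segmentation undefined."""


class SeedError(ValueError):
    """One or more seeds fall outside the embryo mask."""


@dataclass
class MembraneShell:
    """Annulus between a cell's inner border b1 and dilated outer border b2."""

    cell_id: int
    b1_mask: np.ndarray
    b2_mask: np.ndarray
    shell_mask: np.ndarray


def _touching_faces(mask: np.ndarray) -> list[tuple[int, int]]:
    faces = []
    for ax in range(3):
        if np.take(mask, 0, axis=ax).any():
            faces.append((ax, 0))
        if np.take(mask, -1, axis=ax).any():
            faces.append((ax, 1))
    return faces


def binarize_embryo(
    membrane: VoxelGrid3D,
    threshold: str | float = "otsu",
    dilate: int = 2,
) -> np.ndarray:
    """Approximative outer surface: threshold, fill holes, keep the largest
    component, close, and dilate so the result strictly contains the embryo."""
    data = np.asarray(membrane.data, dtype=float)
    thr = float(threshold_otsu(data)) if threshold == "otsu" else float(threshold)
    fg = data > thr
    if not fg.any():
        raise ThresholdError(f"threshold {thr:.4g} leaves no foreground voxels")
    if fg.mean() > 0.35:
        # membrane signal occupies a modest fraction of any real field of
        # view; a half-full binarization means the threshold separates noise
        raise ThresholdError(
            f"threshold {thr:.4g} marks {fg.mean():.0%} of the volume as foreground: "
            "no embryo isolated"
        )
    fg = ndimage.binary_closing(fg, _FACE, iterations=1)
    fg = ndimage.binary_fill_holes(fg)
    lbl, n = ndimage.label(fg, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        raise ThresholdError("no connected foreground component after cleanup")
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    comp = lbl == (1 + int(np.argmax(sizes)))
    faces = _touching_faces(comp)
    axes_spanned = {ax for ax, _ in faces}
    if any(((ax, 0) in faces and (ax, 1) in faces) for ax in axes_spanned):
        raise ThresholdError(
            "binarization percolates across the volume: no embryo isolated "
            "(noise-dominated image or threshold far too low)"
        )
    if faces:
        raise BoundaryContactError(
            f"embryo candidate touches the volume border on faces {faces}"
        )
    if dilate > 0:
        comp = ndimage.binary_dilation(comp, _FACE, iterations=dilate)
        if _touching_faces(comp):
            raise BoundaryContactError("embryo candidate touches the border after dilation")
    return comp


def segment_embryo_surface(
    membrane: VoxelGrid3D,
    edge: EdgeMap,
    params: GsubsurfParams | None = None,
    threshold: str | float = "otsu",
    erode_iters: int = 2,
) -> tuple[np.ndarray, ConvergenceReport]:
    """Segment the embryo outer surface by inward subjective-surface flow.

    The converged front localizes a voxel or two outside the membrane
    signal, hence the final erosion (default 2 steps, 6-connected).
    """
    if params is None:
        params = GsubsurfParams(**SURFACE_FLOW_DEFAULTS)
    if params.delta >= 0:
        raise ValueError("embryo-surface flow must run inward: delta must be negative")
    approx = binarize_embryo(membrane, threshold)
    fld = init_from_mask(approx, membrane.spacing)
    params = replace(params, tau=stable_tau(edge, params, cap=params.tau))
    fld, report = evolve(fld, edge, params)
    mask = zero_set_mask(fld)
    if erode_iters > 0:
        mask = ndimage.binary_erosion(mask, _FACE, iterations=erode_iters, border_value=0)
    return mask, report


def _boundary_voxels(region: np.ndarray) -> np.ndarray:
    return region & ~ndimage.binary_erosion(region, _FACE, border_value=1)


def segment_cells(
    prob: ProbabilityMap,
    seeds: CentroidTable,
    embryo_mask: np.ndarray,
    edge: EdgeMap | None = None,
    params: GsubsurfParams | None = None,
    *,
    frame: int = 0,
    seed_radius_um: float = 2.0,
    membrane_cut: float = 0.5,
    prob_floor: float = 0.2,
    edge_K: float = 2500.0,
    overlap_fraction: float = 0.5,
    max_dilate: int = 5,
) -> tuple[VoxelGrid3D, dict[int, ConvergenceReport]]:
    """Seeded cell segmentation on a membrane-probability map.

    One front per nucleus seed grows outward (ballooning δ > 0) and freezes
    on the membrane; each converged region is then dilated (6-connected)
    until its boundary overlaps membrane-classified voxels (p ≥
    `membrane_cut`) by at least `overlap_fraction`, or `max_dilate` steps.
    Every embryo-mask voxel claimed by several cells — or by none — is
    assigned to the cell whose converged front is nearest (Euclidean, μm),
    which makes the result independent of seed order and an exact partition
    of the embryo mask.
    """
    if params is None:
        params = GsubsurfParams(**CELL_FLOW_DEFAULTS)
    if params.delta <= 0:
        raise ValueError("cell fronts must grow outward: delta must be positive")
    spacing = prob.spacing
    embryo_mask = np.asarray(embryo_mask, dtype=bool)
    if edge is None:
        # noise-floor the probability map so spurious ridge responses in the
        # cytoplasm do not pin the growing fronts, then build the edge field
        floored = np.where(prob.p < prob_floor, 0.0, prob.p)
        edge = edge_from_probability(
            ProbabilityMap(floored, prob.spacing, prob.provenance), sigma=1.0, K=edge_K
        )
    params = replace(params, tau=stable_tau(edge, params, cap=params.tau))

    table = seeds.at_frame(frame).sort_values("cell_id")
    if table.empty:
        raise SeedError(f"no seeds at frame {frame}")
    bad: list[int] = []
    shape = embryo_mask.shape
    voxels = []
    for _, row in table.iterrows():
        vox = tuple(
            int(np.clip(c / s, 0, n - 1))
            for c, s, n in zip((row.z_um, row.y_um, row.x_um), spacing, shape)
        )
        if not embryo_mask[vox]:
            bad.append(int(row.cell_id))
        voxels.append(vox)
    if bad:
        raise SeedError(f"seeds outside the embryo mask for cell ids {bad}")

    regions: dict[int, np.ndarray] = {}
    dist: dict[int, np.ndarray] = {}
    reports: dict[int, ConvergenceReport] = {}
    membrane_vox = prob.p >= membrane_cut
    for (_, row), vox in zip(table.iterrows(), voxels):
        cid = int(row.cell_id)
        fld = init_from_seed((row.z_um, row.y_um, row.x_um), seed_radius_um, shape, spacing)
        fld, rep = evolve(fld, edge, params)
        reports[cid] = rep
        region = zero_set_mask(fld) & embryo_mask
        if not region.any():
            region = np.zeros(shape, bool)
            region[vox] = True
        boundary = _boundary_voxels(region)
        dist[cid] = ndimage.distance_transform_edt(~boundary, sampling=spacing)
        grown = region
        for _ in range(max_dilate):
            b = _boundary_voxels(grown)
            frac = float(membrane_vox[b].mean()) if b.any() else 1.0
            if frac >= overlap_fraction:
                break
            grown = ndimage.binary_dilation(grown, _FACE) & embryo_mask
        regions[cid] = grown

    ids = sorted(regions)
    claim_count = np.zeros(shape, dtype=np.int16)
    for cid in ids:
        claim_count += regions[cid]
    labels = np.zeros(shape, dtype=np.uint16)
    for cid in ids:
        sole = regions[cid] & (claim_count == 1)
        labels[sole] = cid
    needs_distance = embryo_mask & (labels == 0)
    if needs_distance.any():
        stack = np.stack([dist[cid][needs_distance] for cid in ids])
        winner = np.asarray(ids, dtype=np.uint16)[np.argmin(stack, axis=0)]
        labels[needs_distance] = winner
    labels[~embryo_mask] = 0
    return VoxelGrid3D(labels, spacing), reports


def extract_membrane_shell(
    labels: VoxelGrid3D, cell_id: int, dilate_steps: int = 2
) -> MembraneShell:
    """b1 = cell boundary voxels; b2 = boundary after `dilate_steps`
    dilations; shell = everything between (b1 and b2 inclusive).

    Shells of adjacent cells overlap on shared membrane — by design, the
    signal there counts for both cells.
    """
    region = np.asarray(labels.data) == int(cell_id)
    if not region.any():
        raise KeyError(f"cell id {cell_id} not present in label volume")
    b1 = _boundary_voxels(region)
    grown = (
        ndimage.binary_dilation(region, _FACE, iterations=dilate_steps)
        if dilate_steps > 0
        else region
    )
    b2 = _boundary_voxels(grown)
    shell = grown & ~(region & ~b1)
    return MembraneShell(cell_id=int(cell_id), b1_mask=b1, b2_mask=b2, shell_mask=shell)


def segment_cavity(
    membrane: VoxelGrid3D | ProbabilityMap,
    embryo_mask: np.ndarray,
    sigma: float = 2.0,
    min_volume: float = 8000.0,
) -> tuple[VoxelGrid3D, float]:
    """Cavity (signal-free lumen) segmentation.

    Resample to 1 μm isotropic, Gaussian-blur (`sigma` μm), invert, Otsu
    within the embryo mask, and keep connected components that lie fully
    inside the mask with volume ≥ `min_volume` μm³ (default 8000 μm³ — well
    above any cytoplasm pocket, well below a nascent blastocoel).  Returns
    the cavity mask on the 1 μm grid and the total volume in μm³; absence of
    a cavity is volume 0, not an error.
    """
    if isinstance(membrane, ProbabilityMap):
        membrane = membrane.as_grid()
    work = resample_isotropic(membrane, 1.0)
    mask_grid = resample_labels(
        VoxelGrid3D(np.asarray(embryo_mask, dtype=np.uint8), membrane.spacing), 1.0
    )
    mask = np.asarray(mask_grid.data, dtype=bool)
    # resampling can differ by one voxel per axis; crop to the common shape
    common = tuple(min(a, b) for a, b in zip(work.shape, mask.shape))
    data = np.asarray(work.data, float)[: common[0], : common[1], : common[2]]
    mask = mask[: common[0], : common[1], : common[2]]
    blurred = ndimage.gaussian_filter(data, sigma, mode="nearest")
    inverted = blurred.max() - blurred
    vals = inverted[mask]
    empty = VoxelGrid3D(np.zeros(common, dtype=np.uint8), (1.0, 1.0, 1.0))
    if vals.size == 0 or vals.max() <= vals.min():
        return empty, 0.0
    thr = threshold_otsu(vals)
    cand = mask & (inverted > thr)
    lbl, n = ndimage.label(cand, structure=_FACE)
    if n == 0:
        return empty, 0.0
    rim = ndimage.binary_dilation(~mask, _FACE)
    cavity = np.zeros(common, dtype=bool)
    total = 0.0
    for i in range(1, n + 1):
        comp = lbl == i
        # the size filter acts on the thresholded core: cytoplasm pockets
        # have small cores even when their crest-grown extent is cell-sized
        if comp.sum() < min_volume:
            continue
        if (comp & rim).any():
            continue
        grown = _grow_to_crest(comp, blurred, mask)
        # boundary voxels straddle the membrane crest: count them half
        boundary = grown & ~ndimage.binary_erosion(grown, _FACE, border_value=1)
        vol = float(grown.sum()) - 0.5 * float(boundary.sum())
        cavity |= grown
        total += vol
    return VoxelGrid3D(cavity.astype(np.uint8), (1.0, 1.0, 1.0)), total


def _grow_to_crest(comp: np.ndarray, blurred: np.ndarray, mask: np.ndarray, max_grow: int = 6):
    """Dilate a thresholded cavity component up to the membrane-signal crest.

    Any intensity threshold on the blurred image places the boundary on the
    rising flank of the membrane ridge, a couple of voxels short of the true
    cell-cavity interface at the ridge crest.  Growing while the mean
    intensity on each freshly added ring still increases stops exactly at
    the crest, with no tunable offset.
    """
    grown = comp.copy()
    for _ in range(max_grow):
        src = np.where(grown, blurred, -np.inf)
        nb_max = ndimage.maximum_filter(src, footprint=_FACE)
        accept = mask & ~grown & np.isfinite(nb_max) & (blurred >= nb_max)
        if not accept.any():
            break
        grown |= accept
    return grown


def add_cavity_label(labels: VoxelGrid3D, cavity_mask_1um: VoxelGrid3D) -> VoxelGrid3D:
    """Resample the 1 μm cavity mask onto the label grid and write it as the
    reserved label max(cells) + 1 (excluded from cell statistics)."""
    cav = resample_labels(cavity_mask_1um, float(labels.spacing[0]))
    out = np.asarray(labels.data).copy()
    common = tuple(min(a, b) for a, b in zip(out.shape, cav.shape))
    sel = np.zeros(out.shape, dtype=bool)
    sel[: common[0], : common[1], : common[2]] = (
        np.asarray(cav.data, bool)[: common[0], : common[1], : common[2]]
    )
    out[sel] = out.max() + CAVITY_LABEL_OFFSET
    return VoxelGrid3D(out, labels.spacing)
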