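"""High-level pipeline compositions used by the CLI, tests, and scripts.

These wire the individual stages together in the standard order:
membrane channel → edge field / probability map → embryo surface → seeded
cell fronts → label volume → shape records → division statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .division_orientation import daughter_axis, division_angle
from .edges import edge_detector, membrane_probability
from .imageio import CentroidTable, VoxelGrid3D
from .segmentation import segment_cells, segment_embryo_surface
from .shape_metrics import shape_record


def segment_frame(
    membrane: VoxelGrid3D,
    seeds_um: list[tuple[float, float, float]],
    *,
    edge_sigma: float = 1.0,
    edge_K: float = 2500.0,
) -> VoxelGrid3D:
    """Full single-frame segmentation: surface, then seeded cells."""
    edge = edge_detector(membrane, sigma=edge_sigma, K=edge_K)
    mask, _ = segment_embryo_surface(membrane, edge)
    rows = [
        {"cell_id": i + 1, "frame": 0, "z_um": c[0], "y_um": c[1], "x_um": c[2],
         "parent_id": pd.NA}
        for i, c in enumerate(seeds_um)
    ]
    labels, _ = segment_cells(
        membrane_probability(membrane, "ridge", sigma=edge_sigma),
        CentroidTable(pd.DataFrame(rows)),
        mask,
    )
    return labels


def recover_division_angle(
    mother_membrane: VoxelGrid3D,
    mother_seed_um,
    daughter_membrane: VoxelGrid3D,
    daughter_seeds_um,
) -> float:
    """Division angle θ from raw membrane frames: segment the mother and the
    daughter frame, take the mother's shortest axis and the inter-daughter
    centroid axis, and return θ = 90° − arccos|e1·e2| in degrees."""
    lab_m = segment_frame(mother_membrane, [mother_seed_um])
    e1 = shape_record(lab_m, 1).e_short
    lab_d = segment_frame(daughter_membrane, list(daughter_seeds_um))
    c1 = shape_record(lab_d, 1).centroid
    c2 = shape_record(lab_d, 2).centroid
    return division_angle(e1, daughter_axis(c1, c2))
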