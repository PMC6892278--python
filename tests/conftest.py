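"""Shared fixtures: one small synthetic embryo and its segmentation products,
computed once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from blastoseg.edges import edge_detector, membrane_probability
from blastoseg.segmentation import segment_cells, segment_embryo_surface
from blastoseg.synthetic_embryo import SyntheticEmbryoSpec, generate_embryo


@pytest.fixture(scope="session")
def small_embryo():
    """6-cell embryo at 1 μm voxels: (membrane, nuclear, polarity, truth)."""
    spec = SyntheticEmbryoSpec(n_cells=6, embryo_radius_um=18.0, spacing=(1, 1, 1), rng_seed=1)
    return generate_embryo(spec)


@pytest.fixture(scope="session")
def small_embryo_surface(small_embryo):
    mem, _, _, truth = small_embryo
    edge = edge_detector(mem, sigma=1.0, K=2500.0)
    mask, report = segment_embryo_surface(mem, edge)
    return mask, report


@pytest.fixture(scope="session")
def small_embryo_labels(small_embryo, small_embryo_surface):
    mem, _, _, truth = small_embryo
    mask, _ = small_embryo_surface
    prob = membrane_probability(mem, "ridge", sigma=1.0)
    labels, reports = segment_cells(prob, truth.centroid_table(), mask)
    return labels, reports


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / s if s else 1.0
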