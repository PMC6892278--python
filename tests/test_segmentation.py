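"""Embryo-surface, cell, shell, and cavity segmentation procedures."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from blastoseg.edges import edge_detector, membrane_probability
from blastoseg.imageio import CentroidTable, VoxelGrid3D
from blastoseg.segmentation import (
    BoundaryContactError,
    SeedError,
    ThresholdError,
    binarize_embryo,
    extract_membrane_shell,
    segment_cavity,
    segment_cells,
    segment_embryo_surface,
)
from blastoseg.synthetic_embryo import SyntheticEmbryoSpec, generate_blastocyst

from .conftest import dice


class TestEmbryoSurface:
    def test_surface_recovers_embryo_mask(self, small_embryo, small_embryo_surface):
        _, _, _, truth = small_embryo
        mask, report = small_embryo_surface
        assert report.converged
        assert dice(mask, truth.embryo_mask) >= 0.95

    def test_zero_erosion_leaves_converged_set(self, small_embryo):
        mem, _, _, truth = small_embryo
        edge = edge_detector(mem, sigma=1.0, K=2500.0)
        m0, _ = segment_embryo_surface(mem, edge, erode_iters=0)
        m2, _ = segment_embryo_surface(mem, edge, erode_iters=2)
        # eroding the raw converged set twice reproduces the default output
        eroded = ndimage.binary_erosion(
            m0, ndimage.generate_binary_structure(3, 1), iterations=2
        )
        assert np.array_equal(eroded, m2)
        assert m0.sum() > m2.sum()

    def test_pure_noise_image_raises_threshold_error(self, rng):
        noise = VoxelGrid3D(rng.uniform(0, 1, size=(32, 32, 32)), (1, 1, 1))
        with pytest.raises(ThresholdError):
            binarize_embryo(noise)

    def test_embryo_touching_border_raises(self):
        z, y, x = np.mgrid[:32, :32, :32]
        r = np.sqrt((z - 16.0) ** 2 + (y - 16.0) ** 2 + (x - 16.0) ** 2)
        # membrane shell whose embryo reaches the volume faces
        img = VoxelGrid3D(10 + 100 * np.exp(-((r - 15.5) ** 2) / 2), (1, 1, 1))
        with pytest.raises(BoundaryContactError):
            binarize_embryo(img)

    def test_outward_flow_rejected(self, small_embryo):
        mem, *_ = small_embryo
        edge = edge_detector(mem, sigma=1.0, K=2500.0)
        from blastoseg.sparse_levelset import GsubsurfParams

        with pytest.raises(ValueError, match="inward"):
            segment_embryo_surface(mem, edge, GsubsurfParams(delta=0.5))


class TestSegmentCells:
    def test_labels_partition_embryo_mask(self, small_embryo_surface, small_embryo_labels):
        mask, _ = small_embryo_surface
        labels, _ = small_embryo_labels
        L = labels.data
        assert ((L > 0) == mask).all()  # union = mask and nothing outside

    def test_per_cell_dice_against_ground_truth(self, small_embryo, small_embryo_labels):
        _, _, _, truth = small_embryo
        labels, reports = small_embryo_labels
        assert all(r.converged for r in reports.values())
        scores = [
            dice(labels.data == cid, truth.labels.data == cid)
            for cid in sorted(truth.centroids)
        ]
        assert min(scores) >= 0.80

    def test_seed_order_independence(self, small_embryo, small_embryo_surface,
                                     small_embryo_labels):
        mem, _, _, truth = small_embryo
        mask, _ = small_embryo_surface
        labels, _ = small_embryo_labels
        prob = membrane_probability(mem, "ridge", sigma=1.0)
        table = truth.centroid_table().df.iloc[::-1].reset_index(drop=True)
        relabeled, _ = segment_cells(prob, CentroidTable(table), mask)
        assert np.array_equal(relabeled.data, labels.data)

    def test_seed_outside_mask_lists_ids(self, small_embryo, small_embryo_surface):
        mem, _, _, truth = small_embryo
        mask, _ = small_embryo_surface
        prob = membrane_probability(mem, "ridge", sigma=1.0)
        df = truth.centroid_table().df.copy()
        df.loc[df.cell_id == 2, ["z_um", "y_um", "x_um"]] = 1.0  # corner, outside
        with pytest.raises(SeedError, match=r"\[2\]"):
            segment_cells(prob, CentroidTable(df), mask)

    def test_two_adjacent_balls_split_at_bisector(self):
        # two identical membrane-shell balls sharing a wall; contested voxels
        # must fall on the side of the nearer seed (within one voxel)
        n = (32, 32, 56)
        z, y, x = np.mgrid[: n[0], : n[1], : n[2]]
        c1 = np.array([16.0, 16.0, 17.0])
        c2 = np.array([16.0, 16.0, 39.0])
        r1 = np.sqrt(((z + 0.5) - c1[0]) ** 2 + ((y + 0.5) - c1[1]) ** 2 + ((x + 0.5) - c1[2]) ** 2)
        r2 = np.sqrt(((z + 0.5) - c2[0]) ** 2 + ((y + 0.5) - c2[1]) ** 2 + ((x + 0.5) - c2[2]) ** 2)
        R = 11.0
        img = 10 + 100 * (np.exp(-((r1 - R) ** 2) / 2) + np.exp(-((r2 - R) ** 2) / 2))
        img[np.minimum(r1, r2) > R] = np.maximum(
            10.0, img[np.minimum(r1, r2) > R]
        )
        mask = (r1 <= R) | (r2 <= R)
        prob = membrane_probability(VoxelGrid3D(img, (1, 1, 1)), "ridge", sigma=1.0)
        rows = [
            {"cell_id": 1, "frame": 0, "z_um": c1[0], "y_um": c1[1], "x_um": c1[2], "parent_id": pd.NA},
            {"cell_id": 2, "frame": 0, "z_um": c2[0], "y_um": c2[1], "x_um": c2[2], "parent_id": pd.NA},
        ]
        labels, _ = segment_cells(prob, CentroidTable(pd.DataFrame(rows)), mask)
        L = labels.data
        clearly_1 = mask & (r1 + 1.0 < r2)
        clearly_2 = mask & (r2 + 1.0 < r1)
        assert np.all(L[clearly_1] == 1)
        assert np.all(L[clearly_2] == 2)

    def test_single_seed_fills_single_ball(self):
        n = 36
        z, y, x = np.mgrid[:n, :n, :n]
        r = np.sqrt((z + 0.5 - 18) ** 2 + (y + 0.5 - 18) ** 2 + (x + 0.5 - 18) ** 2)
        img = 10 + 100 * np.exp(-((r - 12.0) ** 2) / 2)
        mask = r <= 12.0
        prob = membrane_probability(VoxelGrid3D(img, (1, 1, 1)), "ridge", sigma=1.0)
        rows = [{"cell_id": 1, "frame": 0, "z_um": 18.0, "y_um": 18.0, "x_um": 18.0,
                 "parent_id": pd.NA}]
        labels, _ = segment_cells(prob, CentroidTable(pd.DataFrame(rows)), mask)
        assert dice(labels.data == 1, mask) >= 0.98


class TestMembraneShell:
    def test_ball_shell_is_annulus_with_expected_volume(self):
        n = 32
        z, y, x = np.mgrid[:n, :n, :n]
        r = np.sqrt((z + 0.5 - 16) ** 2 + (y + 0.5 - 16) ** 2 + (x + 0.5 - 16) ** 2)
        lab = VoxelGrid3D((r <= 10).astype(np.uint16), (1, 1, 1))
        shell = extract_membrane_shell(lab, 1, dilate_steps=2)
        # annulus from the inner border (~r=9) to the face-dilated outer
        # border: 6-connected dilation advances ~0.75 voxel per step in the
        # Euclidean mean (1 axially, 1/√3 diagonally), so outer r ≈ 11.5
        expected = 4 / 3 * np.pi * (11.5**3 - 9.0**3)
        assert shell.shell_mask.sum() == pytest.approx(expected, rel=0.15)
        assert shell.b1_mask.sum() < shell.shell_mask.sum()
        assert not (shell.b1_mask & ~shell.shell_mask).any()

    def test_zero_dilation_shell_equals_b1(self):
        lab = np.zeros((12, 12, 12), np.uint16)
        lab[3:9, 3:9, 3:9] = 1
        grid = VoxelGrid3D(lab, (1, 1, 1))
        shell = extract_membrane_shell(grid, 1, dilate_steps=0)
        assert np.array_equal(shell.shell_mask, shell.b1_mask)

    def test_adjacent_cells_shells_overlap_on_shared_membrane(self):
        lab = np.zeros((12, 12, 20), np.uint16)
        lab[3:9, 3:9, 2:10] = 1
        lab[3:9, 3:9, 10:18] = 2
        grid = VoxelGrid3D(lab, (1, 1, 1))
        s1 = extract_membrane_shell(grid, 1)
        s2 = extract_membrane_shell(grid, 2)
        assert (s1.shell_mask & s2.shell_mask).any()

    def test_missing_cell_raises(self):
        grid = VoxelGrid3D(np.ones((4, 4, 4), np.uint16), (1, 1, 1))
        with pytest.raises(KeyError):
            extract_membrane_shell(grid, 3)


class TestCavity:
    def test_planted_cavity_volume_within_5_percent(self):
        spec = SyntheticEmbryoSpec(n_cells=16, embryo_radius_um=40.0,
                                   spacing=(1, 1, 1), rng_seed=2)
        mem, _, _, truth = generate_blastocyst(spec, 30.0)
        _, vol = segment_cavity(mem, truth.embryo_mask)
        assert vol == pytest.approx(truth.cavity_volume_um3, rel=0.05)

    def test_compacted_embryo_has_no_cavity(self, small_embryo):
        mem, _, _, truth = small_embryo
        cav, vol = segment_cavity(mem, truth.embryo_mask)
        assert vol == 0.0
        assert not cav.data.any()

    def test_two_cavities_sum(self):
        spec = SyntheticEmbryoSpec(n_cells=32, embryo_radius_um=45.0,
                                   spacing=(1, 1, 1), rng_seed=4)
        mem, _, _, truth = generate_blastocyst(
            spec, [18.0, 16.0], [(0, -20, 0), (0, 20, 8)]
        )
        cav, vol = segment_cavity(mem, truth.embryo_mask)
        assert vol == pytest.approx(truth.cavity_volume_um3, rel=0.05)
        lbl, ncomp = ndimage.label(np.asarray(cav.data))
        assert ncomp == 2
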