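"""Sparse-field subjective-surface solver: initialization, physics, band
bookkeeping against the dense reference."""

import numpy as np
import pytest
from scipy import ndimage

from blastoseg.edges import EdgeMap, edge_detector
from blastoseg.imageio import VoxelGrid3D
from blastoseg.sparse_levelset import (
    GsubsurfParams,
    evolve,
    init_from_mask,
    init_from_seed,
    rasterize_ball,
    zero_set_mask,
)

from ._dense_reference import boundary_hausdorff, dense_evolve


def unit_edge(shape):
    return EdgeMap(np.ones(shape), (1, 1, 1), 0.0, 0.0)


def ball_mask(n, radius, center=None):
    c = (n / 2, n / 2, n / 2) if center is None else center
    return rasterize_ball(c, radius, (n, n, n), (1, 1, 1))


def volume_radius(mask):
    return (3 * mask.sum() / (4 * np.pi)) ** (1 / 3)


class TestInit:
    def test_ball_phi_approximates_signed_distance(self):
        mask = ball_mask(32, 10.0)
        fld = init_from_mask(mask)
        z, y, x = np.mgrid[:32, :32, :32]
        r = np.sqrt((z + 0.5 - 16) ** 2 + (y + 0.5 - 16) ** 2 + (x + 0.5 - 16) ** 2)
        L0 = fld.layers()[0]
        assert L0.any()
        assert np.max(np.abs(fld.phi[L0] - (r - 10.0)[L0])) < 1.0

    def test_single_voxel_mask_gives_minimal_front(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        fld = init_from_mask(mask)
        L0 = fld.layers()[0]
        assert L0[4, 4, 4]
        assert L0.sum() == 7  # voxel plus its 6-neighbourhood shell

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            init_from_mask(np.zeros((5, 5, 5), bool))
        with pytest.raises(ValueError, match="foreground"):
            init_from_mask(np.ones((5, 5, 5), bool))

    def test_layers_disjoint_and_banded(self):
        fld = init_from_mask(ball_mask(32, 10.0))
        layers = fld.layers()
        total = np.zeros((32, 32, 32), int)
        for k, m in layers.items():
            total += m
            if k != 0:
                a = np.abs(fld.phi[m])
                assert np.all(a > abs(k) - 0.5) and np.all(a <= abs(k) + 0.5)
        assert total.max() == 1  # pairwise disjoint

    def test_every_L0_voxel_has_opposite_sign_neighbour(self):
        fld = init_from_mask(ball_mask(32, 9.0))
        L0 = fld.layers()[0]
        inside = fld.phi < 0
        near_opposite = ndimage.binary_dilation(inside) & ndimage.binary_dilation(~inside)
        assert np.all(near_opposite[L0])

    def test_seed_rasterization_volume(self):
        fld = init_from_seed((16.5, 16.5, 16.5), 3.0, (32, 32, 32), (1, 1, 1))
        count = zero_set_mask(fld).sum()
        expected = 4 / 3 * np.pi * 27
        assert abs(count - expected) / expected < 0.15

    def test_seed_contract_errors(self):
        with pytest.raises(ValueError, match="outside"):
            init_from_seed((100, 16, 16), 3.0, (32, 32, 32), (1, 1, 1))
        with pytest.raises(ValueError, match="radius"):
            init_from_seed((16, 16, 16), 0.2, (32, 32, 32), (1, 1, 1))
        with pytest.raises(ValueError, match="fit"):
            init_from_seed((2, 16, 16), 5.0, (32, 32, 32), (1, 1, 1))

    def test_zero_set_mask_inverts_init(self):
        mask = ball_mask(24, 7.0)
        assert np.array_equal(zero_set_mask(init_from_mask(mask)), mask)


class TestFlowPhysics:
    def test_zero_edge_field_freezes_front(self):
        mask = ball_mask(24, 7.0)
        edge = EdgeMap(np.zeros((24, 24, 24)), (1, 1, 1), 0, 0)
        params = GsubsurfParams(w_a=2.0, w_d=1.0, delta=0.9, max_iters=30,
                                convergence_window=10**9)
        out, _ = evolve(init_from_mask(mask), edge, params)
        assert np.array_equal(zero_set_mask(out), mask)

    def test_curvature_flow_radius_law(self):
        mask = ball_mask(40, 15.0)
        fld = init_from_mask(mask)
        R0 = volume_radius(mask)
        params = GsubsurfParams(w_a=0, w_d=1.0, delta=0, tau=0.25, max_iters=1,
                                convergence_window=10**9)
        edge = unit_edge(mask.shape)
        for step in range(120):
            fld, _ = evolve(fld, edge, params)
            t = (step + 1) * params.tau
            Rth = np.sqrt(R0**2 - 4 * t)
            if Rth < 5:
                break
            if (step + 1) % 20 == 0:
                R = volume_radius(zero_set_mask(fld))
                assert R == pytest.approx(Rth, rel=0.05)

    def test_ballooning_constant_speed_growth(self):
        mask = ball_mask(40, 8.0)
        R0 = volume_radius(mask)
        delta, tau, steps = 0.5, 0.25, 48
        params = GsubsurfParams(w_a=0, w_d=0, delta=delta, tau=tau,
                                max_iters=steps, convergence_window=10**9)
        out, _ = evolve(init_from_mask(mask), unit_edge(mask.shape), params)
        Rth = R0 + delta * tau * steps
        assert volume_radius(zero_set_mask(out)) == pytest.approx(Rth, rel=0.05)

    def test_pure_curvature_volume_nonincreasing(self):
        fld = init_from_mask(ball_mask(32, 10.0))
        params = GsubsurfParams(w_a=0, w_d=0.5, delta=0, tau=0.25, max_iters=5,
                                convergence_window=10**9)
        edge = unit_edge((32, 32, 32))
        prev = zero_set_mask(fld).sum()
        for _ in range(8):
            fld, _ = evolve(fld, edge, params)
            cur = zero_set_mask(fld).sum()
            assert cur <= prev
            prev = cur

    def test_front_stops_on_membrane_shell(self):
        n = 48
        z, y, x = np.mgrid[:n, :n, :n]
        r = np.sqrt((z + 0.5 - n / 2) ** 2 + (y + 0.5 - n / 2) ** 2 + (x + 0.5 - n / 2) ** 2)
        rng = np.random.default_rng(0)
        img = 10 + 100 * np.exp(-((r - 15.0) ** 2) / 2) + rng.normal(0, 5, (n, n, n))
        edge = edge_detector(VoxelGrid3D(img, (1, 1, 1)), sigma=1.0, K=2500.0)
        fld = init_from_seed((n / 2, n / 2, n / 2), 3.0, (n, n, n), (1, 1, 1))
        params = GsubsurfParams(w_a=1.0, w_d=0.3, delta=0.8, tau=0.15,
                                max_iters=500, convergence_window=20)
        out, report = evolve(fld, edge, params)
        mask = zero_set_mask(out)
        assert report.converged
        # single 6-connected component
        _, ncomp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
        assert ncomp == 1
        # the front settles at the cytoplasm/membrane border: between the
        # inner flank of the ridge and its crest
        R = volume_radius(mask)
        assert 12.0 <= R <= 15.5

    def test_cfl_violation_rejected_before_iterating(self):
        mask = ball_mask(24, 7.0)
        params = GsubsurfParams(w_a=0, w_d=0, delta=3.0, tau=0.5, max_iters=5)
        with pytest.raises(ValueError, match="CFL"):
            evolve(init_from_mask(mask), unit_edge(mask.shape), params)

    def test_evolve_deterministic(self):
        mask = ball_mask(28, 8.0)
        params = GsubsurfParams(w_a=0, w_d=0.5, delta=0.3, tau=0.2, max_iters=25,
                                convergence_window=10**9)
        a, _ = evolve(init_from_mask(mask), unit_edge(mask.shape), params)
        b, _ = evolve(init_from_mask(mask), unit_edge(mask.shape), params)
        assert np.array_equal(a.phi, b.phi)


class TestAgainstDenseReference:
    @pytest.mark.parametrize(
        "name,w_a,w_d,delta",
        [
            ("curvature", 0.0, 0.5, 0.0),
            ("balloon", 0.0, 0.3, 0.6),
            ("deflate", 0.0, 0.3, -0.3),
        ],
    )
    def test_zero_sets_match_dense_solver(self, name, w_a, w_d, delta):
        n, tau, iters = 32, 0.15, 50
        mask = ball_mask(n, 8.0)
        g = np.ones((n, n, n))
        params = GsubsurfParams(w_a=w_a, w_d=w_d, delta=delta, tau=tau,
                                max_iters=iters, convergence_window=10**9)
        sparse, _ = evolve(init_from_mask(mask), EdgeMap(g, (1, 1, 1), 0, 0), params)
        dense_phi = dense_evolve(mask, g, w_a, w_d, delta, tau, iters)
        hd = boundary_hausdorff(zero_set_mask(sparse), dense_phi < 0)
        assert hd <= 1.0

    def test_zero_sets_match_with_real_edge_field(self):
        n, tau, iters = 32, 0.15, 50
        z, y, x = np.mgrid[:n, :n, :n]
        r = np.sqrt((z + 0.5 - 16) ** 2 + (y + 0.5 - 16) ** 2 + (x + 0.5 - 16) ** 2)
        img = 10 + 100 * np.exp(-((r - 11.0) ** 2) / 2)
        edge = edge_detector(VoxelGrid3D(img, (1, 1, 1)), sigma=1.0, K=2500.0)
        mask = ball_mask(n, 4.0)
        params = GsubsurfParams(w_a=1.0, w_d=0.3, delta=0.6, tau=tau,
                                max_iters=iters, convergence_window=10**9)
        sparse, _ = evolve(init_from_mask(mask), edge, params)
        dense_phi = dense_evolve(mask, edge.g, 1.0, 0.3, 0.6, tau, iters)
        assert boundary_hausdorff(zero_set_mask(sparse), dense_phi < 0) <= 1.0
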