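"""Independent dense reference solver for the subjective-surface flow.

A straightforward full-grid explicit solver with none of the narrow-band
bookkeeping of the package solver: signed distance initialized over the
whole volume (unclamped), every voxel updated every step, forward Euler.
Kept deliberately simple so it can serve as an oracle for the sparse-field
implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def dense_evolve(mask, g, w_a, w_d, delta, tau, iters, spacing=(1, 1, 1)):
    """Evolve the full-grid field and return φ after `iters` steps."""
    h = np.asarray(spacing, float) / min(spacing)
    din = ndimage.distance_transform_edt(mask, sampling=h)
    dout = ndimage.distance_transform_edt(~mask, sampling=h)
    phi = np.where(mask, -(din - 0.5), dout - 0.5)
    g = np.asarray(g, float)
    gg = np.gradient(g, *h)
    for _ in range(iters):
        Dm, Dp = [], []
        for ax in range(3):
            d = np.diff(phi, axis=ax) / h[ax]
            pl = [(0, 0)] * 3
            pl[ax] = (1, 0)
            ph = [(0, 0)] * 3
            ph[ax] = (0, 1)
            Dm.append(np.pad(d, pl))
            Dp.append(np.pad(d, ph))
        rhs = np.zeros_like(phi)
        if w_a != 0:
            for ax in range(3):
                a = -w_a * gg[ax]
                rhs -= a * np.where(a > 0, Dm[ax], Dp[ax])
        if delta != 0:
            speed = delta * g
            pos = speed > 0
            acc = np.zeros_like(phi)
            for dm, dp in zip(Dm, Dp):
                aa = np.where(pos, np.maximum(dm, 0), np.minimum(dm, 0))
                bb = np.where(pos, np.minimum(dp, 0), np.maximum(dp, 0))
                acc += np.maximum(aa**2, bb**2)
            rhs -= speed * np.sqrt(acc)
        if w_d != 0:
            fz, fy, fx = np.gradient(phi, *h)
            fzz = np.gradient(fz, h[0], axis=0)
            fzy = np.gradient(fz, h[1], axis=1)
            fzx = np.gradient(fz, h[2], axis=2)
            fyy = np.gradient(fy, h[1], axis=1)
            fyx = np.gradient(fy, h[2], axis=2)
            fxx = np.gradient(fx, h[2], axis=2)
            g2 = fz**2 + fy**2 + fx**2
            kg = (
                fzz * (fy**2 + fx**2)
                + fyy * (fz**2 + fx**2)
                + fxx * (fz**2 + fy**2)
                - 2 * fz * fy * fzy
                - 2 * fz * fx * fzx
                - 2 * fy * fx * fyx
            ) / (g2 + 1e-12)
            rhs += w_d * g * kg
        phi = phi + tau * rhs
    return phi


def boundary_hausdorff(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance (voxels) between two region boundaries."""
    ba = mask_a & ~ndimage.binary_erosion(mask_a)
    bb = mask_b & ~ndimage.binary_erosion(mask_b)
    if not ba.any() or not bb.any():
        return np.inf
    da = ndimage.distance_transform_edt(~ba)
    db = ndimage.distance_transform_edt(~bb)
    return float(max(db[ba].max(), da[bb].max()))
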