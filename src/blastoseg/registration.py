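"""Rigid drift/rotation compensation of nucleus centroid clouds.

Frame-to-frame embryo drift and rotation are estimated from matched nucleus
centroids (Kabsch) or correspondence-free by trimmed iterative closest point
(ICP), and original coordinates are recovered exactly with the inverse
transform.  Reflections are excluded; all transforms are proper rotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class RigidTransform:
    """q = R·p + t with R a proper rotation (det = +1)."""

    rotation: np.ndarray   # 3×3
    translation: np.ndarray  # (3,) μm

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError(f"improper rotation (det = {np.linalg.det(R):.6f})")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "RigidTransform":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def apply_inverse(transform: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Recover original coordinates: Rᵀ·(q − t)."""
    q = np.asarray(points, dtype=float)
    return (q - transform.translation) @ transform.rotation


def kabsch(P: np.ndarray, Q: np.ndarray, correspondence=None) -> RigidTransform:
    """Least-squares rigid transform minimizing Σ|R·p + t − q|² (no reflection).

    `correspondence` is an optional sequence of (i, j) index pairs matching
    P[i] to Q[j]; by default rows correspond positionally.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if correspondence is not None:
        pairs = np.asarray(correspondence, dtype=int)
        P = P[pairs[:, 0]]
        Q = Q[pairs[:, 1]]
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matched (n, 3) point sets")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 correspondences")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return RigidTransform(R, t)


def icp(
    P: np.ndarray,
    Q: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    trim_fraction: float = 0.2,
) -> tuple[RigidTransform, float, bool]:
    """Trimmed ICP aligning P onto Q without known correspondences.

    Alternates nearest-neighbour matching (keeping the best
    ``1 − trim_fraction`` matches, robust to nuclei appearing/disappearing at
    divisions) with a Kabsch fit, until the trimmed RMSD improves by less
    than `tol`.  Returns (transform, rmsd, converged); non-convergence is a
    flag, not an exception.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape[0] < 4 or Q.shape[0] < 4:
        raise ValueError("both clouds need at least 4 points")
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must be in [0, 1)")
    tree = cKDTree(Q)
    transform = RigidTransform.identity()
    n_keep = max(3, int(round(P.shape[0] * (1 - trim_fraction))))
    prev_rmsd = np.inf
    rmsd = np.inf
    converged = False
    for _ in range(max_iter):
        moved = transform.apply(P)
        dists, idx = tree.query(moved)
        keep = np.argsort(dists)[:n_keep]
        rmsd = float(np.sqrt(np.mean(dists[keep] ** 2)))
        if prev_rmsd - rmsd < tol:
            converged = True
            break
        prev_rmsd = rmsd
        transform = kabsch(P[keep], Q[idx[keep]])
    return transform, rmsd, converged
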