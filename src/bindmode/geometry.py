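"""Rigid-body superposition (Kabsch) and RMSD primitives."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "kabsch", "rmsd", "pairwise_rmsd_matrix",
           "random_rigid_transform"]


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ (x - centroid_mobile) + centroid_ref + shift."""

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the transform and the residual RMSD. Requires >= 3 non-collinear
    correspondence points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"shape mismatch {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 correspondence atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("correspondence atoms are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    fitted = P @ R.T + t
    return RigidTransform(R, t), rmsd(fitted, Q)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Coordinate RMSD without refitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def pairwise_rmsd_matrix(blocks: np.ndarray) -> np.ndarray:
    """Pairwise no-refit RMSD over an (m, n_atoms, 3) stack of blocks."""
    X = np.asarray(blocks, dtype=float)
    m = X.shape[0]
    flat = X.reshape(m, -1)
    # RMSD_ij = |x_i - x_j|_2 / sqrt(n_atoms)
    sq = np.sum(flat ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
    np.maximum(d2, 0.0, out=d2)
    mat = np.sqrt(d2 / X.shape[1])
    np.fill_diagonal(mat, 0.0)
    return 0.5 * (mat + mat.T)


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 10.0) -> RigidTransform:
    """Uniform random rotation (QR-based) plus a bounded random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(Q, t)
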