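"""Least-squares rigid-body superposition and rotation analysis.

The fit is the closed-form Kabsch solution: SVD of the cross-covariance of
the centered point sets, with the sign of the smallest singular vector
flipped when needed so that only proper rotations (det = +1, no reflection)
are returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientAtomsError, NoOverlapError
from .model import Selection


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float,
                        translation=(0.0, 0.0, 0.0),
                        center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``center``,
        followed by ``translation`` (Rodrigues formula)."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        th = np.radians(angle_deg)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
        center = np.asarray(center, dtype=float)
        trans = np.asarray(translation, dtype=float) + center - rot @ center
        return cls(rot, trans)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_matched: int


def kabsch_fit(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares proper rotation + translation mapping ``moving`` onto
    ``fixed`` (row-paired N x 3 matrices), with post-fit RMSD.

    Raises :class:`InsufficientAtomsError` below 3 pairs and warns on
    degenerate (rank-deficient / collinear) input.
    """
    A = np.asarray(moving, dtype=float)
    B = np.asarray(fixed, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise InsufficientAtomsError(f"need >= 3 paired atoms, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        warnings.warn("near-collinear input; rotation poorly conditioned")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t)
    rmsd = rmsd_noalign(transform.apply(A), B)
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_matched=n)


def match_residues(sel_a: Selection, sel_b: Selection) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms of two selections by (seq_id, atom_name), ordered by
    seq_id, and return the paired coordinate matrices."""
    key_a = {(r.seq_id, a.atom_name): a.coords for _, r, a in sel_a}
    key_b = {(r.seq_id, a.atom_name): a.coords for _, r, a in sel_b}
    common = sorted(set(key_a) & set(key_b))
    if not common:
        raise NoOverlapError("selections share no (seq_id, atom_name) pairs")
    return (np.array([key_a[k] for k in common]),
            np.array([key_b[k] for k in common]))


def rotation_angle(transform: RigidTransform) -> float:
    """Total rotation magnitude in degrees, θ = arccos((tr R − 1)/2) ∈ [0, 180]."""
    c = (np.trace(transform.rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rmsd_noalign(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square per-row distance without any fitting."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
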