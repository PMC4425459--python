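"""Pose parameterization: six-component descriptors and rigid transforms.

A pose is a point in the six-dimensional search space (tx, ty, tz) in
angstroms plus (rx, ry, rz) in radians.  Rotation uses the fixed-axis
(extrinsic) X-then-Y-then-Z convention, R = Rz(rz) @ Ry(ry) @ Rx(rx),
applied about a pivot (the ligand centroid), then translated:

    p' = R @ (p - pivot) + pivot + t
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransformDescriptor",
    "RigidTransform",
    "SearchSpace",
    "build_transform",
    "apply_transform",
    "rotation_matrix",
]


@dataclass(frozen=True)
class TransformDescriptor:
    """Six-float pose index: translations in angstrom, rotations in radians.

    Angles are stored unwrapped; no modular normalization is applied.
    """

    tx: float
    ty: float
    tz: float
    rx: float
    ry: float
    rz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz,
                         self.rx, self.ry, self.rz], dtype=np.float64)

    @classmethod
    def from_array(cls, a) -> "TransformDescriptor":
        a = np.asarray(a, dtype=np.float64)
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class RigidTransform:
    """A rotation about ``pivot`` followed by a translation ``t``."""

    R: np.ndarray      # (3, 3) orthonormal, det +1
    t: np.ndarray      # (3,) angstrom
    pivot: np.ndarray  # (3,) angstrom


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box of translations plus per-axis rotation bounds."""

    center: np.ndarray       # (3,) angstrom
    half_extent: np.ndarray  # (3,) angstrom, >= 0
    angle_lo: np.ndarray     # (3,) radians
    angle_hi: np.ndarray     # (3,) radians

    def __post_init__(self):
        for name in ("center", "half_extent", "angle_lo", "angle_hi"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(self.half_extent < 0):
            raise ValueError("half_extent must be >= 0 componentwise")
        if np.any(self.angle_lo > self.angle_hi):
            raise ValueError("angle_lo must be <= angle_hi")


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Extrinsic X-Y-Z rotation: R = Rz(rz) @ Ry(ry) @ Rx(rx)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]], dtype=np.float64)
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]], dtype=np.float64)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]], dtype=np.float64)
    return Rz @ Ry @ Rx


def build_transform(td: TransformDescriptor, pivot) -> RigidTransform:
    """Realize a descriptor as a rigid transform about ``pivot``."""
    a = td.as_array()
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite transform descriptor: {td}")
    pivot = np.asarray(pivot, dtype=np.float64)
    if pivot.shape != (3,) or not np.all(np.isfinite(pivot)):
        raise ValueError("pivot must be a finite 3-vector")
    R = rotation_matrix(td.rx, td.ry, td.rz)
    t = a[:3].copy()
    return RigidTransform(R=R, t=t, pivot=pivot)


def apply_transform(tf: RigidTransform, coords) -> np.ndarray:
    """Apply p -> R(p - pivot) + pivot + t to an (n, 3) coordinate array.

    Rigid: all intra-molecular distances are preserved (up to fp rounding).
    """
    c = np.asarray(coords, dtype=np.float64)
    if c.size and not np.all(np.isfinite(c)):
        raise ValueError("non-finite coordinates")
    return (c - tf.pivot) @ tf.R.T + tf.pivot + tf.t


def pose_error(td_a: TransformDescriptor,
               td_b: TransformDescriptor) -> tuple[float, np.ndarray]:
    """Compare two poses: (translation error in A, per-axis angle error in deg).

    The angular part decomposes the *relative* rotation R_a R_b^T back
    into extrinsic X-Y-Z angles, so equivalent Euler representations of
    the same rotation compare as equal instead of differing by pi flips.
    """
    dt = float(np.linalg.norm([td_a.tx - td_b.tx, td_a.ty - td_b.ty,
                               td_a.tz - td_b.tz]))
    rel = (rotation_matrix(td_a.rx, td_a.ry, td_a.rz)
           @ rotation_matrix(td_b.rx, td_b.ry, td_b.rz).T)
    ry = -np.arcsin(np.clip(rel[2, 0], -1.0, 1.0))
    rx = np.arctan2(rel[2, 1], rel[2, 2])
    rz = np.arctan2(rel[1, 0], rel[0, 0])
    return dt, np.rad2deg(np.abs([rx, ry, rz]))


def rotation_matrices(rx: np.ndarray, ry: np.ndarray, rz: np.ndarray) -> np.ndarray:
    """Vectorized extrinsic X-Y-Z rotations: (n, 3, 3) for angle arrays."""
    rx = np.asarray(rx, dtype=np.float64)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(np.asarray(ry, dtype=np.float64)), np.sin(np.asarray(ry, dtype=np.float64))
    cz, sz = np.cos(np.asarray(rz, dtype=np.float64)), np.sin(np.asarray(rz, dtype=np.float64))
    R = np.empty(rx.shape + (3, 3), dtype=np.float64)
    # rows of Rz @ Ry @ Rx, expanded
    R[..., 0, 0] = cz * cy
    R[..., 0, 1] = cz * sy * sx - sz * cx
    R[..., 0, 2] = cz * sy * cx + sz * sx
    R[..., 1, 0] = sz * cy
    R[..., 1, 1] = sz * sy * sx + cz * cx
    R[..., 1, 2] = sz * sy * cx - cz * sx
    R[..., 2, 0] = -sy
    R[..., 2, 1] = cy * sx
    R[..., 2, 2] = cy * cx
    return R
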