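"""Rigid 3D landmark registration of the stack to the reference volume.

The reconstructed stack is matched to the tomographic reference (the CBCT
surrogate) through paired landmarks: samples of the fitted cannula lines
and, when available, groove points.  The closed-form least-squares rigid
fit (Horn/Kabsch: SVD of the cross-covariance of the centered point sets,
sign-corrected to determinant +1) never returns a reflection.  Fit quality
is summarised by the fiducial registration error (FRE), the RMS distance
between matched landmarks after the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RigidTransform3D:
    """Proper rigid motion ``x -> R x + t`` (R orthonormal, det +1)."""

    rotation: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("reflections are not rigid motions (det must be +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation_mm", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation.T + self.translation_mm
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "RigidTransform3D":
        return RigidTransform3D(self.rotation.T, -self.rotation.T @ self.translation_mm)

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        return RigidTransform3D(
            self.rotation @ other.rotation,
            self.rotation @ other.translation_mm + self.translation_mm,
        )

    def matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation_mm
        return m

    @staticmethod
    def from_matrix4(m: np.ndarray) -> "RigidTransform3D":
        m = np.asarray(m, dtype=float)
        return RigidTransform3D(m[:3, :3], m[:3, 3])


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def register_landmarks(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[RigidTransform3D, float]:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed``.

    Both are matched (N, 3) point sets with N >= 3, not collinear (rotation
    about the common line would be unidentifiable).  Returns the transform
    and the FRE in mm.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(
            f"point counts differ: moving {moving.shape} vs fixed {fixed.shape}"
        )
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ValueError("need matched (N, 3) arrays with N >= 3")
    if _collinear(moving) or _collinear(fixed):
        raise ValueError("landmarks are collinear; rotation is unidentifiable")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = fc - rot @ mc
    transform = RigidTransform3D(rot, t)
    fre = float(np.sqrt(np.mean(np.sum((transform.apply(moving) - fixed) ** 2, axis=1))))
    return transform, fre


def sample_lines(lines: list[dict], z_values) -> np.ndarray:
    """Sample 3D lines ``{point_mm, direction}`` at given z planes.

    Returns (len(lines) * len(z_values), 3) points ordered line-major.
    """
    pts = []
    for line in lines:
        p = np.asarray(line["point_mm"], dtype=float)
        d = np.asarray(line["direction"], dtype=float)
        if abs(d[2]) < 1e-12:
            raise ValueError("line parallel to the section planes cannot be sampled by z")
        for z in z_values:
            s = (z - p[2]) / d[2]
            pts.append(p + s * d)
    return np.asarray(pts)


def extract_stack_landmarks(
    lines: list[dict], z_mm: np.ndarray, groove_points: np.ndarray | None = None
) -> np.ndarray:
    """Landmarks of an aligned stack: fitted cannula lines sampled at the
    first, middle and last section planes (9 points), plus optional groove
    points."""
    if not lines:
        raise ValueError("no fitted fiducial lines available")
    z = np.asarray(z_mm, dtype=float)
    z_samples = [z.min(), float(np.median(z)), z.max()]
    pts = sample_lines(lines, z_samples)
    if groove_points is not None and len(groove_points):
        pts = np.vstack([pts, np.asarray(groove_points, dtype=float)])
    return pts
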