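"""Rigid 2D transforms and the planar Procrustes (Kabsch) fit.

Angle convention
----------------
Physical coordinates are ``x = col * spacing_x`` and ``y = row * spacing_y``
(y grows *down* the image).  Orientation angles are measured
counterclockwise in the frame whose vertical axis points *up*, so a CCW
rotation by ``theta`` acts on (x, y) column vectors as::

    M(theta) = [[ cos t,  sin t],
                [-sin t,  cos t]]

All angles are degrees, all lengths millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def rotation_matrix_2d(theta_deg: float) -> np.ndarray:
    """CCW (up-frame) rotation matrix acting on image-frame (x, y) vectors."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s], [-s, c]])


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion ``x -> M(rotation) (x - center) + center + translation``.

    ``center_mm`` is the rotation pivot (typically the section image centre);
    it is part of the parameterisation, not of the group element: two
    transforms with different centers may describe the same motion.
    """

    rotation_deg: float
    translation_mm: tuple[float, float]
    center_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix_2d(self.rotation_deg)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 2) array of mm coordinates."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center_mm, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        out = (p - c) @ self.matrix.T + c + t
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "RigidTransform2D":
        t = np.asarray(self.translation_mm, dtype=float)
        t_inv = -self.matrix.T @ t
        return RigidTransform2D(-self.rotation_deg, tuple(t_inv), self.center_mm)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return ``self o other`` (other applied first), centered at ``self.center_mm``."""
        c = np.asarray(self.center_mm, dtype=float)
        t = self.apply(other.apply(c)) - c
        return RigidTransform2D(
            self.rotation_deg + other.rotation_deg, tuple(t), self.center_mm
        )

    @staticmethod
    def identity(center_mm: tuple[float, float] = (0.0, 0.0)) -> "RigidTransform2D":
        return RigidTransform2D(0.0, (0.0, 0.0), center_mm)


def kabsch_2d(
    src: np.ndarray, dst: np.ndarray, center_mm: tuple[float, float] = (0.0, 0.0)
) -> RigidTransform2D:
    """Least-squares rigid transform mapping ``src`` onto ``dst``.

    Closed-form planar Procrustes: SVD of the cross-covariance of the
    centered point sets, with the singular-vector sign corrected so the
    returned rotation is proper (no reflection).  Needs >= 2 points.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (N, 2) arrays")
    if src.shape[0] < 2:
        raise ValueError("rigid 2D fit needs at least 2 point pairs")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, d]) @ u.T  # maps src-frame to dst-frame
    # rot acts as x -> rot @ x; recover the up-frame CCW angle from our
    # M(theta) parameterisation (M[0, 1] = sin, M[0, 0] = cos).
    theta = np.rad2deg(np.arctan2(rot[0, 1], rot[0, 0]))
    c = np.asarray(center_mm, dtype=float)
    t = dc - rot @ sc - c + rot @ c
    return RigidTransform2D(theta, tuple(t), tuple(c))


def normalize_transform_gauge(
    transforms: list[RigidTransform2D],
    z_mm: np.ndarray,
    detrend_rotation: bool = True,
) -> list[RigidTransform2D]:
    """Fix the gauge of a per-section transform family.

    A stack of fiducial tracks determines the per-section transforms only up
    to (a) one global rigid motion and (b) a translation drift linear in z
    (straight fiducial lines absorb both exactly).  A rotation ramp linear in
    z is additionally a *soft* mode: to first order in the angle it tilts the
    lines without bending them.  This helper removes all of them:

    1. subtract the mean rotation (global rotation gauge),
    2. rotate translations accordingly, then subtract the least-squares
       linear trend of translation vs z (global translation + drift gauge),
    3. optionally subtract the linear trend of rotation vs z (soft twist
       mode; the sectioning perturbations being modelled are zero-mean and
       trend-free, so the detrended estimate is the identifiable part).

    Ground-truth comparisons must pass the true transforms through the same
    normalisation.  All transforms must share the same rotation center.
    """
    if not transforms:
        return []
    centers = {t.center_mm for t in transforms}
    if len(centers) != 1:
        raise ValueError("gauge normalisation requires a common rotation center")
    z = np.asarray(z_mm, dtype=float)
    theta = np.array([t.rotation_deg for t in transforms])
    trans = np.array([t.translation_mm for t in transforms])

    gamma = -theta.mean()
    theta = theta + gamma
    trans = trans @ rotation_matrix_2d(gamma).T

    a = np.vstack([np.ones_like(z), z]).T
    coef, *_ = np.linalg.lstsq(a, trans, rcond=None)
    trans = trans - a @ coef
    if detrend_rotation:
        coef_r, *_ = np.linalg.lstsq(a, theta, rcond=None)
        theta = theta - a @ coef_r
    center = transforms[0].center_mm
    return [
        RigidTransform2D(float(th), (float(tx), float(ty)), center)
        for th, (tx, ty) in zip(theta, trans)
    ]
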