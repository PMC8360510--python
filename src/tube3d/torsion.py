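"""Cartilage orientation per section and total helical torsion.

Each section's cartilage orientation is the direction of the major
principal axis of its binary mask, from second central moments, reported
counterclockwise (up-frame) in (-90, 90].  Orientations live on a
180-degree-periodic circle, so successive sections are unwrapped by
multiples of 180 before the axial trend is read off.  The total torsion is
the difference of the unwrapped orientation between the last and first
reliable sections; a least-absolute-deviations line fit of orientation vs
z provides the slope and goodness of fit.

Sections whose moment ellipse is nearly isotropic (anisotropy ratio below
1.05) carry no usable orientation and are excluded from the fit, with
their unwrap step bridged like a lost-section gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import LabelVolume


def slice_orientation(
    mask: np.ndarray, spacing_mm: tuple[float, float] = (1.0, 1.0)
) -> tuple[float, float]:
    """Principal-axis orientation (deg, CCW up-frame, (-90, 90]) and
    anisotropy ratio sqrt(lambda1/lambda2) of a binary mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no orientation")
    r, c = np.nonzero(mask)
    sx, sy = spacing_mm
    x = c * sx
    y_up = -r * sy                      # physical frame with y pointing up
    x = x - x.mean()
    y_up = y_up - y_up.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y_up * y_up)
    mu11 = np.mean(x * y_up)
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    if theta <= -90.0:
        theta += 180.0
    common = np.hypot(mu20 - mu02, 2 * mu11)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    ratio = float(np.sqrt(lam1 / lam2)) if lam2 > 0 else np.inf
    return float(theta), ratio


def unwrap_orientations(
    theta_deg: np.ndarray, gaps: np.ndarray | None = None
) -> np.ndarray:
    """Unwrap a 180-degree-periodic orientation sequence.

    Each successive value is shifted by the multiple of 180 that minimises
    the step magnitude.  ``gaps`` gives the index distance between
    consecutive entries (>= 1); a step that is ambiguous — within 1e-9 of
    90 degrees per unit gap — raises, naming the pair.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if theta.ndim != 1:
        raise ValueError("expected a 1D orientation sequence")
    if gaps is None:
        gaps = np.ones(len(theta) - 1)
    gaps = np.asarray(gaps, dtype=float)
    out = theta.copy()
    for i in range(1, len(theta)):
        step = theta[i] - out[i - 1]
        adj = step - 180.0 * np.round(step / 180.0)
        if abs(abs(adj) - 90.0 * gaps[i - 1]) < 1e-9 and abs(adj) >= 90.0 - 1e-9:
            raise ValueError(
                f"ambiguous 90-degree orientation step between entries "
                f"{i - 1} and {i}"
            )
        out[i] = out[i - 1] + adj
    return out


def _lad_line(z: np.ndarray, y: np.ndarray, n_iter: int = 60) -> tuple[float, float]:
    """Least-absolute-deviations line fit via IRLS; returns (intercept, slope)."""
    A = np.vstack([np.ones_like(z), z]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    for _ in range(n_iter):
        r = np.abs(y - A @ coef)
        w = 1.0 / np.maximum(r, 1e-8)
        wa = A * w[:, None]
        coef_new = np.linalg.solve(wa.T @ A, wa.T @ y)
        if np.max(np.abs(coef_new - coef)) < 1e-12:
            coef = coef_new
            break
        coef = coef_new
    return float(coef[0]), float(coef[1])


@dataclass
class TorsionEstimate:
    """Per-section orientations and the total unwrapped twist."""

    table: pd.DataFrame                # section_index, z_mm, theta_deg, ...
    total_torsion_deg: float
    fit_slope_deg_per_mm: float
    fit_r2: float

    def summary(self) -> dict:
        return {
            "total_torsion_deg": self.total_torsion_deg,
            "fit_slope_deg_per_mm": self.fit_slope_deg_per_mm,
            "fit_r2": self.fit_r2,
            "n_sections": int(len(self.table)),
        }


def total_torsion(
    stack: LabelVolume,
    label: str = "cartilage",
    min_anisotropy: float = 1.05,
    min_sections: int = 5,
) -> TorsionEstimate:
    """Estimate the total helical torsion of one compartment along the stack.

    Orientation is measured in every section where the compartment is
    present; near-isotropic sections are flagged unreliable and excluded
    from the unwrap and the LAD fit (their step is bridged across the gap).
    The total is the endpoint difference of the unwrapped orientation;
    reversing the section order negates it exactly.
    """
    sx, sy, period = stack.spacing_mm
    missing = set(stack.metadata.get("missing_sections", []))
    rows = []
    for k in range(stack.n_slices):
        if k in missing:
            continue
        mask = stack.voxels[k] == stack.label_scheme[label]
        if not mask.any():
            continue
        theta, ratio = slice_orientation(mask, (sx, sy))
        rows.append((k, stack.origin_mm[2] + k * period, theta, ratio))
    if not rows:
        raise ValueError(f"no sections contain label {label!r}")
    df = pd.DataFrame(rows, columns=["section_index", "z_mm", "theta_deg",
                                     "anisotropy_ratio"])
    df["reliable"] = df["anisotropy_ratio"] >= min_anisotropy
    rel = df[df["reliable"]]
    if len(rel) < min_sections:
        raise ValueError(
            f"only {len(rel)} sections have a reliable orientation "
            f"(need {min_sections})"
        )
    idx = rel["section_index"].to_numpy()
    gaps = np.diff(idx).astype(float)
    unwrapped = unwrap_orientations(rel["theta_deg"].to_numpy(), gaps)
    df["theta_unwrapped_deg"] = np.nan
    df.loc[df["reliable"], "theta_unwrapped_deg"] = unwrapped
    # interpolate unreliable sections through the unwrap for completeness
    df["theta_unwrapped_deg"] = df["theta_unwrapped_deg"].interpolate()

    z = rel["z_mm"].to_numpy()
    intercept, slope = _lad_line(z, unwrapped)
    pred = intercept + slope * z
    ss_res = float(np.sum((unwrapped - pred) ** 2))
    ss_tot = float(np.sum((unwrapped - unwrapped.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    total = float(unwrapped[-1] - unwrapped[0])
    return TorsionEstimate(
        table=df,
        total_torsion_deg=total,
        fit_slope_deg_per_mm=slope,
        fit_r2=r2,
    )
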