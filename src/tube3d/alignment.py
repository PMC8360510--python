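"""Fiducial-based slice realignment and stack assembly.

The three embedded needles are straight in 3D, so their per-section
centroids must fall on three straight lines once every section is rigidly
re-positioned in-plane.  The fit jointly estimates three 3D lines and one
rigid 2D transform per section by minimising the sum of squared in-plane
distances between the transformed detections and the intersection of each
line with the section plane.  Block coordinate descent alternates two exact
sub-problems:

* transforms given lines — planar Procrustes per section;
* lines given transforms — per fiducial, a linear least-squares fit of
  ``x(z) = a + b z`` and ``y(z) = c + d z`` (the exact minimiser of the
  in-plane cost for a line parameterised over z).

The cost is non-increasing per iteration and the iteration stops at a
relative change below 1e-10 (or 200 iterations).  The solution is only
defined up to one global rigid motion plus linear-in-z drift/twist modes
(see ``transforms.normalize_transform_gauge``); the returned transforms are
gauge-normalised to mean-zero, trend-free rotation and translation.

Corrected z positions come from the groove-thickness readings: the mean of
the three readings dates each cut; the plane through the three groove
points estimates the cutting-plane tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import LABELS
from .phantom import LabelVolume
from .sectioning import ProtocolSpec, SectionImage, warp_labels
from .transforms import RigidTransform2D, kabsch_2d, normalize_transform_gauge


# --------------------------------------------------------------------------
# detection

@dataclass
class Detections:
    """Fiducial detections in one section (unordered, mm coordinates)."""

    section_index: int
    centroids_mm: np.ndarray            # (k, 2)
    areas_mm2: np.ndarray | None = None # (k,)
    unalignable: bool = False


def detect_fiducials(
    section: SectionImage, needle_radius_mm: float = 0.45
) -> Detections:
    """Centroids of plausible needle cross-sections in a section.

    Connected components of the fiducial label whose area lies within
    [25%, 400%] of the expected needle cross-section (pi r^2; section
    obliquity changes this by <1% at the permitted needle angles) are kept;
    centroids are sub-pixel centers of mass.  Zero or more than three
    plausible components flag the section unalignable.
    """
    mask = section.labels == section.label_scheme["fiducial"]
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sx, sy = section.spacing_mm
    px_area = sx * sy
    expected = np.pi * needle_radius_mm ** 2
    cents, areas = [], []
    for comp in range(1, n + 1):
        m = lab == comp
        area = m.sum() * px_area
        if not (0.25 * expected <= area <= 4.0 * expected):
            continue
        r, c = ndimage.center_of_mass(m)
        cents.append((c * sx, r * sy))
        areas.append(area)
    cents = np.asarray(cents, dtype=float).reshape(-1, 2)
    bad = not (1 <= len(cents) <= 3)
    return Detections(section.section_index, cents, np.asarray(areas), unalignable=bad)


@dataclass
class FiducialTracks:
    """Corresponded fiducial coordinates across sections.

    ``coords_mm[i, j]`` is the 2D position of fiducial ``j`` in the i-th
    kept section (NaN where undetected); rows follow ``section_indices``.
    """

    section_indices: np.ndarray        # (n,)
    coords_mm: np.ndarray              # (n, 3, 2), NaN = missing
    unalignable: np.ndarray            # (n,) bool

    @property
    def n_sections(self) -> int:
        return len(self.section_indices)

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.coords_mm[..., 0])


def correspond_tracks(
    detections: list[Detections], ambiguity_tol_mm: float = 1e-3
) -> FiducialTracks:
    """Assign consistent fiducial ids across sections.

    Detections in each section are first sorted lexicographically (order
    invariance); ids are seeded on the first fully-detected section (sorted
    order -> ids 0..2) and propagated frame-to-frame by optimal assignment
    (Hungarian on pairwise distances to the most recent localisation of each
    track).  Near-ties within ``ambiguity_tol_mm`` of equal cost emit a
    warning but resolve deterministically (smallest id).
    """
    from scipy.optimize import linear_sum_assignment
    import warnings

    if sum(1 for d in detections if len(d.centroids_mm) >= 2) < 2:
        raise ValueError("need >= 2 sections with >= 2 detections to correspond")

    n = len(detections)
    coords = np.full((n, 3, 2), np.nan)
    flags = np.zeros(n, dtype=bool)
    order = np.argsort([d.section_index for d in detections])
    detections = [detections[i] for i in order]

    anchor = next(
        (i for i, d in enumerate(detections) if not d.unalignable and len(d.centroids_mm) == 3),
        next(i for i, d in enumerate(detections) if not d.unalignable),
    )
    last = {}  # fid id -> last seen position
    seq = list(range(anchor, n)) + list(range(anchor - 1, -1, -1))
    for step, i in enumerate(seq):
        d = detections[i]
        flags[i] = d.unalignable
        pts = d.centroids_mm
        if d.unalignable or len(pts) == 0:
            continue
        key = np.lexsort((pts[:, 1], pts[:, 0]))
        pts = pts[key]
        if i == anchor:
            for j, p in enumerate(pts):
                coords[i, j] = p
                last[j] = p
            continue
        if step == n - anchor:       # restarting backwards from the anchor
            last = {j: coords[anchor, j] for j in range(3) if not np.isnan(coords[anchor, j, 0])}
        ids = sorted(last)
        ref = np.array([last[j] for j in ids])
        cost = np.linalg.norm(pts[:, None, :] - ref[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        total = cost[rows, cols].sum()
        # ambiguity check: second-best assignment within tolerance
        if cost.shape[0] >= 2 and cost.shape[1] >= 2:
            alt = cost.copy()
            alt[rows[0], cols[0]] = np.inf
            r2, c2 = linear_sum_assignment(alt)
            if abs(alt[r2, c2].sum() - total) < ambiguity_tol_mm:
                warnings.warn(
                    f"ambiguous fiducial correspondence at section "
                    f"{d.section_index}; using deterministic tie-break"
                )
        for r, c in zip(rows, cols):
            fid = ids[c]
            coords[i, fid] = pts[r]
            last[fid] = pts[r]
        # unmatched new detections start fresh tracks if an id is free
        unmatched = set(range(len(pts))) - set(rows)
        free = [j for j in range(3) if j not in last]
        for r, fid in zip(sorted(unmatched), free):
            coords[i, fid] = pts[r]
            last[fid] = pts[r]

    return FiducialTracks(
        section_indices=np.array([d.section_index for d in detections]),
        coords_mm=coords,
        unalignable=flags,
    )


# --------------------------------------------------------------------------
# joint line / transform fit

@dataclass
class AlignmentResult:
    """Per-section recovered transforms plus fit diagnostics."""

    section_indices: np.ndarray
    transforms: list[RigidTransform2D]
    z_mm: np.ndarray
    lines: list[dict]                  # per fiducial: {point_mm, direction}
    residuals: pd.DataFrame            # section, fiducial, dx, dy, norm
    cost_history: np.ndarray
    interpolated: np.ndarray           # bool per section
    noise_sigma_mm: float              # dof-corrected residual scale
    converged: bool = True

    @property
    def rms_residual_mm(self) -> float:
        """RMS of residual vector norms over all detections."""
        if len(self.residuals) == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.residuals["norm"] ** 2)))


def _line_targets(lines_ab: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Intersections of 3 lines (x=a+bz, y=c+dz) with each section plane.

    lines_ab: (3, 4) rows (a, b, c, d); returns (n, 3, 2).
    """
    a, b, c, d = lines_ab.T
    x = a[None, :] + np.outer(z, b)
    y = c[None, :] + np.outer(z, d)
    return np.stack([x, y], axis=-1)


def fit_stack_alignment(
    tracks: FiducialTracks,
    z_mm: np.ndarray,
    center_mm: tuple[float, float] = (0.0, 0.0),
    max_iter: int = 200,
    tol: float = 1e-10,
) -> AlignmentResult:
    """Jointly fit three straight fiducial lines and per-section transforms.

    Sections with fewer than two usable detections do not constrain the fit;
    their transforms are linearly interpolated from neighbours afterwards
    and flagged.  Requires >= 3 sections with >= 2 fiducials present in at
    least 80% of them.
    """
    z = np.asarray(z_mm, dtype=float)
    coords = tracks.coords_mm
    n = tracks.n_sections
    if n < 3:
        raise ValueError("need at least 3 sections to fit a stack alignment")
    valid = tracks.valid_mask() & ~tracks.unalignable[:, None]
    usable = valid.sum(axis=1) >= 2
    if usable.mean() < 0.8:
        raise ValueError(
            f"only {int(usable.sum())}/{n} sections have >= 2 usable fiducials"
        )
    for j in range(3):
        if valid[:, j].sum() < 2:
            raise ValueError(f"fiducial {j} detected in fewer than 2 sections")

    thetas = np.zeros(n)
    trans = np.zeros((n, 2))

    def apply_all(th, tr):
        out = np.full_like(coords, np.nan)
        c = np.asarray(center_mm)
        for i in range(n):
            t = np.deg2rad(th[i])
            m = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
            out[i] = (coords[i] - c) @ m.T + c + tr[i]
        return out

    def fit_lines(pts):
        lines = np.zeros((3, 4))
        for j in range(3):
            m = valid[:, j]
            A = np.vstack([np.ones(m.sum()), z[m]]).T
            cx, *_ = np.linalg.lstsq(A, pts[m, j, 0], rcond=None)
            cy, *_ = np.linalg.lstsq(A, pts[m, j, 1], rcond=None)
            lines[j] = (cx[0], cx[1], cy[0], cy[1])
        return lines

    usable_idx = {i: k for k, i in enumerate(np.where(usable)[0])}
    n_use = len(usable_idx)
    rows = [(i, j) for i in usable_idx for j in range(3) if valid[i, j]]
    design = np.zeros((len(rows), n_use + 6))
    for r, (i, j) in enumerate(rows):
        design[r, usable_idx[i]] = 1.0
        design[r, n_use + j] = -1.0
        design[r, n_use + 3 + j] = -z[i]

    def solve_translations_and_lines(th, tr, lines):
        """Exact joint LS for translations and lines at fixed rotations.

        The slowly-converging directions of plain alternation (translation
        drift chased by line tilt) live entirely in this linear sub-problem,
        so solving it in closed form per iteration leaves only the
        well-conditioned rotation block to alternate over.  lstsq returns
        the minimum-norm solution across the gauge null space.
        """
        c = np.asarray(center_mm)
        rotated = np.full_like(coords, np.nan)
        for i in usable_idx:
            t = np.deg2rad(th[i])
            m = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
            rotated[i] = (coords[i] - c) @ m.T + c
        for axis in range(2):
            y = np.array([-rotated[i, j, axis] for (i, j) in rows])
            sol, *_ = np.linalg.lstsq(design, y, rcond=None)
            for i, k in usable_idx.items():
                tr[i, axis] = sol[k]
            lines[:, 2 * axis] = sol[n_use:n_use + 3]
            lines[:, 2 * axis + 1] = sol[n_use + 3:]
        return tr, lines

    def total_cost(pts, lines):
        tgt = _line_targets(lines, z)
        r = pts - tgt
        return float(np.nansum(r[valid] ** 2))

    def gauss_newton_step(th, tr, lines):
        """One joint linearised step over (rotations, translations, lines).

        The per-section rotations are the only nonlinearity; one lstsq over
        the *increments* of all parameters solves the locally quadratic
        model (the increment formulation matters: with min-norm lstsq the
        gauge null space contributes a zero increment instead of a jump
        along the soft rotation-ramp direction, which would break the
        linearisation).  Used as an accelerator: the caller adopts the step
        only when it lowers the exact cost, keeping the descent monotone.
        """
        c = np.asarray(center_mm)
        n_rows = 2 * len(rows)
        a_mat = np.zeros((n_rows, 3 * n_use + 12))
        rhs = np.zeros(n_rows)
        for r_i, (i, j) in enumerate(rows):
            t = np.deg2rad(th[i])
            m = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
            dm = np.array([[-np.sin(t), np.cos(t)], [-np.cos(t), -np.sin(t)]])
            base = m @ (coords[i, j] - c) + c
            dtheta = dm @ (coords[i, j] - c)
            k = usable_idx[i]
            for axis in range(2):
                r_row = 2 * r_i + axis
                a_mat[r_row, k] = dtheta[axis]
                a_mat[r_row, n_use + axis * n_use + k] = 1.0
                a_mat[r_row, 3 * n_use + 6 * axis + j] = -1.0
                a_mat[r_row, 3 * n_use + 6 * axis + 3 + j] = -z[i]
                rhs[r_row] = -(
                    base[axis] + tr[i, axis]
                    - lines[j, 2 * axis] - lines[j, 2 * axis + 1] * z[i]
                )
        # The Jacobian has near-null directions (the soft rotation-ramp
        # mode) along which the full step can overshoot the linearisation's
        # validity, so offer backtracking-scaled versions of the increment
        # (and two Levenberg-damped solves) as candidates; the caller keeps
        # the cheapest by exact cost.
        try:
            sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        except np.linalg.LinAlgError:
            return []
        increments = [sol * s for s in (1.0, 0.5, 0.25, 0.1, 0.05)]
        h = a_mat.T @ a_mat
        g = a_mat.T @ rhs
        scale = float(np.trace(h)) / h.shape[0]
        for lam in (1e-6, 1e-3):
            try:
                increments.append(
                    np.linalg.solve(h + lam * scale * np.eye(h.shape[0]), g)
                )
            except np.linalg.LinAlgError:
                pass
        candidates = []
        for d in increments:
            th2, tr2, lines2 = th.copy(), tr.copy(), lines.copy()
            for i, k in usable_idx.items():
                th2[i] = th[i] + np.rad2deg(d[k])
                tr2[i, 0] = tr[i, 0] + d[n_use + k]
                tr2[i, 1] = tr[i, 1] + d[2 * n_use + k]
            for axis in range(2):
                lines2[:, 2 * axis] += d[3 * n_use + 6 * axis:
                                         3 * n_use + 6 * axis + 3]
                lines2[:, 2 * axis + 1] += d[3 * n_use + 6 * axis + 3:
                                             3 * n_use + 6 * axis + 6]
            candidates.append((th2, tr2, lines2))
        return candidates

    # The joint cost is flat along the gauge directions (one global rigid
    # motion, linear-in-z drift), where block coordinate descent moves
    # arbitrarily slowly.  Reaching max_iter therefore only means the
    # remaining motion lies in directions that the gauge normalisation
    # below removes anyway; it is recorded, not an error.
    cost_hist = []
    converged = False
    lines = fit_lines(apply_all(thetas, trans))
    for _ in range(max_iter):
        tgt = _line_targets(lines, z)
        for i in range(n):
            if not usable[i]:
                continue
            m = valid[i]
            t2 = kabsch_2d(coords[i][m], tgt[i][m], center_mm)
            thetas[i] = t2.rotation_deg
            trans[i] = t2.translation_mm
        trans, lines = solve_translations_and_lines(thetas, trans, lines)
        pts = apply_all(thetas, trans)
        cost = total_cost(pts, lines)
        for th_c, tr_c, lines_c in gauss_newton_step(thetas, trans, lines):
            cost_c = total_cost(apply_all(th_c, tr_c), lines_c)
            if cost_c < cost:
                thetas, trans, lines, cost = th_c, tr_c, lines_c, cost_c
        pts = apply_all(thetas, trans)
        cost_hist.append(cost)
        if len(cost_hist) >= 2:
            prev = cost_hist[-2]
            if not np.isfinite(cost):
                raise RuntimeError(f"alignment diverged (cost {cost!r})")
            if prev - cost < tol * max(prev, 1.0e-30):
                converged = True
                break

    # interpolate transforms for unusable sections
    interpolated = ~usable
    if interpolated.any():
        good = np.where(usable)[0]
        thetas[~usable] = np.interp(z[~usable], z[good], thetas[good])
        for k in range(2):
            trans[~usable, k] = np.interp(z[~usable], z[good], trans[good, k])

    transforms = [
        RigidTransform2D(float(th), (float(tx), float(ty)), tuple(center_mm))
        for th, (tx, ty) in zip(thetas, trans)
    ]
    transforms = normalize_transform_gauge(transforms, z)
    thetas = np.array([t.rotation_deg for t in transforms])
    trans = np.array([t.translation_mm for t in transforms])

    pts = apply_all(thetas, trans)
    lines = fit_lines(pts)
    tgt = _line_targets(lines, z)
    resid = pts - tgt

    rows = []
    for i in range(n):
        for j in range(3):
            if valid[i, j]:
                dx, dy = resid[i, j]
                rows.append(
                    (int(tracks.section_indices[i]), j, float(dx), float(dy),
                     float(np.hypot(dx, dy)))
                )
    residuals = pd.DataFrame(rows, columns=["section", "fiducial", "dx", "dy", "norm"])

    # dof-corrected noise scale: 2 coords per detection, 3 params per usable
    # section, 12 line params, ~5 gauge dimensions returned to the residual.
    n_obs = 2 * int(valid.sum())
    n_par = 3 * int(usable.sum()) + 12 - 5
    dof = max(n_obs - n_par, 1)
    sigma = float(np.sqrt((residuals[["dx", "dy"]].to_numpy() ** 2).sum() / dof))

    line_dicts = [
        {
            "point_mm": [float(a), float(c), 0.0],
            "direction": (np.array([b, d, 1.0]) / np.linalg.norm([b, d, 1.0])).tolist(),
        }
        for a, b, c, d in lines
    ]
    return AlignmentResult(
        section_indices=tracks.section_indices.copy(),
        transforms=transforms,
        z_mm=z,
        lines=line_dicts,
        residuals=residuals,
        cost_history=np.asarray(cost_hist),
        interpolated=interpolated,
        noise_sigma_mm=sigma,
        converged=converged,
    )


# --------------------------------------------------------------------------
# z assignment from groove readings

def assign_z(
    sections: list[SectionImage],
    proto: ProtocolSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected z per section and per-section tilt estimates from grooves.

    ``z_i = block_offset + block_height - mean(groove_remaining_i) - period``
    (exactly ``i * period`` for noiseless, tilt-free readings).  The plane
    through the three groove points gives the tilt estimate.  When the three
    readings disagree by more than the tilt prior plus 3x the reading noise,
    one groove is presumed mis-read and the median replaces the mean
    (tilt unavailable, NaN).

    Raises if the corrected z sequence is non-monotone.
    """
    gxy = np.asarray(proto.groove_xy_mm, dtype=float)
    center = gxy.mean(axis=0)
    span = np.max(np.linalg.norm(gxy - center, axis=1))
    allowance = (
        2.0 * np.tan(np.deg2rad(3.0 * proto.tilt_sd_deg)) * span
        + 3.0 * proto.groove_noise_um / 1000.0
        + 1e-9
    )
    starts = proto.block_starts()
    z_out = np.empty(len(sections))
    tilts = np.full((len(sections), 2), np.nan)
    A = np.column_stack([np.ones(3), gxy - center])
    for i, sec in enumerate(sections):
        if sec.groove_remaining_mm is None:
            raise ValueError(f"section {sec.section_index} has no groove readings")
        rem = np.asarray(sec.groove_remaining_mm, dtype=float)
        block = sec.block_id
        offset = starts[block] * proto.period_mm
        height = proto.block_height_mm(block)
        spread = np.max(np.abs(rem[:, None] - rem[None, :]))
        if spread > allowance:
            level = np.median(rem)
        else:
            coef, *_ = np.linalg.lstsq(A, rem, rcond=None)
            level = coef[0]
            tilts[i] = np.arctan(coef[1:])
        z_out[i] = offset + height - level - proto.period_mm
    order = np.argsort([s.section_index for s in sections])
    dz = np.diff(z_out[order])
    if np.any(dz <= 0):
        bad = [int(sections[order[k + 1]].section_index) for k in np.where(dz <= 0)[0]]
        raise ValueError(f"non-monotone corrected z at sections {bad}")
    return z_out, tilts


# --------------------------------------------------------------------------
# assembly

def assemble(
    sections: list[SectionImage],
    transforms: list[RigidTransform2D],
    period_mm: float | None = None,
    n_sections: int | None = None,
    max_voxels: int = 400_000_000,
) -> LabelVolume:
    """Resample corrected sections into a 3D label volume.

    z spacing is one section period; planes of lost sections remain
    background and are listed in ``metadata['missing_sections']``.
    """
    if len(sections) != len(transforms):
        raise ValueError("one transform per section required")
    if not sections:
        raise ValueError("no sections to assemble")
    order = np.argsort([s.section_index for s in sections])
    sections = [sections[i] for i in order]
    transforms = [transforms[i] for i in order]
    sx, sy = sections[0].spacing_mm
    ny, nx = sections[0].labels.shape
    if period_mm is None:
        idx = np.array([s.section_index for s in sections])
        z = np.array([s.nominal_z_mm for s in sections])
        steps = np.diff(z) / np.diff(idx)
        period_mm = float(np.median(steps))
    if n_sections is None:
        n_sections = max(s.section_index for s in sections) + 1
    if n_sections * ny * nx > max_voxels:
        raise ValueError(
            f"assembled grid {n_sections}x{ny}x{nx} exceeds the voxel budget "
            f"({max_voxels}); coarsen the grid or raise max_voxels"
        )
    vol = np.zeros((n_sections, ny, nx), dtype=np.int16)
    present = []
    for sec, tf in zip(sections, transforms):
        vol[sec.section_index] = warp_labels(sec.labels, tf, (sx, sy))
        present.append(sec.section_index)
    missing = sorted(set(range(n_sections)) - set(present))
    return LabelVolume(
        vol,
        (sx, sy, period_mm),
        label_scheme=dict(sections[0].label_scheme),
        metadata={"missing_sections": missing},
    )


def align_stack(
    sections: list[SectionImage],
    proto: ProtocolSpec | None = None,
    needle_radius_mm: float = 0.45,
) -> tuple[AlignmentResult, LabelVolume]:
    """Convenience pipeline: detect, correspond, assign z, fit, assemble."""
    detections = [detect_fiducials(s, needle_radius_mm) for s in sections]
    tracks = correspond_tracks(detections)
    if proto is not None and all(s.groove_remaining_mm is not None for s in sections):
        z, _ = assign_z(sections, proto)
    else:
        z = np.array([s.nominal_z_mm for s in sections])
    center = sections[0].center_mm
    result = fit_stack_alignment(tracks, z, center_mm=center)
    period = proto.period_mm if proto is not None else None
    n_total = proto.n_sections if proto is not None else None
    volume = assemble(sections, result.transforms, period_mm=period, n_sections=n_total)
    return result, volume
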