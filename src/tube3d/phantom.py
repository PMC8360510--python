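"""Ground-truth phantom: a helically twisted cartilaginous tube in a block.

The phantom emulates an embedded Eustachian-tube specimen: a J-shaped
cartilage cross-section (long medial lamina joined to a short lateral
lamina) swept along a gently curved axis, with lumen, mucosa, muscle
(TVPM/LVPM), Ostmann-fat-pad and bone compartments placed relative to the
axis, three near-axis-parallel cylindrical needle fiducials, and three
reference grooves milled into the block faces.  The cross-section rotates
in-plane about the axis point; the rotation angle is interpolated linearly
in arc length from 0 at the pharyngeal end to ``twist_total_deg`` at the
middle-ear end, so the total twist is an exactly known ground truth.

Geometry is deterministic: a seeded RNG is used only for optional surface
roughness.  The companion ``make_reference_volume`` maps labels to density
and box-downsamples to emulate a CBCT of the block before sectioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .labels import LABELS, LABEL_NAMES


# --------------------------------------------------------------------------
# specification dataclasses

@dataclass(frozen=True)
class CartilageProfile:
    """Parametric J ("paisley") cross-section in local (u, v) mm coordinates.

    Two stadium-shaped laminae joined at a corner: the long medial lamina
    runs along +u, the short lateral lamina along +v.  ``elongation_end``
    rescales lamina lengths by ``s(t) = 1 + (elongation_end - 1) t`` and the
    thickness by ``1/s(t)`` along the axis parameter ``t``, which keeps the
    cross-sectional area essentially constant while the perimeter shrinks —
    the increasingly compact shape observed towards the isthmus.
    """

    medial_length_mm: float = 8.0
    lateral_length_mm: float = 3.0
    thickness_mm: float = 1.0
    elongation_end: float = 1.0
    lumen_margin_mm: float = 0.2
    mucosa_thickness_mm: float = 0.15

    def scale(self, t: float) -> float:
        return 1.0 + (self.elongation_end - 1.0) * t


@dataclass(frozen=True)
class EllipseCompartment:
    """Axis-relative elliptical compartment (muscles, fat pad, bone)."""

    name: str
    center_uv_mm: tuple[float, float]
    radii_mm: tuple[float, float]
    taper: float = 0.0          # radii scale with (1 - taper * t)
    t_range: tuple[float, float] = (0.0, 1.0)


@dataclass(frozen=True)
class Fiducial:
    """Straight cylindrical needle: entry point, unit direction, radius.

    Default radius matches a 0.9 mm injection cannula.
    """

    entry_mm: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius_mm: float = 0.45

    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("fiducial direction must be non-zero")
        return d / n

    def center_at_z(self, z: float) -> np.ndarray:
        d = self.unit_direction()
        if abs(d[2]) < 1e-9:
            raise ValueError("fiducial direction must have a z component")
        e = np.asarray(self.entry_mm, dtype=float)
        return e[:2] + d[:2] * (z - e[2]) / d[2]


@dataclass(frozen=True)
class Groove:
    """Reference channel milled into a lateral block face, running along z."""

    face: str                   # one of '-x', '+x', '-y', '+y'
    position_mm: float          # coordinate along the face
    width_mm: float = 0.8
    depth_mm: float = 0.8

    def surface_xy(self, block_size_mm) -> tuple[float, float]:
        """(x, y) of the groove mouth on the block surface."""
        bx, by = block_size_mm[0], block_size_mm[1]
        if self.face == "-x":
            return (0.0, self.position_mm)
        if self.face == "+x":
            return (bx, self.position_mm)
        if self.face == "-y":
            return (self.position_mm, 0.0)
        if self.face == "+y":
            return (self.position_mm, by)
        raise ValueError(f"unknown groove face {self.face!r}")


def _default_compartments() -> tuple[EllipseCompartment, ...]:
    return (
        EllipseCompartment("TVPM", (3.4, 2.8), (1.5, 1.0)),
        EllipseCompartment("LVPM", (-3.4, 2.4), (1.4, 1.0)),
        EllipseCompartment("OFP", (0.0, 2.2), (2.4, 1.3), taper=0.5),
        EllipseCompartment("bone", (-4.2, -1.8), (1.8, 1.0), t_range=(0.7, 1.0)),
    )


def default_axis(
    block_size_mm, z_range_mm: tuple[float, float] | None = None,
    curvature_mm: float = 1.5, n_points: int = 61,
) -> np.ndarray:
    """Gently curved (quadratic in x) axis polyline through the block center.

    Curvature exercises non-axis-aligned sectioning without the axis leaving
    the block; the drift is ``curvature_mm * (4 (t - 1/2)^2 - 1)`` so the end
    points sit at the block-center x and the midpoint bows sideways.
    """
    bx, by, bz = block_size_mm
    z0, z1 = (0.0, bz) if z_range_mm is None else z_range_mm
    t = np.linspace(0.0, 1.0, n_points)
    x = bx / 2.0 + curvature_mm * (4.0 * (t - 0.5) ** 2 - 1.0)
    y = np.full_like(t, by / 2.0)
    z = z0 + t * (z1 - z0)
    return np.column_stack([x, y, z])


@dataclass(frozen=True)
class PhantomSpec:
    """All geometric constants of the synthetic specimen.

    ``tube_axis`` runs from the pharyngeal end (low z, section index 0) to
    the middle-ear end.  ``lumen_gap_mm`` is a piecewise-linear profile of
    (t, gap) breakpoints: the lumen is an open slit of this width on the
    concave side of the medial lamina (wide near the pharyngeal orifice,
    nearly closed elsewhere by default).
    """

    block_size_mm: tuple[float, float, float] = (25.0, 25.0, 40.0)
    voxel_mm: tuple[float, float, float] = (0.05, 0.05, 0.05)
    tube_axis: np.ndarray | None = None
    cartilage_profile: CartilageProfile = field(default_factory=CartilageProfile)
    twist_total_deg: float = 0.0
    base_orientation_deg: float = 10.0
    lumen_gap_mm: tuple[tuple[float, float], ...] = (
        (0.0, 0.45), (0.12, 0.02), (1.0, 0.02),
    )
    compartments: tuple[EllipseCompartment, ...] = field(
        default_factory=_default_compartments
    )
    fiducials: tuple[Fiducial, ...] = (
        Fiducial((12.5, 4.0, 0.0), (0.015, 0.010, 1.0)),
        Fiducial((19.9, 16.6, 0.0), (-0.018, 0.008, 1.0)),
        Fiducial((5.0, 17.0, 0.0), (0.006, -0.020, 1.0)),
    )
    grooves: tuple[Groove, ...] = (
        Groove("-x", 8.0), Groove("+x", 17.0), Groove("-y", 12.5),
    )
    max_fiducial_angle_deg: float = 5.0
    roughness_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        voxel = np.asarray(self.voxel_mm, dtype=float)
        if np.any(voxel <= 0):
            raise ValueError("voxel_mm must be strictly positive componentwise")
        axis = self.axis_points()
        if len(axis) < 2:
            raise ValueError("tube_axis needs at least two points")
        steps = np.diff(axis, axis=0)
        if np.any(np.linalg.norm(steps, axis=1) == 0):
            raise ValueError("degenerate tube_axis: repeated points")
        if np.any(steps[:, 2] <= 0):
            raise ValueError("tube_axis must be strictly increasing in z")
        mean_dir = axis[-1] - axis[0]
        mean_dir = mean_dir / np.linalg.norm(mean_dir)
        for k, f in enumerate(self.fiducials):
            ang = np.rad2deg(
                np.arccos(np.clip(np.dot(f.unit_direction(), mean_dir), -1, 1))
            )
            if ang > self.max_fiducial_angle_deg:
                raise ValueError(
                    f"fiducial {k} deviates {ang:.2f} deg from the mean tube axis "
                    f"(limit {self.max_fiducial_angle_deg} deg)"
                )

    def axis_points(self) -> np.ndarray:
        if self.tube_axis is None:
            return default_axis(self.block_size_mm)
        return np.asarray(self.tube_axis, dtype=float)

    def lumen_gap(self, t) -> np.ndarray:
        bp = np.asarray(self.lumen_gap_mm, dtype=float)
        return np.interp(np.asarray(t, dtype=float), bp[:, 0], bp[:, 1])


@dataclass
class LabelVolume:
    """3D integer label map with anisotropic spacing.

    ``voxels`` is indexed ``[z, y, x]``; ``spacing_mm`` and ``origin_mm`` are
    (x, y, z) ordered.  The voxel with index (k, r, c) has its center at
    ``origin + (c sx, r sy, k sz)``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    label_scheme: dict[str, int] = field(default_factory=lambda: dict(LABELS))
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.size == 0 or self.voxels.ndim != 3:
            raise ValueError("voxels must be a non-empty 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if np.any(np.asarray(self.spacing_mm, dtype=float) <= 0):
            raise ValueError("spacing_mm must be strictly positive")
        allowed = set(self.label_scheme.values())
        present = set(np.unique(self.voxels).tolist())
        unknown = sorted(present - allowed)
        if unknown:
            raise ValueError(f"voxel values {unknown} outside the label scheme")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def z_coords(self) -> np.ndarray:
        return self.origin_mm[2] + np.arange(self.n_slices) * self.spacing_mm[2]

    def mask(self, label: str) -> np.ndarray:
        if label not in self.label_scheme:
            raise ValueError(f"unknown label {label!r}")
        return self.voxels == self.label_scheme[label]


# --------------------------------------------------------------------------
# geometry helpers

def _dist2_to_segment(u, v, p0, p1):
    """Squared distance of grid points (u, v) to segment p0-p1."""
    du, dv = p1[0] - p0[0], p1[1] - p0[1]
    l2 = du * du + dv * dv
    t = ((u - p0[0]) * du + (v - p0[1]) * dv) / l2
    t = np.clip(t, 0.0, 1.0)
    return (u - (p0[0] + t * du)) ** 2 + (v - (p0[1] + t * dv)) ** 2


def _cartilage_mask(u, v, prof: CartilageProfile, t: float, h_jitter: float = 0.0):
    s = prof.scale(t)
    lm, ll = prof.medial_length_mm * s, prof.lateral_length_mm * s
    h = 0.5 * prof.thickness_mm / s + h_jitter
    joint = (-0.4 * lm, 0.0)
    medial = _dist2_to_segment(u, v, joint, (0.6 * lm, 0.0)) <= h * h
    lateral = _dist2_to_segment(u, v, joint, (joint[0], ll)) <= h * h
    return medial | lateral, (lm, h, joint)


def _lumen_bounds(prof: CartilageProfile, lm: float, h: float, joint):
    u0 = joint[0] + 2.0 * h + prof.lumen_margin_mm
    u1 = 0.45 * lm
    return u0, u1


def axis_interpolator(axis: np.ndarray):
    """Return (xy_at_z, arc_fraction_at_z, z_range) for a polyline axis."""
    seg = np.diff(axis, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    z = axis[:, 2]

    def xy_at(zq):
        return np.interp(zq, z, axis[:, 0]), np.interp(zq, z, axis[:, 1])

    def frac_at(zq):
        return np.interp(zq, z, arc) / arc[-1]

    return xy_at, frac_at, (z[0], z[-1])


# --------------------------------------------------------------------------
# operations

def build_phantom(spec: PhantomSpec) -> tuple[LabelVolume, dict]:
    """Rasterize the phantom and return it with its ground-truth metadata.

    Labels are painted per z-slice in priority order (bone < muscles < fat
    pad < mucosa < lumen < cartilage < fiducial < groove); compartment
    membership is evaluated at voxel centers.  A fiducial overlapping
    cartilage or lumen raises immediately, naming the fiducial.

    The ground-truth dict records the applied per-slice twist angle, the
    axis track, the fiducial line parameters and the per-compartment
    centroids, and is what downstream parameter-recovery tests compare
    against.
    """
    bx, by, bz = spec.block_size_mm
    sx, sy, sz = spec.voxel_mm
    nx, ny, nz = (int(round(b / s)) + 1 for b, s in zip((bx, by, bz), (sx, sy, sz)))
    vol = np.zeros((nz, ny, nx), dtype=np.int16)

    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    xg, yg = np.meshgrid(xs, ys)          # (ny, nx)
    zs = np.arange(nz) * sz

    axis = spec.axis_points()
    xy_at, frac_at, (z0, z1) = axis_interpolator(axis)
    prof = spec.cartilage_profile
    rng = np.random.default_rng(spec.seed)

    twist_by_slice = np.full(nz, np.nan)
    axis_by_slice = np.full((nz, 2), np.nan)

    order = {"bone": 0, "TVPM": 1, "LVPM": 2, "OFP": 3}
    comps = sorted(spec.compartments, key=lambda c: order.get(c.name, 4))

    fid_centers = []  # (slice, fiducial, cx, cy) for straightness truth
    for k, zc in enumerate(zs):
        plane = vol[k]
        in_tube = z0 - 1e-9 <= zc <= z1 + 1e-9
        if in_tube:
            ax, ay = xy_at(zc)
            t = float(frac_at(zc))
            theta = spec.base_orientation_deg + spec.twist_total_deg * t
            twist_by_slice[k] = spec.twist_total_deg * t
            axis_by_slice[k] = (ax, ay)
            ct, st = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
            dx, dy = xg - ax, yg - ay
            # local = M(theta)^T @ global offset, M as in transforms.py
            u = ct * dx - st * dy
            v = st * dx + ct * dy

            for comp in comps:
                tlo, thi = comp.t_range
                if not (tlo <= t <= thi):
                    continue
                ru, rv = comp.radii_mm
                f = 1.0 - comp.taper * t
                ru, rv = ru * f, rv * f
                cu, cv = comp.center_uv_mm
                inside = ((u - cu) / ru) ** 2 + ((v - cv) / rv) ** 2 <= 1.0
                plane[inside] = LABELS[comp.name]

            jit = rng.normal(0.0, spec.roughness_mm) if spec.roughness_mm > 0 else 0.0
            cart, (lm, h, joint) = _cartilage_mask(u, v, prof, t, jit)
            gap = float(spec.lumen_gap(t))
            u0, u1 = _lumen_bounds(prof, lm, h, joint)
            band_u = (u >= u0) & (u <= u1)
            mucosa = band_u & (v > h + gap) & (v <= h + gap + prof.mucosa_thickness_mm)
            lumen = band_u & (v > h) & (v <= h + gap)
            plane[mucosa] = LABELS["mucosa"]
            plane[lumen] = LABELS["lumen"]
            plane[cart] = LABELS["cartilage"]

        for fi, fid in enumerate(spec.fiducials):
            cx, cy = fid.center_at_z(zc)
            r2 = fid.radius_mm ** 2
            disk = (xg - cx) ** 2 + (yg - cy) ** 2 <= r2
            clash = disk & np.isin(plane, (LABELS["cartilage"], LABELS["lumen"]))
            if np.any(clash):
                raise ValueError(
                    f"fiducial {fi} intersects cartilage/lumen at z={zc:.3f} mm"
                )
            plane[disk] = LABELS["fiducial"]
            if disk.any():
                fid_centers.append((k, fi, cx, cy))

        for g in spec.grooves:
            if g.face in ("-x", "+x"):
                along, depth_axis = yg, xg
                edge = 0.0 if g.face == "-x" else bx
            else:
                along, depth_axis = xg, yg
                edge = 0.0 if g.face == "-y" else by
            near_face = np.abs(depth_axis - edge) <= g.depth_mm
            channel = near_face & (np.abs(along - g.position_mm) <= g.width_mm / 2.0)
            plane[channel] = LABELS["groove"]

    volume = LabelVolume(vol, (sx, sy, sz))
    truth = {
        "spec_twist_total_deg": float(spec.twist_total_deg),
        "base_orientation_deg": float(spec.base_orientation_deg),
        "z_mm": zs.tolist(),
        "twist_deg_by_slice": twist_by_slice.tolist(),
        "axis_xy_by_slice": axis_by_slice.tolist(),
        "axis_z_range_mm": [float(z0), float(z1)],
        "fiducial_lines": [
            {
                "point_mm": list(map(float, f.entry_mm)),
                "direction": f.unit_direction().tolist(),
                "radius_mm": float(f.radius_mm),
            }
            for f in spec.fiducials
        ],
        "groove_xy_mm": [list(g.surface_xy(spec.block_size_mm)) for g in spec.grooves],
        "compartment_centroids_mm": _centroids(volume),
    }
    return volume, truth


def _centroids(vol: LabelVolume) -> dict[str, list[float]]:
    out = {}
    for name, code in vol.label_scheme.items():
        if code == 0 or not np.any(vol.voxels == code):
            continue
        zc, yc, xc = ndimage.center_of_mass(vol.voxels == code)
        sx, sy, sz = vol.spacing_mm
        out[name] = [float(xc * sx), float(yc * sy), float(zc * sz)]
    return out


#: Label -> relative radiodensity used for the CBCT surrogate.  Metal
#: needles and bone map high, soft tissue mid, embedding medium low and the
#: carved grooves to air.
DENSITY_MAP: dict[str, float] = {
    "background": 0.10,
    "cartilage": 0.50,
    "lumen": 0.12,
    "mucosa": 0.35,
    "TVPM": 0.40,
    "LVPM": 0.40,
    "OFP": 0.25,
    "bone": 1.00,
    "fiducial": 1.00,
    "groove": 0.00,
}


def make_reference_volume(
    vol: LabelVolume, resolution_mm: float = 0.3
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Map labels to density and box-average down to ``resolution_mm``.

    The integer downsampling factor per axis is ``round(resolution /
    spacing)`` (at least 1); trailing voxels that do not fill a complete box
    are trimmed, so on commensurate grids the box filter conserves the mean
    exactly.  Returns ``(density, spacing)`` with spacing (x, y, z) ordered.
    """
    spacing = np.asarray(vol.spacing_mm, dtype=float)
    if resolution_mm < spacing.max() - 1e-12:
        raise ValueError(
            f"resolution {resolution_mm} mm is finer than the source spacing "
            f"{tuple(spacing)} mm"
        )
    lut = np.zeros(max(vol.label_scheme.values()) + 1)
    for name, code in vol.label_scheme.items():
        lut[code] = DENSITY_MAP.get(name, 0.0)
    dens = lut[vol.voxels]

    fx, fy, fz = (max(1, int(round(resolution_mm / s))) for s in spacing)
    nz, ny, nx = dens.shape
    dens = dens[: (nz // fz) * fz, : (ny // fy) * fy, : (nx // fx) * fx]
    dens = dens.reshape(nz // fz, fz, ny // fy, fy, nx // fx, fx).mean(axis=(1, 3, 5))
    out_spacing = (spacing[0] * fx, spacing[1] * fy, spacing[2] * fz)
    return dens, out_spacing
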