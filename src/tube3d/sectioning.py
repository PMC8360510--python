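"""Simulated serial sectioning of the phantom block.

Emulates the cutting protocol: 33 um sections taken at a 330 um blade
pitch (one section per 363 um period), the block split into two halves,
the first section of each half lost during mounting, per-section rigid
in-plane perturbations from handling, small cutting-plane tilts, and the
groove-thickness readings taken after every cut.

A section is represented by the single mid-plane resample of its 33 um
slab (one digitized image per section).  Tilt is treated to first order:
it offsets the three groove readings (and would shift fiducial centers by
only a few micrometres, which is neglected) but does not re-warp the 2D
image content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import LABELS
from .phantom import LabelVolume
from .transforms import RigidTransform2D


@dataclass(frozen=True)
class ProtocolSpec:
    """Sectioning protocol constants.

    The section period is ``section_thickness + blade_thickness`` (363 um by
    default: 33 um section, 330 um saw blade).  ``lost_section_indices``
    defaults to the first section of each block, mirroring loss during
    mounting of the blocks on the sample holder.
    """

    section_thickness_um: float = 33.0
    blade_thickness_um: float = 330.0
    n_sections: int = 100
    split_into_blocks: int = 2
    lost_section_indices: tuple[int, ...] | None = None
    translation_sd_mm: float = 0.3
    rotation_sd_deg: float = 2.0
    tilt_sd_deg: float = 0.2
    groove_noise_um: float = 5.0
    groove_xy_mm: tuple[tuple[float, float], ...] = (
        (0.0, 8.0), (25.0, 17.0), (12.5, 0.0),
    )
    seed: int = 0

    def __post_init__(self):
        if self.section_thickness_um <= 0 or self.blade_thickness_um <= 0:
            raise ValueError("thickness values must be positive")
        if self.n_sections < 1 or self.split_into_blocks < 1:
            raise ValueError("n_sections and split_into_blocks must be >= 1")
        for i in self.lost_indices():
            if not 0 <= i < self.n_sections:
                raise ValueError(f"lost section index {i} outside [0, {self.n_sections})")

    @property
    def period_mm(self) -> float:
        return (self.section_thickness_um + self.blade_thickness_um) / 1000.0

    def block_starts(self) -> list[int]:
        n, b = self.n_sections, self.split_into_blocks
        base = n // b
        starts, acc = [], 0
        for k in range(b):
            starts.append(acc)
            acc += base + (1 if k < n % b else 0)
        return starts

    def block_of(self, index: int) -> int:
        starts = self.block_starts()
        return int(np.searchsorted(starts, index, side="right") - 1)

    def block_n_sections(self, block_id: int) -> int:
        starts = self.block_starts() + [self.n_sections]
        return starts[block_id + 1] - starts[block_id]

    def block_height_mm(self, block_id: int) -> float:
        return self.block_n_sections(block_id) * self.period_mm

    def lost_indices(self) -> tuple[int, ...]:
        if self.lost_section_indices is not None:
            return tuple(self.lost_section_indices)
        return tuple(self.block_starts())


@dataclass
class SectionImage:
    """One digitized section: a 2D label map plus cutting metadata.

    ``true_transform`` (the applied mounting perturbation, image =
    perturbed slice) and ``true_tilt_rad`` exist only for synthetic data.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float]
    section_index: int
    block_id: int = 0
    nominal_z_mm: float = 0.0
    groove_remaining_mm: tuple[float, float, float] | None = None
    true_transform: RigidTransform2D | None = None
    true_tilt_rad: tuple[float, float] | None = None
    rgb: np.ndarray | None = None
    label_scheme: dict[str, int] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("section labels must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("section labels must be integer")
        if np.any(np.asarray(self.spacing_mm, dtype=float) <= 0):
            raise ValueError("spacing must be positive")

    @property
    def center_mm(self) -> tuple[float, float]:
        ny, nx = self.labels.shape
        return ((nx - 1) / 2.0 * self.spacing_mm[0], (ny - 1) / 2.0 * self.spacing_mm[1])


def warp_labels(
    labels: np.ndarray,
    transform: RigidTransform2D,
    spacing_mm: tuple[float, float],
) -> np.ndarray:
    """Nearest-neighbour resample of a label image under a rigid transform.

    Output pixel (r, c) takes the value of the input at ``T^-1(x, y)``;
    labels are categorical so only order-0 interpolation is used.
    """
    ny, nx = labels.shape
    sx, sy = spacing_mm
    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    xg, yg = np.meshgrid(xs, ys)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    src = transform.inverse().apply(pts)
    rows = src[:, 1] / sy
    cols = src[:, 0] / sx
    out = ndimage.map_coordinates(
        labels, np.vstack([rows, cols]), order=0, mode="constant", cval=0,
    )
    return out.reshape(ny, nx).astype(labels.dtype)


def _groove_tilt_offsets_mm(
    proto: ProtocolSpec, tilt_rad: tuple[float, float]
) -> np.ndarray:
    gxy = np.asarray(proto.groove_xy_mm, dtype=float)
    center = gxy.mean(axis=0)
    a, b = tilt_rad
    return np.tan(a) * (gxy[:, 0] - center[0]) + np.tan(b) * (gxy[:, 1] - center[1])


def simulate_groove_measurements(
    proto: ProtocolSpec,
    section_index: int,
    tilt_rad: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Remaining block thickness at the three grooves after one cut.

    ``block_height - (local_index + 1) * period`` plus the tilt-plane offset
    at each groove position and Gaussian reading noise (``groove_noise_um``).
    """
    if not 0 <= section_index < proto.n_sections:
        raise ValueError(f"section index {section_index} out of range")
    block = proto.block_of(section_index)
    local = section_index - proto.block_starts()[block]
    base = proto.block_height_mm(block) - (local + 1) * proto.period_mm
    offs = _groove_tilt_offsets_mm(proto, tilt_rad)
    if rng is None:
        rng = np.random.default_rng(proto.seed)
    noise = rng.normal(0.0, proto.groove_noise_um / 1000.0, size=3)
    return base + offs + noise


def simulate_sectioning(
    vol: LabelVolume,
    proto: ProtocolSpec,
    rng: np.random.Generator | None = None,
) -> list[SectionImage]:
    """Cut the phantom into perturbed 2D sections.

    Each kept section is the nearest mid-plane z-resample of its slab,
    rigidly perturbed in-plane (translation/rotation drawn from the protocol
    SDs about the image center).  Perturbations, tilts and groove noise are
    drawn for *all* section indices from a single seeded stream so the set
    of lost sections does not reshuffle the draws of the kept ones.  Lost
    sections are absent from the output; their indices and z bookkeeping are
    preserved on the kept sections.
    """
    sx, sy, sz = vol.spacing_mm
    period = proto.period_mm
    z_extent = (vol.n_slices - 1) * sz
    z_needed = (proto.n_sections - 1) * period + proto.section_thickness_um / 2000.0
    if z_needed > z_extent + sz / 2.0 + 1e-9:
        raise ValueError(
            f"block too shallow: {proto.n_sections} sections need "
            f"{z_needed:.2f} mm, volume spans {z_extent:.2f} mm"
        )
    if rng is None:
        rng = np.random.default_rng(proto.seed)

    n = proto.n_sections
    translations = rng.normal(0.0, proto.translation_sd_mm, size=(n, 2))
    rotations = rng.normal(0.0, proto.rotation_sd_deg, size=n)
    tilts = rng.normal(0.0, np.deg2rad(proto.tilt_sd_deg), size=(n, 2))
    groove_noise = rng.normal(0.0, proto.groove_noise_um / 1000.0, size=(n, 3))

    lost = set(proto.lost_indices())
    ny, nx = vol.voxels.shape[1:]
    center = ((nx - 1) / 2.0 * sx, (ny - 1) / 2.0 * sy)

    sections: list[SectionImage] = []
    for i in range(n):
        if i in lost:
            continue
        z_mid = i * period + proto.section_thickness_um / 2000.0
        k = int(round(z_mid / sz))
        k = min(max(k, 0), vol.n_slices - 1)
        transform = RigidTransform2D(
            float(rotations[i]), tuple(translations[i]), center
        )
        img = warp_labels(vol.voxels[k], transform, (sx, sy))
        block = proto.block_of(i)
        local = i - proto.block_starts()[block]
        base = proto.block_height_mm(block) - (local + 1) * period
        remaining = base + _groove_tilt_offsets_mm(proto, tuple(tilts[i])) + groove_noise[i]
        sections.append(
            SectionImage(
                labels=img,
                spacing_mm=(sx, sy),
                section_index=i,
                block_id=block,
                nominal_z_mm=i * period,
                groove_remaining_mm=tuple(remaining),
                true_transform=transform,
                true_tilt_rad=tuple(tilts[i]),
                label_scheme=dict(vol.label_scheme),
            )
        )
    return sections


def white_balance(rgb: np.ndarray) -> np.ndarray:
    """Gray-world white balance: scale each channel to the joint mean.

    Accepts float or uint8 3-channel images; output matches the input dtype
    and is clipped to the valid range.  A zero channel mean is an error.
    """
    img = np.asarray(rgb)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    data = img.astype(float)
    means = data.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        raise ValueError("channel mean of 0: cannot white-balance")
    target = means.mean()
    out = data * (target / means)
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return np.clip(np.round(out), info.min, info.max).astype(img.dtype)
    return np.clip(out, 0.0, None)
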