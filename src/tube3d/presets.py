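"""Ready-made specimen and protocol configurations.

``specimen_phantom_spec`` is the reference fixture used by the demo and the
validation experiments: a 25 x 25 x 36.3 mm block whose twisted tube spans
exactly the 100-section cutting range (100 sections x 363 um period), with
the cartilage twisting by the reported specimen torsion of 38 degrees from
the pharyngeal to the middle-ear end.  The in-plane voxel pitch of 0.1 mm
keeps a full sectioning-and-realignment experiment in the seconds range
while leaving the needle cross-sections (0.45 mm radius, ~64 pixels) and
lamina orientation well resolved.
"""

from __future__ import annotations

import numpy as np

from .phantom import CartilageProfile, Fiducial, Groove, PhantomSpec, default_axis
from .sectioning import ProtocolSpec

#: Total cartilage torsion of the reference specimen, pharynx to middle ear.
SPECIMEN_TORSION_DEG = 38.0

_BLOCK = (25.0, 25.0, 36.3)


def specimen_protocol(seed: int = 0, **overrides) -> ProtocolSpec:
    """The cutting protocol: 33 um sections at a 330 um blade pitch, 100
    sections in two blocks, first section of each block lost."""
    kw = dict(
        section_thickness_um=33.0,
        blade_thickness_um=330.0,
        n_sections=100,
        split_into_blocks=2,
        groove_xy_mm=((0.0, 8.0), (25.0, 17.0), (12.5, 0.0)),
        seed=seed,
    )
    kw.update(overrides)
    return ProtocolSpec(**kw)


def specimen_phantom_spec(
    twist_total_deg: float = SPECIMEN_TORSION_DEG,
    voxel_mm: tuple[float, float, float] = (0.1, 0.1, 0.055),
    curvature_mm: float = 1.5,
    seed: int = 0,
) -> PhantomSpec:
    """Specimen-like fixture phantom matched to the 100-section protocol.

    The tube axis spans the sectioned z range so the twist parameter is the
    ground truth for the torsion recovered over the cut series.  The
    cartilage elongation tapers towards the isthmus (constant area, falling
    perimeter), the lumen is open only near the pharyngeal orifice, and the
    fat pad shrinks continuously towards the isthmus.
    """
    axis = default_axis(_BLOCK, z_range_mm=(0.0, _BLOCK[2]),
                        curvature_mm=curvature_mm)
    return PhantomSpec(
        block_size_mm=_BLOCK,
        voxel_mm=voxel_mm,
        tube_axis=axis,
        cartilage_profile=CartilageProfile(
            medial_length_mm=8.0,
            lateral_length_mm=3.0,
            thickness_mm=1.0,
            elongation_end=0.8,
        ),
        twist_total_deg=twist_total_deg,
        base_orientation_deg=10.0,
        lumen_gap_mm=((0.0, 0.45), (0.12, 0.02), (1.0, 0.02)),
        fiducials=(
            Fiducial((12.5, 4.0, 0.0), (0.015, 0.010, 1.0)),
            Fiducial((19.9, 16.6, 0.0), (-0.018, 0.008, 1.0)),
            Fiducial((5.0, 17.0, 0.0), (0.006, -0.020, 1.0)),
        ),
        grooves=(Groove("-x", 8.0), Groove("+x", 17.0), Groove("-y", 12.5)),
        seed=seed,
    )


def tiny_phantom_spec(
    twist_total_deg: float = 0.0,
    n_sections: int = 12,
    voxel_mm: tuple[float, float, float] = (0.1, 0.1, 0.1),
    seed: int = 0,
) -> tuple[PhantomSpec, ProtocolSpec]:
    """Desk-scale phantom + protocol pair for fast unit-level experiments."""
    period = 0.363
    block = (14.0, 14.0, n_sections * period)
    axis = default_axis(block, z_range_mm=(0.0, block[2]), curvature_mm=0.4)
    spec = PhantomSpec(
        block_size_mm=block,
        voxel_mm=voxel_mm,
        tube_axis=axis,
        cartilage_profile=CartilageProfile(
            medial_length_mm=3.6, lateral_length_mm=1.4, thickness_mm=0.6,
        ),
        twist_total_deg=twist_total_deg,
        base_orientation_deg=10.0,
        lumen_gap_mm=((0.0, 0.3), (0.3, 0.05), (1.0, 0.05)),
        compartments=(
            _scaled_ellipses()
        ),
        fiducials=(
            Fiducial((7.0, 2.6, 0.0), (0.012, 0.008, 1.0)),
            Fiducial((11.0, 9.5, 0.0), (-0.015, 0.006, 1.0)),
            Fiducial((3.0, 9.8, 0.0), (0.005, -0.016, 1.0)),
        ),
        grooves=(Groove("-x", 4.0), Groove("+x", 10.0), Groove("-y", 7.0)),
        seed=seed,
    )
    proto = ProtocolSpec(
        n_sections=n_sections,
        split_into_blocks=2,
        groove_xy_mm=((0.0, 4.0), (14.0, 10.0), (7.0, 0.0)),
        seed=seed,
    )
    return spec, proto


def _scaled_ellipses():
    from .phantom import EllipseCompartment

    return (
        EllipseCompartment("TVPM", (1.7, 1.4), (0.8, 0.55)),
        EllipseCompartment("LVPM", (-1.7, 1.2), (0.75, 0.55)),
        EllipseCompartment("OFP", (0.0, 1.2), (1.2, 0.7), taper=0.5),
        EllipseCompartment("bone", (-2.1, -0.9), (0.9, 0.55), t_range=(0.7, 1.0)),
    )


def spawn_seed(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG: one global seed fanned out by stage name
    so toggling one stage does not reshuffle another stage's draws."""
    stage_key = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "little")
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, stage_key])
    return np.random.default_rng(ss)
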