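"""Readers and writers for section series, manifests and 3D volumes.

On-disk layout of a section series::

    stack_dir/
      manifest.json          # spacing, period, label scheme, per-section rows
      sec_0001.tif           # one 2D label TIFF per kept section
      ...

The manifest is the single source of z and groove metadata; ground-truth
perturbations of synthetic stacks are stored under a ``truth`` key per
section so that real data (without truth) uses the identical schema.
3D label and density volumes are stored as NRRD with the anisotropic
spacing in the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .labels import LABELS, validate_labels
from .phantom import LabelVolume
from .sectioning import SectionImage
from .transforms import RigidTransform2D

MANIFEST_NAME = "manifest.json"


def write_stack(sections: list[SectionImage], path: str | Path) -> dict:
    """Write a section series and return the manifest dict."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if not sections:
        raise ValueError("cannot write an empty stack")
    spacing = sections[0].spacing_mm
    scheme = sections[0].label_scheme
    entries = []
    for sec in sections:
        if tuple(sec.spacing_mm) != tuple(spacing):
            raise ValueError(
                f"section {sec.section_index}: spacing {sec.spacing_mm} differs "
                f"from stack spacing {spacing}"
            )
        fname = f"sec_{sec.section_index:04d}.tif"
        tifffile.imwrite(path / fname, sec.labels.astype(np.int16))
        entry = {
            "index": int(sec.section_index),
            "filename": fname,
            "block_id": int(sec.block_id),
            "nominal_z_mm": float(sec.nominal_z_mm),
            "groove_remaining_mm": (
                None
                if sec.groove_remaining_mm is None
                else [float(v) for v in sec.groove_remaining_mm]
            ),
        }
        if sec.true_transform is not None:
            entry["truth"] = {
                "rotation_deg": float(sec.true_transform.rotation_deg),
                "translation_mm": [float(v) for v in sec.true_transform.translation_mm],
                "center_mm": [float(v) for v in sec.true_transform.center_mm],
                "tilt_rad": (
                    None
                    if sec.true_tilt_rad is None
                    else [float(v) for v in sec.true_tilt_rad]
                ),
            }
        entries.append(entry)
    indices = [e["index"] for e in entries]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate section indices in stack")
    manifest = {
        "spacing_mm": [float(spacing[0]), float(spacing[1])],
        "label_scheme": {k: int(v) for k, v in scheme.items()},
        "sections": entries,
    }
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_stack(path: str | Path) -> list[SectionImage]:
    """Read a section series; validates files, labels and spacing.

    ``write_stack`` then ``read_stack`` is the identity on labels, spacing,
    z and groove data (labels are stored as int16, bit-exact).
    """
    path = Path(path)
    manifest_path = path if path.name.endswith(".json") else path / MANIFEST_NAME
    stack_dir = manifest_path.parent
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    spacing = tuple(float(v) for v in manifest["spacing_mm"])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"manifest spacing {spacing} must be strictly positive")
    scheme = {k: int(v) for k, v in manifest["label_scheme"].items()}
    if scheme.get("background", None) != 0:
        raise ValueError("label scheme must contain background=0")

    sections = []
    seen = set()
    for entry in manifest["sections"]:
        idx = int(entry["index"])
        if idx in seen:
            raise ValueError(f"duplicate section index {idx} in manifest")
        seen.add(idx)
        fpath = stack_dir / entry["filename"]
        if not fpath.exists():
            raise FileNotFoundError(f"section file missing: {fpath}")
        labels = tifffile.imread(fpath)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"{fpath.name}: label image has non-integer dtype {labels.dtype}")
        validate_labels(labels, scheme)
        truth = entry.get("truth")
        transform = tilt = None
        if truth is not None:
            transform = RigidTransform2D(
                truth["rotation_deg"],
                tuple(truth["translation_mm"]),
                tuple(truth["center_mm"]),
            )
            tilt = None if truth.get("tilt_rad") is None else tuple(truth["tilt_rad"])
        sections.append(
            SectionImage(
                labels=labels,
                spacing_mm=spacing,
                section_index=idx,
                block_id=int(entry.get("block_id", 0)),
                nominal_z_mm=float(entry["nominal_z_mm"]),
                groove_remaining_mm=(
                    None
                    if entry.get("groove_remaining_mm") is None
                    else tuple(entry["groove_remaining_mm"])
                ),
                true_transform=transform,
                true_tilt_rad=tilt,
                label_scheme=scheme,
            )
        )
    sections.sort(key=lambda s: s.section_index)
    return sections


# --------------------------------------------------------------------------
# 3D volumes (NRRD)

def write_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a label volume as compressed NRRD (spacing in the header)."""
    img = sitk.GetImageFromArray(vol.voxels.astype(np.int16))
    img.SetSpacing(tuple(float(s) for s in vol.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in vol.origin_mm))
    sitk.WriteImage(img, str(path), useCompression=True)


def read_volume(path: str | Path, scheme: dict[str, int] | None = None) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no volume at {path}")
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path.name}: label volume has non-integer dtype {arr.dtype}")
    scheme = dict(LABELS) if scheme is None else scheme
    validate_labels(arr, scheme)
    return LabelVolume(
        arr,
        tuple(img.GetSpacing()),
        label_scheme=scheme,
        origin_mm=tuple(img.GetOrigin()),
    )


def write_density(
    density: np.ndarray, spacing_mm, path: str | Path, origin_mm=(0.0, 0.0, 0.0)
) -> None:
    """Write a float density (CBCT-surrogate) volume as NRRD."""
    img = sitk.GetImageFromArray(np.asarray(density, dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    img.SetOrigin(tuple(float(o) for o in origin_mm))
    sitk.WriteImage(img, str(path), useCompression=True)


def read_density(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img), tuple(img.GetSpacing())
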