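"""Label scheme shared by the phantom, the stack readers and the morphometry.

Integer codes are fixed so that label volumes written to disk are
self-describing together with the ``label_scheme`` entry of the manifest.
"""

from __future__ import annotations

#: Canonical compartment name -> integer code.  ``background`` must be 0.
LABELS: dict[str, int] = {
    "background": 0,
    "cartilage": 1,
    "lumen": 2,
    "mucosa": 3,
    "TVPM": 4,
    "LVPM": 5,
    "OFP": 6,
    "bone": 7,
    "fiducial": 8,
    "groove": 9,
}

#: Reverse mapping, integer code -> name.
LABEL_NAMES: dict[int, str] = {v: k for k, v in LABELS.items()}

#: Compartments plotted in the default axial profile (mucosa is available
#: behind a flag, bone/fiducial/groove are never profiled by default).
PROFILE_COMPARTMENTS: tuple[str, ...] = ("cartilage", "lumen", "OFP", "TVPM", "LVPM")


def validate_labels(values, scheme: dict[str, int] | None = None) -> None:
    """Raise ``ValueError`` listing any label codes not present in *scheme*."""
    import numpy as np

    scheme = LABELS if scheme is None else scheme
    allowed = set(scheme.values())
    present = set(np.unique(np.asarray(values)).tolist())
    unknown = sorted(present - allowed)
    if unknown:
        raise ValueError(
            f"labels {unknown} are not part of the label scheme {sorted(allowed)}"
        )
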