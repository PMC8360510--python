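import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tube3d.labels import LABELS
from tube3d.morphometry import (
    compartment_area,
    compartment_perimeter,
    mask_perimeter,
    merge_perforated,
    profile,
)
from tube3d.phantom import LabelVolume
from tube3d.sectioning import SectionImage


def _section(mask, spacing=(0.1, 0.1), label="cartilage"):
    return SectionImage((mask.astype(np.int16) * LABELS[label]), spacing, 0)


# --------------------------------------------------------------------------
# independent oracles

def marching_squares_length_oracle(mask, spacing):
    """Table-driven marching squares on a zero-padded binary mask.

    For binary data the 0.5-level crossings sit at pixel-edge midpoints, so
    each 2x2 cell contributes segment lengths that depend only on its corner
    pattern (diagonal pairs cut both corners).  Independent of the contour
    tracing used by the implementation; compared against the raw
    (``smooth_sigma=0``) contour length.
    """
    sx, sy = spacing
    m = np.pad(mask.astype(np.int8), 1)
    tl, tr = m[:-1, :-1], m[:-1, 1:]
    bl, br = m[1:, :-1], m[1:, 1:]
    corner = np.hypot(0.5 * sx, 0.5 * sy)
    total = 0.0
    for pattern in range(1, 15):
        bits = [(pattern >> k) & 1 for k in range(4)]  # tl, tr, bl, br
        cells = ((tl == bits[0]) & (tr == bits[1]) & (bl == bits[2]) & (br == bits[3]))
        n = int(cells.sum())
        if n == 0:
            continue
        ones = sum(bits)
        if ones in (1, 3):
            total += n * corner
        elif ones == 2:
            if (bits[0] and bits[1]) or (bits[2] and bits[3]):
                total += n * sx        # horizontal pair -> horizontal segment
            elif (bits[0] and bits[2]) or (bits[1] and bits[3]):
                total += n * sy        # vertical pair -> vertical segment
            else:
                total += n * 2 * corner  # diagonal pair -> two corner cuts
    return total


def union_find_components_oracle(mask):
    """Brute-force 26-connected labelling with a hand-rolled union-find."""
    idx = {tuple(p): i for i, p in enumerate(np.argwhere(mask))}
    parent = list(range(len(idx)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for (z, y, x), i in idx.items():
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dz, dy, dx) == (0, 0, 0):
                        continue
                    j = idx.get((z + dz, y + dy, x + dx))
                    if j is not None:
                        union(i, j)
    roots = {find(i) for i in range(len(idx))}
    labels = {}
    out = np.zeros(mask.shape, dtype=int)
    for (z, y, x), i in idx.items():
        r = find(i)
        labels.setdefault(r, len(labels) + 1)
        out[z, y, x] = labels[r]
    return out, len(roots)


# --------------------------------------------------------------------------
# area

def test_area_is_pixel_count_times_pixel_size():
    mask = np.zeros((5, 5), bool)
    mask[1:3, 1:3] = True
    assert compartment_area(_section(mask), "cartilage") == pytest.approx(0.04)


def test_empty_mask_has_zero_area_and_perimeter():
    sec = _section(np.zeros((5, 5), bool))
    assert compartment_area(sec, "cartilage") == 0.0
    assert compartment_perimeter(sec, "cartilage") == 0.0


def test_unknown_label_rejected():
    sec = _section(np.zeros((5, 5), bool))
    with pytest.raises(ValueError, match="unknown"):
        compartment_area(sec, "gristle")
    with pytest.raises(ValueError, match="unknown"):
        compartment_perimeter(sec, "gristle")


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_area_matches_per_pixel_summation(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((12, 14)) < 0.4
    sec = _section(mask, spacing=(0.07, 0.11))
    brute = sum(0.07 * 0.11 for r in range(12) for c in range(14) if mask[r, c])
    assert compartment_area(sec, "cartilage") == pytest.approx(brute, abs=1e-12)


def test_area_additivity_of_disjoint_masks(rng):
    a = np.zeros((10, 10), bool)
    b = np.zeros((10, 10), bool)
    a[:4], b[6:] = True, True
    sa = compartment_area(_section(a), "cartilage")
    sb = compartment_area(_section(b), "cartilage")
    su = compartment_area(_section(a | b), "cartilage")
    assert su == pytest.approx(sa + sb, abs=1e-12)


# --------------------------------------------------------------------------
# perimeter

def test_disk_perimeter_approaches_2_pi_r():
    r = 25
    ys, xs = np.mgrid[:2 * r + 5, :2 * r + 5]
    mask = (xs - r - 2) ** 2 + (ys - r - 2) ** 2 <= r * r
    per = mask_perimeter(mask, (1.0, 1.0))
    assert per == pytest.approx(2 * np.pi * r, rel=0.02)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_perimeter_equals_marching_squares_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((15, 13)) < 0.45
    got = mask_perimeter(mask, (0.3, 0.2), smooth_sigma=0.0)
    want = marching_squares_length_oracle(mask, (0.3, 0.2))
    assert got == pytest.approx(want, abs=1e-9)


def test_holes_contribute_to_total_but_not_outer_perimeter():
    mask = np.ones((11, 11), bool)
    mask[4:7, 4:7] = False
    total = mask_perimeter(mask, (1.0, 1.0))
    outer = mask_perimeter(mask, (1.0, 1.0), outer_only=True)
    assert total > outer


def test_isoperimetric_inequality_on_convex_masks():
    for side in (4, 9, 15):
        mask = np.zeros((side + 4, side + 4), bool)
        mask[2:2 + side, 2:2 + side] = True
        p = mask_perimeter(mask, (1.0, 1.0))
        a = mask.sum()
        assert p ** 2 >= 4 * np.pi * a - 1e-9


# --------------------------------------------------------------------------
# 3D merging

def _volume(mask):
    return LabelVolume(mask.astype(np.int16) * LABELS["OFP"], (0.1, 0.1, 0.363))


def test_blobs_joined_only_through_adjacent_section_merge_to_one_unit():
    mask = np.zeros((3, 3, 3), bool)
    mask[0, 0, 0] = True
    mask[2, 0, 2] = True
    mask[1, 0, 1] = True   # touches both diagonally across z
    _, log = merge_perforated(_volume(mask), "OFP")
    assert log["n_components"].max() == 1


def test_blobs_never_adjacent_stay_two_units():
    mask = np.zeros((3, 5, 5), bool)
    mask[0, 0, 0] = True
    mask[2, 4, 4] = True
    comp, log = merge_perforated(_volume(mask), "OFP")
    assert len(np.unique(comp[comp > 0])) == 2


@pytest.mark.parametrize("seed", range(4))
def test_component_labelling_matches_union_find_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((12, 12, 12)) < 0.18
    comp, _ = merge_perforated(_volume(mask), "OFP")
    oracle, n_oracle = union_find_components_oracle(mask)
    assert comp.max() == n_oracle
    # identical partitions: co-membership must agree voxel for voxel
    got = comp[mask]
    want = oracle[mask]
    pairs = {(g, w) for g, w in zip(got, want)}
    assert len(pairs) == n_oracle


# --------------------------------------------------------------------------
# profiles

def test_single_section_stack_profiles_once_per_compartment():
    vol = np.zeros((1, 20, 20), dtype=np.int16)
    vol[0, 2:6, 2:6] = LABELS["cartilage"]
    vol[0, 10:12, 10:14] = LABELS["OFP"]
    df = profile(LabelVolume(vol, (0.1, 0.1, 0.363)))
    assert len(df) == len({"cartilage", "lumen", "OFP", "TVPM", "LVPM"})
    assert (df.groupby("compartment").size() == 1).all()


def test_perimeter_zero_iff_area_zero(tiny):
    _, _, vol, _ = tiny
    df = profile(vol)
    assert ((df.area_mm2 == 0) == (df.perimeter_mm == 0)).all()


@pytest.fixture(scope="module")
def df(specimen):
    return profile(specimen[0])


class TestSpecimenProfileShape:
    """Axial profile properties of the reference phantom."""

    def test_cartilage_area_cv_below_10_percent(self, df):
        cart = df[df.compartment == "cartilage"]
        assert cart.area_mm2.std() / cart.area_mm2.mean() < 0.10

    def test_cartilage_perimeter_decreases_toward_isthmus(self, df):
        from scipy.stats import kendalltau

        cart = df[df.compartment == "cartilage"]
        tau, p = kendalltau(cart.z_mm, cart.perimeter_mm)
        assert tau < -0.8 and p < 1e-6

    def test_lumen_open_only_near_pharyngeal_orifice(self, df):
        lum = df[df.compartment == "lumen"]
        zmax = df.z_mm.max()
        near = lum[lum.z_mm < 0.08 * zmax].area_mm2.mean()
        far = lum[lum.z_mm > 0.3 * zmax].area_mm2.mean()
        assert far < 0.1 * near

    def test_ofp_area_decreases_toward_isthmus(self, df):
        from scipy.stats import kendalltau

        ofp = df[df.compartment == "OFP"]
        tau, p = kendalltau(ofp.z_mm, ofp.area_mm2)
        assert tau < -0.8 and p < 1e-6
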