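# Methods

This note documents the models, estimators and numerical choices behind
`tube3d`, and what the synthetic validation does and does not establish.

## The synthetic specimen

The phantom emulates an embedded cartilaginous-tube specimen at the level
of detail the downstream estimators are sensitive to, not anatomically.

**Geometry.** A block (default fixture 25 × 25 × 36.3 mm, in-plane voxel
0.1 mm, axial voxel 0.055 mm) contains a tube axis — a gently curved
polyline, quadratic in x with ±1.5 mm bow, so sectioning is not trivially
axis-aligned — running from the pharyngeal end (z = 0, section index 0) to
the middle-ear end. At each z the cross-section is drawn in the section
plane around the axis point, rotated by

    θ(z) = θ₀ + T · s(z)/s_total ,

with `T = twist_total_deg` and `s` arc length: the twist is linear in arc
length and exactly known, which makes `T` the ground truth for torsion
recovery. The cartilage is a J of two stadium-shaped laminae (long medial
8 mm, short lateral 3 mm, thickness 1 mm). Along the axis the lamina
lengths scale by `s(t) = 1 − 0.2 t` and the thickness by `1/s(t)`: the
cross-sectional area stays constant while the perimeter falls — the
"increasingly compact cartilage towards the isthmus" that the axial
profiles are meant to detect. The lumen is a slit on the concave side of
the medial lamina whose width profile is open (0.45 mm) only near the
pharyngeal orifice and nearly closed (0.02 mm, sub-voxel) elsewhere; a
0.15 mm mucosa band lines it. TVPM, LVPM, OFP and bone are ellipses placed
relative to the axis; the OFP radii taper linearly towards the isthmus,
and bone exists only in the last third. Three needle fiducials (radius
0.45 mm, i.e. 0.9 mm cannulas) are straight 3D lines within 1.5° of the
mean axis direction; rasterisation refuses (hard error) any fiducial voxel
that would overwrite cartilage or lumen. Three grooves are carved into the
lateral block faces.

Labels are painted at voxel centers in a fixed priority order (bone <
muscles < fat pad < mucosa < lumen < cartilage < fiducial < groove).
Geometry is deterministic; the seed only drives optional surface roughness
(off by default). A CBCT surrogate maps labels to relative densities
(metal/bone 1.0, soft tissue 0.25–0.5, embedding 0.1, grooves 0) and
box-averages to 0.3 mm; trailing voxels that do not fill a box are
trimmed, so on commensurate grids the filter conserves the mean exactly.

**What it does not emulate:** stain texture and intensity variability,
tears/folds, saw-kerf artefacts beyond rigid motion, curved needles, real
CBCT physics. Consequences for interpretation are discussed at the end.

## Sectioning model

One section = the mid-plane nearest-neighbour resample of its 33 µm slab
(one digitised image per section; where in the slab the imaged face lies
is a convention — mid-plane here). Sections occur every
`period = 33 + 330 µm = 363 µm`. Per section a rigid in-plane perturbation
is drawn (translation SD 0.3 mm, rotation SD 2°, about the image center)
and applied to the image; a small cutting-plane tilt (SD 0.2° per
component) is drawn but — first order — only offsets the groove readings
(the in-image shift of a needle centroid from tilt is ~2 µm and is
neglected, as is the sub-1% ellipticity of an oblique needle
cross-section). Groove readings are
`block_height − (local_index+1)·period` plus the tilt-plane offset at each
groove position plus Gaussian reading noise (5 µm SD). The default lost
sections are the first of each block half. All draws for all section
indices come from one seeded stream, so losing different sections does not
reshuffle the kept ones.

## Alignment estimator

Unknowns: three 3D lines (parameterised `x = a + b z`, `y = c + d z`) and
one rigid 2D transform per section; cost: sum of squared in-plane
distances between transformed detections and the line intersections with
each section plane. Solved by block coordinate descent whose two blocks
are exact minimisers — planar Procrustes per section given lines, and a
joint linear solve of all translations *and* line parameters given
rotations (the translation/line coupling is where plain alternation
zig-zags) — plus one Gauss–Newton step per iteration over all parameters,
offered at several backtracking scales and Levenberg dampings and adopted
only if it lowers the exact cost. The recorded cost history is therefore
non-increasing by construction; iteration stops at a relative change
below 1e-10 (or 200 iterations, recorded as `converged=False` — with
noisy detections the cost plateaus at the noise floor while still creeping
along near-flat directions, which is not a failure).

**Gauge.** Straight lines determine the solution only up to (i) a global
rigid motion, (ii) a translation drift linear in z (tilted lines absorb it
exactly), and (iii), to first order in angle, a rotation ramp linear in z
(a soft, quartic-cost mode — the classic twist ambiguity of
serial-section reconstruction, which the original workflow resolves by
registering to a tomogram of the uncut block). The returned transforms are
normalised to mean-zero, trend-free rotation and translation;
`normalize_transform_gauge` is public so ground-truth comparisons apply
the identical convention. Zero-mean, trend-free is also the statistically
correct prior for mounting perturbations, which are independent per
section.

Sections with fewer than two usable fiducial detections do not constrain
the fit; their transforms are interpolated from neighbours and flagged.
Corrected z comes from the mean groove reading per section
(`z_i = block_offset + height − mean(remaining) − period`, exactly
`i·period` when noiseless); the plane through the three groove points
estimates the cutting tilt. A median fallback replaces the mean when the
three readings disagree by more than a tilt allowance (3σ_tilt over the
groove span) plus 3× the reading noise — with only three readings a
smaller threshold would misfire on legitimate tilt.

The fit reports per-detection residuals, their norm-RMS, and a
dof-corrected noise scale (observations minus effective parameters,
gauge dimensions returned to the residual). For per-coordinate detection
noise σ, the expected residual norm-RMS is ≈ 0.99σ (per-coordinate
deflation factor ≈ 0.70 from the 3-points-per-section fit).

## Registration, morphometry, torsion, meshes

**Registration** is the closed-form Horn/Kabsch fit on matched landmarks
(≥3, non-collinear; SVD sign-corrected so no reflection can be returned),
with FRE = RMS post-fit distance. Stack landmarks are the fitted cannula
lines sampled at the first/median/last section planes.

**Area** is an exact pixel count times pixel area. **Circumference** is
the length of the 0.5-level marching-squares contour, holes included
(a folded, closed lumen shows a large circumference at near-zero area —
the observation the profiles exist for); an outer-boundary-only column is
reported alongside since either convention is defensible. The raw binary
contour is a midpoint staircase that overestimates smooth boundaries by up
to ~8%, so by default each closed contour polygon is smoothed along its
arc (Gaussian, σ = 1 vertex) before measuring: rasterised disks of radius
≥ 20 px then come out within ~1% of 2πr, at the price of rounding genuine
corners by about a pixel. Contours with fewer than 20 vertices are left
raw, so the perimeter of any nonempty mask is strictly positive
(perimeter = 0 ⇔ area = 0 holds exactly). `smooth_sigma=0` exposes the
uncorrected staircase length. **Perforation merging** labels each
compartment in 3D with 26-connectivity (in-plane 8-connectivity plus any
face/edge/corner adjacency across the one-period z gap); per-section
component counts refer to these merged functional units.

**Torsion.** Orientation per section is the major principal axis of the
compartment mask from second central moments, in degrees CCW (y-up) in
(−90°, 90°]; the anisotropy ratio √(λ₁/λ₂) gates reliability (< 1.05 →
near-isotropic, excluded). The sequence is unwrapped by choosing, per
step, the 180° multiple minimising the jump (error if a step is exactly
ambiguous at 90° per unit gap; the bound scales with index gaps from lost
sections). Total torsion is the endpoint difference of the unwrapped
sequence; a least-absolute-deviations line (IRLS) provides slope and R².
Reversing the section order negates the total exactly; rotating all
sections by a common angle leaves it unchanged.

**Meshes** come from marching cubes at 0.5 on the zero-padded binary mask
with the anisotropic spacing applied, so solid compartments are
watertight; volumes are computed by the divergence theorem. Output is
binary little-endian STL (80-byte header, uint32 count, 50 bytes per
triangle); reading validates the byte layout and reports the offset of
the first inconsistency. Laplacian smoothing is off by default and, when
requested, runs pass by pass and stops before the enclosed volume drifts
more than 5%.

## Pipeline, seeding, determinism

`run_pipeline` executes phantom → section → align → register → profile →
torsion → mesh with dependency validation, per-stage logging and a JSON
run report. One global seed is fanned out per stage through a seed
sequence keyed by the stage name, so toggling one stage does not reshuffle
another's draws; identical configuration and seed give byte-identical CSV
and JSON outputs (fixed float formatting, sorted keys).

## Problem sizes

The reference fixture uses a 0.1 mm in-plane voxel (needle cross-sections
~64 px, lamina orientation resolved to ≪ 0.1°) and 0.055 mm axial voxel
(twist sampling error ~0.03°); one phantom build plus a full
section-align-estimate cycle takes a few seconds, and the headline
ten-seed torsion-recovery experiment completes in well under a minute on
one CPU. Unit-level tests use a scaled-down phantom (14 mm block, 12
sections) with the same protocol constants.

## Known limitations

- The rotation-ramp gauge mode is fundamentally unidentifiable from
  straight fiducials at first order; detrending fixes it to zero, which is
  correct for trend-free mounting noise but would silently remove any
  *real* systematic per-section rotation drift. The original workflow's
  tomographic registration is the physical resolution of this ambiguity;
  here the reference volume is used only for landmark registration and FRE
  reporting.
- Recovered total torsion is the endpoint difference over the *kept*
  sections: lost end sections shave off their share of twist (~0.6° for
  the default protocol), a bias inherent to the measurement, not the
  estimator.
- Tilt is first-order: groove readings feel it, image content is not
  re-warped. At the protocol's 0.2° SD the neglected in-plane effects are
  micrometres.
- Perimeter smoothing rounds genuine corners (~1 px); thin 1-px structures
  keep a positive but underestimated circumference. Area is exact always.
- Passing phantom recovery shows the estimators are correct under the
  modelled degradations (rigid mounting error, tilt, loss, quantisation).
  It does not certify robustness to stain variability, nonrigid section
  distortion, or detection failures in real RGB imagery — real-data use
  enters at `FiducialTracks`/`SectionImage` with labels or detections
  produced upstream.
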