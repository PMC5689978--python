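# Methods

This note records the models, conventions and numerical choices behind
`brachydeck`, in the spirit of a methods section: what is computed, under
which assumptions, and where the design was genuinely open.

## Coordinate and unit conventions

Everything lives in the DICOM patient frame (LPS), in millimetres, with
voxel-center addressing. Arrays are indexed `[k, j, i]` = (slice, row,
column) mapping to (+z, +y, +x). Only axis-aligned axial volumes are
supported; oblique series are rejected on read, because the phantoms and
the clinical exports this pipeline targets are axial and supporting
oblique lattices would complicate the deck geometry for no current user.
TG43 quantities use centimetres (radii), degrees (polar angle from the
source long axis, tip side = 0°), U for air-kerma strength and cGy/h for
dose rate; plans carry seconds and rendered grids Gy, with the single
conversion 1/(3600·100) applied in `render_rtdose`.

## DICOM dialect

Brachytherapy RT Plans are not uniquely transferable between planning
systems, so the reader supports one documented channel layout and rejects
others explicitly: each channel's control-point sequence lists the
catheter reconstruction points (tip first) once each, followed by every
dwell position twice (arrival/departure) with a cumulative time-weight
increment. Per-dwell times are reconstructed with the standard encoding

    t_i = (w_depart − w_arrive) / FinalCumulativeTimeWeight × ChannelTotalTime.

A consequence of the duplicate-pair convention is that a dwell lying
exactly (within 1 µm) on a catheter path point would be mis-grouped; the
phantom generators therefore keep path points offset half a step from
dwell positions, and the writer preserves this property, making plan
round trips exact to the DS-string precision (≤ 1e-3 mm, ≤ 1e-6 s).

UIDs are generated deterministically from an integer seed so written
fixtures are byte-reproducible. RT Dose values are stored as 32-bit
integers with `DoseGridScaling = max/ (2³² − 1)`; the worst-case
quantization is half an LSB, i.e. ~1.2e-10 of the grid maximum.

## Voxel material model

Density is piecewise-linear in HU between calibration anchors, clamped
outside them (clamping is the contract: air below −1000 HU and the
densest anchor above). The default anchors are
(−1000, 0.0012), (−700, 0.30), (0, 1.00), (300, 1.20), (1200, 1.85),
(3000, 2.70) g/cm³ — a conventional soft-tissue/bone curve, replaceable
via CSV since clinical calibrations are scanner-specific.

Density is then **truncated** (toward zero, not rounded) to two
significant digits, and optionally collapsed onto a 54-bin scheme. The
truncation order — truncate first, then bin — means the binner only ever
sees values on the 2-significant-digit grid, which is 0.01 g/cm³ wide
below 1 and 0.1 g/cm³ wide above. The bundled scheme respects that
quantization: one bin for near-air densities, 25 bins of 0.032 g/cm³
across 0.05–0.85 (lung/adipose), eight fine 0.02 g/cm³ bins across
0.85–1.01 (soft tissue, with the water bin's representative exactly
1.00), nineteen 0.1-aligned bins to 2.91 and a final closed bin to 3.0 —
54 in total. Every representative is itself a 2-significant-digit value,
which makes truncate-then-bin idempotent; fine bins above 1 g/cm³ were
deliberately avoided because no truncation-stable representative exists
there. Numerically, truncation computes `floor(d/scale + 1e-6)·scale`
with `scale = 10^(e−1)`; the 1e-6 mantissa epsilon (quantization unit is
1) prevents representation error from flipping exact values down a step.

Elemental composition comes from a 23-row density-partitioned table in
the Schneider CT-segmentation style: air, lung, adipose, breast,
water-equivalent soft tissue, muscle, liver, cartilage, thirteen graded
skeletal rows (1.10–1.75 g/cm³, compositions interpolated between
red-marrow-rich and cortical bone), dense bone and cortical bone. Ranges
are half-open [low, high) with the last closed; boundary densities belong
to the row whose range starts there; out-of-range values clamp to the end
rows. Mass fractions sum to 1 within 1e-6 (the CSV absorbs rounding
residue into the largest element).

In-plane down-sampling (factors 2/4/8) block-averages HU *before* any
density assignment, matching the principle that the image, not the model,
is down-sampled. The pooled HU is kept at float precision so the volume
mean is conserved exactly; matrices not divisible by the factor are
padded with air on the high-index side.

## Source model

The source long axis at a dwell is the unit vector from the higher-index
to the lower-index of the two catheter control points nearest the dwell
center — control points are ordered tip first, so this points tip-ward.
The sign convention (tip = +z = θ 0°) is a package convention; the
about-axis rotation is left free (minimal rotation, axis = z×d) because
HDR sources are axisymmetric. Distance ties are broken toward the tip,
which makes a dwell coincident with a control point behave continuously
under perturbation.

Dwell selection for phase-space replay is per photon, with probability
t_i/Σt — the natural reading of sampling from the dwell-time fraction
distribution (the alternative, partitioning the file into contiguous
per-dwell segments, would correlate record order with position).

The `.phsp` format is repo-defined: one ASCII header line
`PHSP1 <source_id> <n_records> <n_emitted>` followed by little-endian
float32 ×7 records (E MeV, x y z mm, u v w), chosen for streaming reads
and bit-exact round trips. The bundled toy generator emits photons from
the lateral surface of a 0.9 mm × 3.6 mm cylinder, isotropically, with
energies from the ¹⁹²Ir line spectrum (standard nuclear-data intensities,
editable CSV). It intentionally models no capsule attenuation or
scatter — it exists to exercise transforms, sampling and I/O, not to be
dosimetrically accurate. Likewise the emitted deck contains no source
structure, so backscatter traversing the source volume would not be
handled correctly by a transport run; the effect is small for the small
volume of HDR ¹⁹²Ir sources.

## TG43 engine

The geometry factor uses the two-arctangent form
β = atan2(x+L/2, y) − atan2(x−L/2, y) with x = r·cosθ, y = r·sinθ, which
is stable near the long axis; for sinθ < 1e-6 it switches to the closed
form 1/(r² − L²/4), valid only outside the source (r > L/2, enforced).
L = 0 degenerates to 1/r². Radial dose interpolation is linear in log r;
anisotropy interpolation is bilinear in (r, θ); both clamp outside their
tables with a logged warning rather than extrapolating.

Rendering clamps radii below 0.2 cm (just beyond L/2 = 0.18 cm of the
default active length) so the handful of voxels containing the source
stay finite; no claim of accuracy is made inside that radius.

The bundled g_L and F tables are smooth synthetic curves
(g = 1 + 0.009(r−1) − 0.0035(r−1)², F = 1 − (0.15 + 0.02 ln r)|cosθ|^2.5)
normalized exactly at (1 cm, 90°). They are *test* tables: published
consensus data for a real source can be dropped in as CSV, but bundling
none avoids implying a validated source model.

## Extraction and comparison

g/F extraction inverts the dose grid through the line-source formalism,
sampling trilinearly. Transverse-axis doses are averaged over the two
opposite transverse directions (azimuthal averaging beyond that is
unnecessary on TG43-rendered grids, which are azimuthally symmetric by
construction). Accuracy is dominated by trilinear interpolation against
the ~1/r² curvature: sample points that fall on voxel centers are exact,
off-grid points at radius r on a grid of spacing h carry an O((h/r)²)
error (~0.75% at r = 1 cm, h = 1 mm). The parameter-recovery checks
therefore place the dwell on a voxel center of a 1 mm grid and use
whole-millimetre radii for g; F is extracted on the 5° table grid where
the bound is ≤ 1% for θ ∈ [10°, 170°].

Difference maps are 100·(test−ref)/ref on voxels where the reference is
positive, optionally intersected with a body mask and a density-derived
air exclusion (default threshold 0.05 g/cm³ — the policy of excluding
air is standard, the threshold is a package default). Voxels inside
catheters are not excluded. Grids with matching extents but different
spacing are resampled trilinearly onto the reference.

DVHs rasterize contours at voxel centers with the even-odd rule, each
polygon toggling membership on its slice, so holes behave correctly.
Skin is dilation minus erosion of the body mask, one pass each, with the
2D 3×3 cross structuring element applied slice by slice — contours are
per-slice planar objects, so 3D morphology would couple slices that the
contouring never related.

## Deck encoding

One lattice universe per distinct (tissue row, density) pair — at most
23 × 54 by construction, 2 for the binary water sphere. The FILL array is
written x-fastest, then y, then z (stated in a deck comment) using the
`nR` repeat syntax; cards wrap at 80 columns with 5-space continuation.
Mass fractions are negative-signed (mass-fraction convention) and the
printed values are adjusted on the largest element so each card sums to
−1 at the printed precision. `validate_deck` is an independent
mini-parser used as a round-trip oracle: it re-expands the FILL repeats,
re-counts universes and materials and re-checks fraction sums. NPS equals
the phase-space record count, mirroring replaying each stored photon
once; no variance-reduction cards are emitted.

## What the synthetic fixtures do and do not show

The water-sphere phantom is binary at voxel centers (no partial-volume
HU, no noise, no beam hardening), so tests on it validate geometry,
bookkeeping and the dosimetric formalism — not CT calibration realism.
The multicatheter plan is a regular grid of parallel catheters with
reproducible times, exercising multi-dwell kinematics, not clinical
implant geometry. Passing the suite therefore demonstrates that the
pipeline parses, transforms and tallies correctly and that rendering and
extraction are mutually consistent; it does not certify agreement with a
commercial planning system or a transport code, which requires running
the emitted deck.

## Problem sizes

The parameter-recovery checks render a 201³ voxel, 1 mm cube (20 cm) in a
few seconds; the full-scale bookkeeping checks use the reference
256×256×320 study (~21 M voxels), chosen to match the reference phantom
exactly. The geometry-factor oracle integrates numerically on a 20×18
(r, θ) grid to a 1e-12 relative quadrature tolerance.

## Known limitations

- No transport is run; tally specifications are emitted, not evaluated.
- One plan dialect; applicators, oblique series and electron records are
  unsupported.
- The toy phase space is not a validated source model.
- Down-sampled volumes carry float HU; writers round to integers.
- g/F extraction assumes a single dominant dwell (the pose argument);
  multi-dwell grids must isolate the dwell of interest first.
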