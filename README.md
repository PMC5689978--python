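# brachydeck

Tools for QA of high-dose-rate (HDR) ¹⁹²Ir brachytherapy dose calculations:
parse a treatment plan exported in DICOM RT format, build a voxelized
computational model from the CT series, emit a Monte Carlo (MCNP-style)
input deck with phase-space source handling, and compare dose
distributions with the TG43 formalism.

## Who this is for

Medical physicists and researchers who want an independent, transport-ready
model of a clinical brachytherapy plan. A planning system ships a dose
grid; checking it requires (a) reconstructing the geometry the system saw —
voxel densities and tissue compositions from CT, source positions,
orientations and dwell times from the plan — and (b) a common dosimetric
language for the comparison. `brachydeck` automates both ends and includes
synthetic phantom generators so the whole pipeline is testable without
patient data.

## What it computes

**TG43 dose formalism.** Around a line source of active length *L*, the
water dose rate is

    Ḋ(r, θ) = S_K · Λ · [G_L(r, θ) / G_L(r₀, θ₀)] · g_L(r) · F(r, θ)

with air-kerma strength S_K (U), dose-rate constant Λ (cGy h⁻¹ U⁻¹), the
line-source geometry factor G_L = β/(L·r·sinθ), the radial dose function
g_L(r) and the 2D anisotropy function F(r, θ), normalized at r₀ = 1 cm,
θ₀ = 90°. The engine renders RT Dose grids from these quantities and the
benchmark module inverts a dose grid back into g_L and F tables — a
parameter-recovery loop that validates both directions.

**Voxel model.** Each CT voxel gets a mass density from a piecewise-linear
HU calibration, truncated to two significant digits, optionally collapsed
onto a 54-bin density scheme, and an elemental composition from a 23-row
density-partitioned tissue table. The emitted deck encodes the model as a
rectangular lattice with exactly one element per CT voxel, an F6
collisional-kerma tally, and a mesh tally of energy fluence weighted by
μ_en/ρ of water over the RT Dose grid extent. The source is a `.phsp`
phase-space sidecar replayed through per-dwell rigid transforms, each
chosen with probability equal to the dwell's share of the total
irradiation time.

**Comparison metrics.** Percentage-difference maps 100·(test−ref)/ref and
their histograms, cumulative DVHs from RT Structure Set contours, and a
skin surrogate obtained by subtracting a single-pass erosion from a
single-pass dilation of the body mask.

## Worked example

Generate a water-sphere study (a 30 mm sphere here; the full reference
phantom is 150 mm radius, 340 mm FOV, 256 matrix, 1 mm slices), convert it
to a deck, render the TG43 reference dose and extract g(r) back:

```sh
brachydeck phantom --out study --radius 30 --fov 80 --matrix 32 \
    --slice-thickness 2.5 --n-slices 32 --seed 1
# wrote study to study (32x32x32 CT, 1 dwells)

brachydeck convert study/ct --plan study/rtplan.dcm --out mc \
    --phsp-photons 10000 --seed 1
# deck.inp: 32768 lattice elements, 2 materials, tallies [6], nps 1000000

brachydeck render --plan study/rtplan.dcm --out tg43_dose.dcm \
    --grid-size 81 --grid-spacing 1
# rendered 81^3 TG43 dose grid -> tg43_dose.dcm (max 4274.273 Gy)

brachydeck extract --dose tg43_dose.dcm --plan study/rtplan.dcm \
    --mode g --out g.csv
# wrote 14 rows -> g.csv
```

The deck reports 32768 lattice elements — one per voxel of the 32³ CT —
and two materials (water and air: the phantom is binary). The rendered
grid's dose at 1 cm on the transverse axis is S_K·Λ·t = 40000 U ×
1.109 cGy h⁻¹ U⁻¹ × 300 s = 36.97 Gy, and the extracted `g.csv` starts

```
r_cm,g
5.0e-01,0.994625
7.5e-01,1.010309
1.0e+00,1.000000
```

g(1 cm) = 1 by construction; g(0.5 cm) reproduces the source table value
0.994625 exactly because 5 mm falls on a voxel center of the 1 mm grid,
while the half-millimetre point at 0.75 cm shows the ~1% trilinear
interpolation error expected off-grid near the source. Comparing a grid
against itself closes the loop:

```sh
brachydeck compare --ref tg43_dose.dcm --test tg43_dose.dcm --out cmp
# {"min_pct": 0.0, "max_pct": 0.0, "fraction_within_2pct": 1.0, "n_compared": 68921}
```

## Layout

- `brachydeck.dicom_io` — CT / RT Plan / RT Dose / RT Structure Set
  readers and writers (LPS frame, mm, voxel centers)
- `brachydeck.phantoms` — synthetic water-sphere and multicatheter
  fixtures, TG43-conditions CT modification
- `brachydeck.materials` — HU calibration, density truncation/binning,
  tissue lookup, in-plane down-sampling
- `brachydeck.sources` — dwell transforms, dwell-time sampling table,
  phase-space I/O and toy generator
- `brachydeck.tg43` — geometry factor, dose rate, grid rendering
- `brachydeck.deck` — deck assembly and validation
- `brachydeck.benchmark` — difference maps/histograms, g/F extraction,
  DVHs, skin morphology
- `brachydeck.cli` — the `brachydeck` command

See `docs/methods.md` for the modelling choices and their rationale.
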