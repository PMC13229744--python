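# Methods

## Model and procedure

`dgcurve` treats a treatment plan's 3D dose grid as a scalar field
`D(x)` in Gy and characterises its fall-off by the family of nested
isodose regions `{x : D(x) ≥ d}`.  For a ladder of dose levels generated
symmetrically around the prescription dose `D0` (so that `D0` is always an
explicit level), it measures the enclosed volume `V(d)` and surface area
`S(d)` at every level and forms:

* `dDGI_d = [V(d) − V(d+Δd)] / (½[S(d) + S(d+Δd)])` — shell volume over
  mean shell surface, the average normal distance (mm) between adjacent
  isodose surfaces;
* `dDGI_N = dDGI/Δd` (mm/Gy) — step-normalised, comparable across
  configurations since raw dDGI scales with `Δd`;
* `cDGI_i = Σ_{j=i}^{D0−Δd} dDGI_j` with `cDGI_{D0} = 0` — the cumulative
  physical fall-off distance from the prescription isodose surface down to
  level `i`.  Levels above `D0` have no defined cumulative value (reported
  NaN); the curve is defined downward from the reference surface.

The dDGI at the prescription dose is the shell anchored at `d = D0`
(between `D0` and `D0 + Δd`).  When the dose maximum does not exceed `D0`
— always the case for the plateau phantom — that shell does not exist and
the shell below (`[D0 − Δd, D0]`) is used instead; the result carries an
explicit fallback flag.  Shells with zero mean surface are flagged and
excluded from the minimum-dDGI summary.

### Estimators

* **Volume**: count of voxels at or above the level (inclusive `≥`, with a
  1e-9 relative guard so plateaus exactly at the level survive
  floating-point scaling), times the voxel volume.
* **Surface (default)**: marching cubes at the 0.5 level of the binary
  mask, zero-padded so regions touching the grid edge still close.  The
  binary field is first anti-aliased with a 0.8-voxel Gaussian: raw
  level-0.5 extraction from 0/1 data tracks the voxel staircase and
  overestimates a smooth surface by a scale-invariant ~9%; the sub-voxel
  filter restores the smooth surface without moving it (sphere areas
  within ~1% across 0.25–1 mm grids).  `smooth_sigma=0` recovers raw
  binary extraction.  Masks too thin to survive the filter (smoothed peak
  below 0.5, e.g. a single voxel) automatically fall back to raw
  extraction so a surface always exists.
* **Surface (fast alternative)**: six-connectivity exposed-face counting.
  This measures the L1-projected ("Manhattan") surface, which exceeds a
  smooth surface by exactly 3/2 for a sphere; the estimate is returned raw
  (`correction_factor = 1.0`) with the factor exposed for users who want a
  calibrated variant.  Because surface area sits in the dDGI denominator,
  the method choice rescales dDGI by the inverse surface ratio; it is
  reported alongside every result.

### DVH and indices

Structure masks are built by even-odd point-in-polygon tests of voxel
centres against each contour plane (XOR across co-planar polygons, so
nested contours carve holes); contour planes match the nearest dose slice
within half the slice spacing.  The differential dose histogram over
masked voxels is binned at 1 cGy and accumulated to the cumulative DVH.
`Dx` is the largest dose still covering x% of the structure, linearly
interpolated inside the bracketing bin (on flat stretches of the curve the
upper end is taken — so a 50/50 structure at 5 and 10 Gy has D50 = 10 Gy);
values beyond the curve's support clamp to the curve end rather than
extrapolate.  `Vx` interpolates on the dose axis.  Mean dose is the
trapezoidal integral of the normalised cumulative curve; max/min are the
D2/D98 surrogates.  Structure volume is independently computed from the
contours (shoelace areas per plane, even-odd parity, times the inter-slice
thickness).  The prescription isodose volume (PIV) for the Paddick CI is
the inclusive `≥ Rx` mask.

### Prescription resolution

Precedence: explicit user override > RT Plan
(`DoseReferenceSequence` target prescription, fractions from
`FractionGroupSequence`) > estimate `5/6 · Dmax`, i.e. the grid maximum is
taken to sit at roughly the 83% isodose level, a common SRS/SABR
prescription convention.  The provenance is recorded in every output.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| dose step `Δd` | 1% of Rx | %/Gy | makes the prescription and 50% levels exact grid points; reported with every dDGI since raw dDGI scales with it |
| lower bound | 30% of Rx | — | covers the clinically relevant fall-off range |
| surface method | marching cubes | — | quantitatively accurate; voxel method is faster but biased high by 3/2 on smooth surfaces |
| MC smoothing | 0.8 voxel | — | smallest sub-voxel width that removes the staircase bias |
| grade bounds | 3 / 5 / 7 | mm | lower-inclusive half-open bands; 3 mm is the classical SRS fall-off benchmark |
| slice-offset uniformity | 0.01 | mm | far below any clinical grid pitch |
| contour→slice matching | ½ slice spacing | mm | nearest-slice assignment without resampling |

## Synthetic phantom

The generator emulates an SRS-like plan: a uniform plateau `d0` inside a
sphere of radius `r0` with linear radial fall-off of slope `g` outside.
Defaults are the clinical SRS conditions the package targets: 1.0 mm
isotropic grid, `d0 = 13` Gy, `r0 = 10` mm, `g = 2` Gy/mm (placing the
cumulative 50%-fall-off distance at 3.25 mm, within the 1.4–6 mm range
typical of single-fraction SRS).  The linear profile was chosen over
inverse-square or Gaussian fall-off because it makes every analysed
quantity closed-form: isodose radius `r(d) = r0 + (d0−d)/g`, sphere
volume/surface, shell dDGI `= Δd/g`, cDGI `= (d0−d)/g`, and
`GI = (1 + d_f/r0)³` with `d_f = 0.5·d0/g`.  An optional second slope
below a breakpoint dose yields a piecewise-linear profile whose minimum
dDGI differs from the dDGI at the prescription.  A multi-sphere variant
(voxelwise maximum of disjoint components) mimics multi-target geometries;
it refuses configurations whose components overlap at the lowest analysed
level, where the closed forms would stop holding.

The dose grid is placed with a seeded sub-voxel offset relative to the
sphere centre.  Exact lattice alignment is a degenerate geometry — whole
shells of voxel centres sit exactly on an isodose sphere — that inflates
voxel-count errors several-fold; clinical grids are never aligned to the
target, and a generic offset reproduces the realistic case.  Bundles are
written as standards-conformant RT Dose / RT Structure Set / RT Plan files
with `DoseGridScaling = 1e-4` Gy (quantisation ≪ 0.01% of the
prescription) and all UIDs derived by hashing the spec and seed, so
identical inputs produce bit-identical files.

What the phantom does **not** emulate: concave or irregular target shapes,
heterogeneous tissue, multi-focal plateaus with interacting dose regions,
delineation noise (beyond the optional paired jitter used for
reproducibility simulations), and non-isotropic grids.  Tests passing on
the phantom therefore establish the correctness of the estimators and
index algebra, not the clinical behaviour of the metrics on complex
anatomy.

## Numerical choices and degenerate inputs

* Problem sizes: validation suites use spheres of 10–20 mm radius on
  0.5–1 mm grids with 5–10% steps, where all estimators sit well inside
  their tolerances (volumes ≤ 0.2% vs closed form, surfaces ≤ 0.7%,
  per-shell dDGI ≤ 2.2%, cDGI at 50% ≤ 1.4%); resolution rules are
  spacing ≤ r/10 and shell thickness ≥ 2 voxels.
* Level ladders stop upward at the first empty isodose mask above the
  prescription; the step must leave at least two levels or the
  configuration is rejected.
* Self-intersecting contour polygons are not repaired (shoelace applied
  as-is with absolute value); contours with fewer than 3 vertices are
  dropped with a warning; single-plane structures need an explicit slice
  thickness.
* Correlations use scipy's t-distribution p-values for both Pearson and
  Spearman at every sample size — an exact permutation Spearman test is
  infeasible beyond trivial n and a Monte-Carlo version would make an
  otherwise deterministic pipeline seed-dependent.  Constant series yield
  flagged NaN correlations.  No multiple-testing correction is applied.
* Mean absolute percentage difference excludes pairs with zero mean
  (flagged); volume subgroup bands are lower-inclusive, so a 1.000 cc
  target falls in the 1–3 cc band.
* Patient demographics are parsed and echoed in reports for verification
  but never used in computation.

## Known limitations

* No voxel supersampling for small structures: masks use voxel centres
  only, biasing DVHs of structures a few voxels across; structures much
  smaller than the grid pitch may produce empty masks.
* The voxel surface method's correction factor defaults to 1.0 (raw
  exposed-face area); calibrated factors from other implementations are
  not reproduced, only exposed as a parameter.
* Single-plan analysis only; no multi-plan comparative scoring, no BED/
  EQD2 conversion, no CT handling or registration, no DICOM networking.
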