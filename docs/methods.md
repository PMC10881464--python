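# Methods

## The measurement problem

Bone-augmentation materials are evaluated in vivo by creating critical-size
defects (CSD) — here 8 mm circular, trephine-cut defects in rabbit calvaria
— grafting them, and quantifying how much new bone has formed after a
healing period. Histology, the traditional readout, is destructive and
samples only a few 2D planes. Micro-CT provides the full 3D volume, but the
interesting biology is spatially structured: new bone grows inward from the
defect margin, so a single whole-defect number hides the difference between
a graft that supports central ossification and one that only preserves the
periphery. `defectvol` implements a zonal volumetric analysis that makes
the radial structure of healing explicit, together with the group
statistics used to compare graft materials.

## Equal-volume cylindrical partition

Each defect of radius R is modeled as a cylinder normal to the calvarial
plate, split into three coaxial regions of equal volume — a central
cylinder (*inner*) and two tubes (*middle*, *outer*) — plus a fourth
concentric annulus (*control*) of the same volume immediately outside the
defect, representing pristine bone. Because all four regions share one
axial extent, equal volume reduces to equal cross-sectional area, with
closed-form radii

    r1 = R/√3,   r2 = R·√(2/3),   Rc = 2R/√3,

so that π r1² = π(r2²−r1²) = π(R²−r2²) = π(Rc²−R²) exactly. For the 8 mm
defect (R = 4 mm): r1 ≈ 2.309, r2 ≈ 3.266, Rc ≈ 4.619 mm.

Voxels are assigned to regions by the position of their **centers**
(index + ½ scaled by spacing), with half-open boundaries whose ties go
inward: inner for d ≤ r1, middle for r1 < d ≤ r2, outer for r2 < d ≤ R,
control for R < d ≤ Rc. This rule is deterministic, trivially matched by a
per-voxel brute-force oracle (tested exhaustively on grids up to 64³), and
invariant under in-plane 90° rotations of the grid about the defect axis.
Voxelization makes the four region volumes only approximately equal; the
pairwise count mismatch decreases with spacing and is ≈0.11% at the 0.046 mm
grid used throughout the tests (well below the 0.5% we require).

**Axial extent.** The source workflow does not fix the cylinders' height.
Our rule: the z-range of bone voxel centers inside the control annulus,
expanded by one voxel on each side — tying the cylinder height to the local
"normal bone thickness" the control annulus is meant to represent. The
range can always be overridden per defect in the configuration; it is never
defaulted silently when the control annulus contains no bone.

**Control semantics.** The control annulus is equal in *volume*, not
matched in bone content. Regeneration percentages can therefore exceed 100
and are never clipped. Graft found in the control annulus (spillover) is
reported as a warning but not subtracted.

## Segmentation

Bone and mineralized graft are separated from background by gray-level
thresholds: explicit half-open intervals, or an automatic 3-class split.
The automatic mode seeds two cut points with 3-class multi-Otsu and then
iterates a Lloyd-style refinement (move each cut to the midpoint of the
adjacent class means) until stable. The refinement exists because
multi-Otsu's objective is flat across empty histogram valleys — any cut in
a gap is equally optimal — whereas the mean-midpoint fixpoint is unique and
lands at the geometric midpoint between class gray levels. The cut points
actually used are logged so no interactive step is needed to reproduce a
run.

Residual graft particles are connected components of the graft class,
26-connected by default (configurable to 6 or 18); per-particle volumes are
voxel counts × spacing³ and sum exactly to the total graft volume.

## Quantities

Per defect region (inner/middle/outer):

* **regeneration %** = 100 × bone volume in region / bone volume in the
  control annulus of the same defect. The denominator is bone-only: the
  control is described as pristine *bone*, and an ungrafted annulus
  contains nothing else.
* **graft fraction %** = 100 × graft / (bone + graft). For an ungrafted
  defect with bone present this is 0 by definition; it is NaN (undefined,
  excluded from group statistics) only when bone + graft = 0.

**Corticality.** A defect is classified uni- vs. bi-cortical from the
inferior cortical band: for every axial column through the inner region,
test for bone in [z_low, z_low + band]; the coverage fraction ≥ 0.5 means
the inferior plate is substantially intact (uni-cortical). Band defaults to
25% of the cylinder height; both parameters are configurable and recorded
in the report. The rule is this package's own operationalization of a 3D
morphology readout that is usually described qualitatively.

## Group statistics

Published results in this field are printed as mean ± SD with n per group.
One-way ANOVA, the Tukey–Kramer procedure and the pooled two-sample t-test
are exact functions of those moments, so all routines have
summary-statistics forms; the raw-data forms reduce to them (a tested
identity, ≤1e−10 relative on F). Printed SDs are treated as sample (n−1)
standard deviations and the two-sample t is pooled, not Welch — the
combination that reproduces every published p-value we checked to within
±0.005 (the bound imposed by the tables' two-decimal rounding).

Tukey–Kramer: q_ij = |m_i − m_j| / √((MSW/2)(1/n_i + 1/n_j)), with the
adjusted p from scipy's studentized-range distribution (k groups, within
df); for k = 2 this reduces to the pooled t-test p (tested to 1e−8).
Degenerate inputs (all-zero variances, zero-variance paired differences)
return explicitly flagged degenerate results instead of dividing by zero.
No correction beyond Tukey itself is applied. The ANOVA's type-I error
under the null (four equal-mean normal groups of eight) is checked by
simulation: 10⁴ cohorts give a rejection rate within 0.05 ± 0.01.

Defects are treated as independent observations, as in the original
analysis; per-animal nesting is recorded in the output CSV so users can fit
hierarchical models elsewhere.

## Synthetic phantoms

Because the study's raw scans are not publicly deposited, all volumetric
tests run on phantoms with exact ground truth. A phantom is a flat bone
plate (default 2 mm thick, the calvarial thickness scale) carrying circular
defects of default radius 4 mm, each surrounded by pristine plate serving
as its control annulus. Healing is emulated per region by a target bone
fill fraction laid down either as an **annular front** growing inward from
the region's outer margin (the dominant observed pattern) or as scattered
**bony islets** (spheres, emulating central ossification nuclei; also the
right choice when a 2D section must be a stereologically unbiased sample of
the 3D fills). Residual graft is placed as non-overlapping spheres with
diameters uniform in 0.25–1.0 mm (the granule sizes of the commercial
materials), by rejection sampling with a √3·spacing clearance so particles
remain distinct under 26-connectivity; 10⁴ consecutive rejections stop
placement and record the shortfall. Bi-cortical defects are through-holes;
uni-cortical defects keep the inferior 25% of the plate intact. The gray
volume is class means (0/100/200 by default) plus Gaussian noise (σ = 5,
i.e. 5% of the class separation — comfortably inside the regime where
threshold segmentation is essentially error-free, which is what lets
recovery tests isolate geometry errors from segmentation errors).

Ground truth is recorded from the final rasterized voxel counts, so
pipeline recovery can be asserted to machine precision where segmentation
is exact, and to ±2 percentage points under noise. Generation is fully
deterministic given spec + seed.

Cohorts emulate the eight-animal, four-defect design: per-subject region
fills are drawn Normal(group mean, group sd), clipped to [0, 1], one defect
per group per subject. The fills-level simulation (no rasterization) is
used for statistical calibration at 10⁴ replicates; full rasterized cohorts
are exercised at small replicate counts.

**What phantoms do not emulate:** CT physics (beam hardening, scatter,
rings, partial-volume blur beyond optional noise), irregular defect
margins, graft particle shapes other than spheres, and biological coupling
between neighboring defects. Passing recovery tests therefore demonstrates
the correctness of the geometry, counting and statistics — not robustness
to scanner artifacts, which real-data thresholds must absorb.

## 2D zonal histomorphometry

Labeled section images (bone / connective tissue / graft) are zoned by the
half-distance of pixel columns from the defect center, using the projected
3D radii (inner |x−c| ≤ R/√3, middle to R√(2/3), outer to R) so the 2D
zones are the exact planar sections of the 3D regions; an equal-width
alternative (thirds of the half-width) is available behind a flag.
Percentages follow the histometric formulas with denominator
bone + connective tissue: bone% and connective% are complements (the
complement is computed as 100 − bone% so the identity holds exactly in
floating point), and graft% shares the same denominator, so it may exceed
100 in heavily grafted sections. This denominator choice follows the
formulas stated in the histometric procedure rather than the table-header
phrasing of the published summaries, because the published numbers
themselves obey it (bone and connective rows sum to 100; graft reaches
67.44).

## Numerical and design choices

* Index order (z, y, x), z normal to the plate; world coordinates in mm;
  voxel volume is spacing³ everywhere; only isotropic spacing is accepted
  (anisotropic input is a hard error, resampling is out of scope).
* Missing spacing metadata is always a hard error, never defaulted.
* Ties at region boundaries go inward (d ≤ bound), matching the brute-force
  oracle by construction.
* Defect centers come from configuration; the z-projection circle-fit
  auto-detector is a convenience that is never applied silently.
* Test volumes use 0.046 mm spacing (half the source scans' 0.023 mm),
  keeping the standard phantom at ~3×10⁶ voxels and the full suite under
  ten seconds; all tolerances are stated at that resolution. The geometry
  converges as spacing shrinks, so finer grids only tighten the numbers.
* Seeds are explicit arguments everywhere; identical spec + seed produces
  bit-identical phantoms.

## Known limitations

* The published per-group regeneration means cannot be reproduced without
  the original scans; the statistics layer reproduces the published
  p-values from the printed summaries instead, and the imaging layer is
  validated against synthetic ground truth.
* The paired region-to-region t-tests require per-subject values that were
  never published; they are implemented and tested on simulated cohorts
  only.
* Thresholds for real scans must come from the operator (no universal
  calibration is attempted); the auto mode assumes three reasonably
  separated gray populations.
* No trabecular microarchitecture indices (Tb.Th, Tb.Sp, SMI) and no
  density calibration.
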