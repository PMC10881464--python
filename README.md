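# defectvol

Zonal volumetric micro-CT analysis of calvarial critical-size defects, for
evaluating bone-augmentation graft materials in animal models.

Critical-size defect (CSD) studies create standardized circular defects —
typically 8 mm in diameter in rabbit calvaria — fill them with candidate
graft materials, and quantify new bone after healing. Because regeneration
proceeds inward from the defect margin, whole-defect numbers blur exactly
the signal that distinguishes graft materials: what happens in the defect
center. `defectvol` partitions each defect cylinder into three coaxial
regions of **equal volume** — inner, middle, outer — plus an equal-volume
annulus of surrounding pristine bone that serves as the within-defect
control, then quantifies new bone and residual graft per region and runs
the associated group statistics.

With defect radius R and a shared axial extent, equal volumes mean equal
cross-section areas, giving closed-form radii

```
r1 = R/√3        (inner cylinder)
r2 = R·√(2/3)    (middle tube outer radius)
Rc = 2R/√3       (control annulus outer radius)
```

so that V_inner = V_middle = V_outer = V_control exactly. Per region the
package reports

* **regeneration %** — bone volume / pristine-bone volume of the control
  annulus × 100 (may exceed 100; never clipped), and
* **graft fraction %** — graft / (bone + graft) × 100,

plus a residual-particle inventory (26-connected components with
sphere-equivalent diameters) and a 3D uni-/bi-cortical morphology
classification. The statistics layer provides one-way ANOVA and
Tukey–Kramer post-hoc tests computable **directly from printed summary
tables** (mean, SD, n), paired t-tests between regions, and pooled
two-sample t-tests — so published group tables can be re-analyzed without
raw data. A synthetic phantom generator produces calvaria-like volumes with
exact voxel-level ground truth for validation, and a 2D module applies the
matching zonal analysis to labeled histological sections.

## Worked example

Generate a phantom with a known healing profile, then recover it with the
full pipeline (segmentation from the noisy gray volume, axial-extent
estimation, partitioning, quantification):

```python
from defectvol import (DefectROI, PhantomDefect, PhantomSpec, ThresholdSpec,
                       generate_phantom, partition_volume, quantify_defect,
                       threshold_segment)
from defectvol.geometry import estimate_z_extent

spec = PhantomSpec(
    plate_size_mm=(11.0, 11.0), spacing=0.046,
    defects=(PhantomDefect(
        defect_id="d1", group="DBBMb", center_xy=(5.5, 5.5),
        bone_fill=(0.2, 0.45, 0.8),     # inner, middle, outer
        graft_fill=(0.10, 0.05, 0.0),
    ),),
    seed=17,
)
gray, labels, truth = generate_phantom(spec)

seg = threshold_segment(gray, ThresholdSpec(bone_range=(50, 150),
                                            graft_range=(150, None)))
roi = spec.defects[0].roi()
roi = roi.with_z_range(estimate_z_extent(seg, roi))
quant = quantify_defect(seg, partition_volume(seg, roi))
for region in ("inner", "middle", "outer"):
    print(f"{region:>6}: regeneration {quant.regeneration_pct[region]:6.2f} %"
          f"   graft fraction {quant.graft_fraction_pct[region]:6.2f} %")
```

```
 inner: regeneration  20.06 %   graft fraction  33.24 %
middle: regeneration  44.73 %   graft fraction  10.06 %
 outer: regeneration  79.48 %   graft fraction   0.00 %
```

The prescribed bone fills (20/45/80% of the pristine plate density) come
back to within fractions of a percentage point; graft fractions equal
graft/(bone+graft) of the placed material. Re-analyzing a published
summary table is one call per region:

```python
from defectvol.datasets import micro_ct_summary, group_summaries
from defectvol import anova_from_summary, tukey_hsd_from_summary

groups = group_summaries(micro_ct_summary(), "inner", "regeneration_pct")
res = anova_from_summary(groups)
print(f"inner-region ANOVA: F = {res.F:.3f}, p = {res.p:.4f}")
print(f"blood vs DBBMb Tukey p = "
      f"{tukey_hsd_from_summary(groups).p_value('blood', 'DBBMb'):.4f}")
```

```
inner-region ANOVA: F = 7.030, p = 0.0011
blood vs DBBMb Tukey p = 0.0484
```

Only the inner region separates the graft materials (middle p ≈ 0.038,
outer p ≈ 0.156) — the zonal partition is what exposes the contrast.

A CLI wraps the same functionality:

```bash
defectvol phantom --spec spec.yaml --out run/ --seed 17
defectvol segment run/volume.nii.gz --bone 50:150 --graft 150: --out run/seg.nii.gz
defectvol quantify -c run.yaml --out results/
defectvol stats --summary summary.csv --out stats.json
defectvol histo -c histo.yaml --out zones.csv
```

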