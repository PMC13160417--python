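# trabseg

Adaptive local thresholding and trabecular morphometry for HR-pQCT-class
volumetric images.

## The problem

High-resolution peripheral quantitative CT (HR-pQCT, 60.7 μm isotropic
voxels) can image trabecular bone microarchitecture in vivo, but the
standard segmentation pipeline — Gaussian smoothing plus a fixed global
threshold of 320 mg HA/cm³ — struggles where trabeculae are fine or bone is
locally under-mineralized (e.g. carpal bones): a single global threshold
merges narrow marrow spaces and over-dilates bright trabeculae, inflating
Tb.Th and BV/TV. `trabseg` implements an **adaptive local thresholding
(AT)** segmentation for such images, alongside the two standard comparator
pipelines and the micro-CT gold-standard pathway, plus everything needed to
evaluate them: sphere-filling morphometry, spatial-agreement metrics,
DSC-maximizing parameter search, stack-shift artifact correction, and a
synthetic phantom generator so the whole pipeline is testable without any
scan data.

## The method

For a voxel *v* with spherical neighborhood *N(v)* (Euclidean ball of
radius *r* voxels, clipped at the volume border), the local threshold is

```
T(v) = min( mean N(v), (min N(v) + max N(v)) / 2 )
```

and *v* is classified as bone iff its intensity ≥ max(T(v), T_lower),
where T_lower is a global lower bound in mg HA/cm³. Connected components
smaller than a minimum structure size are then removed (26-connectivity).
Defaults are the carpal-bone optimum: r = 6 voxels, T_lower = 350
mg HA/cm³, minimum size = 16 voxels.

Comparators: `standard` = Gaussian (σ 0.8, support 1.0) + 320 mg HA/cm³;
`laplace_hamming` = Laplace–Hamming filter (ε 0.45, cutoff 0.3) + 475 per
mille; `otsu` = Gaussian (σ 2.0) + Otsu threshold (the micro-CT gold
pathway). Morphometry (Tb.Th, Tb.Sp, BV/TV) uses the maximal-inscribed-
sphere ("sphere filling") local thickness; agreement metrics are DSC, mean
Hausdorff distance, HD95 and ASSD. See `docs/methods.md` for conventions
and numerical choices.

## Worked example

```bash
# a synthetic "HR-pQCT" case: plates of thickness 0.2 mm, gaps 0.6 mm,
# degraded with PSF blur, a ±20% mineralization bias field, and noise
trabseg --seed 7 phantom --geometry plate_stack --outdir case/

# segment the degraded volume with the adaptive and the standard method
trabseg segment --method adaptive --in case/coarse.nii.gz --out at.nii.gz
trabseg segment --method standard --in case/coarse.nii.gz --out std.nii.gz

# spatial agreement with the gold mask, inside the trabecular VOI
trabseg compare --pred at.nii.gz  --gold case/gold_coarse.nii.gz \
                --voi case/voi_coarse.nii.gz --out at.json
trabseg compare --pred std.nii.gz --gold case/gold_coarse.nii.gz \
                --voi case/voi_coarse.nii.gz --out std.json

# morphometry of the adaptive segmentation
trabseg morpho --bone at.nii.gz --voi case/voi_coarse.nii.gz --out morpho.json
```

With seed 7 this prints (`at.json`, `std.json`, `morpho.json`):

```
adaptive:  dsc 0.962  hd95_mm 0.0607  assd_mm 0.0059
standard:  dsc 0.843  hd95_mm 0.0607  assd_mm 0.0277
adaptive morphometry: tb_th_mm 0.272  tb_sp_mm 0.706  bvtv 0.227
```

The truth for this phantom is Tb.Th = 0.2 mm, BV/TV = 0.25 inside the
periodic region: the adaptive mask overestimates thickness by ~0.07 mm
(one coarse voxel; partial-volume limit of the resolution), while the
standard global threshold both dilates the plates (ASSD ~5× larger) and
overlaps the gold mask visibly less (DSC 0.84 vs 0.96).

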