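# Methods

This note documents the models, conventions and numerical choices behind
`trabseg`, in enough detail to reproduce every number the package emits.

## Data model

Volumes live on regular isotropic grids; the physical position of voxel
`i` is `origin + i * spacing` (voxel-center convention, matching ITK), axis
order `(x, y, z)` with `z` axial. Density volumes declare one of three
intensity units: `mgHA_cm3` (hydroxyapatite-equivalent density from linear
scanner calibration), `per_mille` (range-normalized 0–1000, the scale on
which the Laplace–Hamming global threshold of 475 is defined), or `raw`.
Calibration is a single linear map `density = slope * raw + intercept`
supplied by the user; scanner-internal calibration procedures are not
modeled. Masks are 0/1 volumes stored as unsigned 8-bit; any nonzero voxel
read from disk is normalized to 1.

## Segmentation methods

**Adaptive local thresholding (AT).** For voxel *v*, over the Euclidean
ball *N(v)* of radius *r* voxels (clipped at the volume border — border
neighborhoods use only in-volume voxels, so no padding value can corrupt
the min/max statistics at bone–air boundaries):

    T(v) = min( mean N(v), (min N(v) + max N(v)) / 2 )
    bone(v) = [ I(v) >= max(T(v), T_lower) ]

followed by one pass of connected-component filtering that removes
foreground components smaller than the minimum structure size
(26-connectivity by default, preserving thin oblique connections). All
comparisons are `>=`. Because of the `max` with `T_lower`, the AT mask is
always a subset of the global-threshold mask at `T_lower` — the local
criterion can only remove voxels; this ordering is enforced by tests.

Defaults: kernel radius 6 voxels, lower threshold 350 mg HA/cm³, minimum
structure size 16 voxels. The default *prefilter* is none: the package's
own DSC-maximizing parameter search on its synthetic tuning phantoms (the
same selection procedure the method prescribes when moving to a new
anatomical site or dataset) favors operating on the unfiltered density
volume at these study conditions, where the neighborhood statistics and
the component filter already absorb the noise level; Gaussian and
Laplace–Hamming prefilters remain available as configuration and are what
the default search grid explores.

**Standard.** Gaussian smoothing with σ = 0.8, support = 1.0, then a fixed
global threshold of 320 mg HA/cm³. "Support" is interpreted as the
truncation half-width of the kernel in voxels: support 1.0 yields a 3×3×3
kernel whose weights are renormalized to sum to 1 after truncation.
Convolution boundary handling is symmetric (reflect) padding.

**Laplace–Hamming.** A frequency-domain filter
`H(f) = [(1−ε) + ε·L̂(f)] · W(f)` with ε = 0.45, where `L̂` is the
magnitude response of the discrete 3D Laplacian normalized to peak 1 at
Nyquist (so the blend sharpens high frequencies), and `W` is a separable
per-axis Hamming taper `w(f) = 0.54 + 0.46·cos(π f / f_c)` for normalized
frequency `f ≤ f_c` (zero beyond), cutoff `f_c` = 0.3 with 1.0 = Nyquist.
Applied by FFT. The output is affinely rescaled: to `per_mille`
(min → 0, max → 1000) for the fixed 475 per-mille threshold, or back to
the input range when the filter acts as an AT prefilter, so density-unit
lower thresholds remain meaningful. This transfer function is one concrete,
fully specified realization of the filter family; it is fixed by its
properties (linearity up to the final rescale, contrast invariance of the
per-mille output, high-frequency attenuation) rather than bit-compatibility
with any scanner firmware. Whether the original window is applied radially
or separably is not public; separable is the documented choice here. Note
that with the cutoff normalized to Nyquist, 0.3 is a strong low-pass at
60.7 μm voxel scale — one reason the package does not default AT to this
prefilter (see above).

**Otsu pathway (micro-CT gold standard).** Gaussian smoothing σ = 2.0,
support 1.0, then Otsu's threshold: the histogram-bin boundary (128
equal-width bins spanning [min, max] by default) maximizing between-class
variance, reported in the volume's intensity unit; ties take the lowest
boundary. Constant input raises (degenerate histogram).

## Morphometry

Local thickness uses the sphere-filling (maximal inscribed sphere)
definition via the Euclidean distance transform: each foreground voxel *x*
supports the open ball of radius `EDT(x)` (its distance to the nearest
background voxel center), and

    thickness(p) = 2 · max{ EDT(x) : ‖p − x‖ < EDT(x) } .

Balls are painted in descending radius order; both distances are
correctly-rounded square roots of integers, so the strict comparison is
exact. **No half-voxel surface offset is applied.** Quantization
consequence: a slab of even voxel thickness reads exactly, a slab of odd
thickness reads one voxel high (e.g. a 3-voxel plate reads 4 voxels); a
digital ball of radius R reads 2R within half a voxel. Tests pin this
convention.

Tb.Th is the mean thickness of the bone mask over bone voxels inside the
VOI; Tb.Sp is the mean thickness of the bone complement over non-bone VOI
voxels. In both cases the thickness map is computed on the full mask, so
structure outside the VOI still supports spheres reaching into it (no
artificial thinning at VOI borders); the Tb.Sp background is the VOI minus
bone, not the full image background. BV/TV is the exact integer voxel-count
ratio |bone ∩ VOI| / |VOI|. Means, not medians, are reported. Tb.N is
deliberately out of scope.

## Segmentation-quality metrics

Surfaces are foreground voxels with at least one 6-neighbor outside the
foreground, the volume edge counting as outside. Distances are Euclidean
between voxel centers, in mm. With directed distance sets
`D_ab = {d(x, S_b) : x ∈ S_a}` and `D_ba`: ASSD is the mean and HD95 the
95th percentile (linear interpolation) of the pooled multiset
`D_ab ∪ D_ba`; the mean Hausdorff distance is `max(mean D_ab, mean D_ba)`.
The pooled conventions make ASSD and HD95 symmetric; anyone comparing
against numbers produced with directed-average conventions should expect
small systematic differences. DSC is `2|A∩B| / (|A|+|B|)`, undefined
(error) when both masks are empty. Implementation computes exact distances
by a distance transform of each surface; tests verify equality with
all-pairs brute force.

## Parameter search

Exhaustive grid evaluation: for each combination of prefilter, kernel
radius, minimum structure size and lower threshold, segment every case,
intersect prediction and gold with the case VOI, compute DSC; the optimum
maximizes the **median** DSC across cases (median matches how a
distributional optimum is reported; mean vs median is not distinguishable
from the published description). Default grid: radii {3, 6, 9} × sizes
{16, 32, 64} × thresholds 250–500 step 5 (51 values) × prefilters
{gaussian, laplace_hamming} = 459 combinations per prefilter. Quartiles
use linear-interpolation percentiles. Ties break deterministically toward
smaller radius, then smaller minimum size, then larger lower threshold
(cheaper and more conservative settings); evaluation order is fixed, so
repeated runs are identical.

## Stack-shift correction

Multi-stack axial acquisitions (the wrist protocol: 1344 slices = 8 stacks
of 168) can show in-plane misalignment at stack boundaries. Correction
walks outward from a reference stack (default: stack 0, most distal); at
each boundary the first slice of the uncorrected stack is registered to
the facing slice of the already-corrected neighbor with a rigid 2D
registration: normalized-correlation metric, Euler-2D transform centered
on the slice, B-spline interpolation, regular-step gradient descent with a
one-voxel initial step, and a 3-level multi-resolution pyramid (shrink
4/2/1, smoothing 2/1/0 voxels). The metric is evaluated on a central
window excluding a 10% border: candidate transforms sweep out-of-field
background into the border, which otherwise biases the optimum (observed
as ~0.3° rotation bias on synthetic slices; with the mask, synthetic
transforms are recovered to well under 0.1 voxel / 0.1°). Because the
fixed side is already corrected, the recovered transform is directly the
composed correction for the stack; it is applied to every slice of that
stack (B-spline interpolation, background fill 0; masks would use nearest
neighbor). One slice per side is used at each boundary. Transforms are
resampling maps (output → input points), the SimpleITK convention.

## Synthetic phantoms

The generator emulates the paired-modality validation setting: an
analytic trabecular geometry sampled on a fine 0.02 mm grid ("micro-CT
gold"), and a degraded coarse 0.0607 mm volume ("HR-pQCT-like").
Geometries: parallel plates (thickness t, gap g; truth Tb.Th = t,
Tb.Sp = g, BV/TV = t/(t+g)), a 3-axis rod lattice (cylinder diameter =
feature size; truth Tb.Th = feature size), and a gyroid sheet (robustness
only; no analytic truth claimed). Degradation chain, all randomness from
one seed: multiplicative bias field (1 + a·mean of 3 random-phase cosine
products with 1–2 cycles per axis, emulating smooth local mineralization
variation; amplitude a = 0.2 by default), Gaussian PSF blur, box-average
downsampling (each coarse voxel averages the fine voxels whose centers
fall in its cube — a partial-volume/detector-binning model that makes the
no-blur-no-noise case exactly equal to block averaging), then additive
Gaussian noise.

Defaults and why: bone 700 and background 50 mg HA/cm³ (mineralized
trabecular bone vs marrow-equivalent soft tissue); PSF σ = 0.7 coarse
voxels (≈ 95 μm FWHM, the scale of second-generation HR-pQCT resolution);
noise σ = 30 mg HA/cm³; plate t = 0.2 mm / g = 0.6 mm and rod diameter
0.2 mm / pitch 0.8 mm, matching carpal trabecular scale (Tb.Th ≈ 0.2–0.25
mm, BV/TV ≈ 0.25–0.35); extent 2.4 mm. What the phantom does **not**
emulate: beam hardening, ring artifacts, projection-domain physics,
anatomically realistic bone shapes, cortical shells. Passing tests
therefore demonstrate correctness of the algorithms and the direction of
method differences under controlled degradation — not clinical accuracy on
scanner data.

On these phantoms the adaptive method beats the fixed-global-threshold
pipeline in exactly the way it is designed to: the global threshold (320)
sits below the blurred bone–marrow edge midpoint, so it dilates bright
structure and merges narrow gaps, while the AT midpoint rule tracks the
local edge; the bias field widens the gap further. The acceptance script
quantifies this (DSC, surface distances, Tb.Th error) per run.

## Degenerate inputs and edge conventions

Constant volumes: error for Otsu and for per-mille LH scaling; identity
for input-range LH. Empty masks: error for thickness, surfaces and DSC
(both empty). A VOI with no bone yields BV/TV 0 and missing (NaN) Tb.Th
with a warning; an all-bone VOI yields BV/TV 1 and missing Tb.Sp. Mask
resampling is strictly nearest-neighbor (never interpolates new labels).

## Test problem sizes

Oracle-equivalence tests run 100 seeded trials per operation on volumes up
to ~10³ (exhaustive oracles are quadratic or worse); morphometry
identities use the 0.06/0.12 mm plate phantom on a 54³ fine grid and
digital balls up to radius 7; the degraded comparison uses six phantoms
(three plate, three rod seeds) at 2.4 mm extent; registration fixtures are
96×96×24. These sizes were chosen so the full suite exercises every code
path in well under a minute of compute while keeping every oracle exact.
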