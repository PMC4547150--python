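# Methods

## Image model and pipeline

One image is one TMA cylinder: a roughly circular tissue core, much
darker than the bright scanner background, containing brown
(DAB-chromogen) stained regions which in turn enclose unstained holes —
the lumina of tumour glands and the hematoxylin-blue nuclei.

The pipeline quantifies the percent of the cylinder's area that is
stained:

1. **Lightness channel.** RGB is converted to CIE L\*a\*b\* and the L\*
   channel kept, linearly rescaled from [0, 100] to [0, 255] and rounded
   half-up. The conversion assumes sRGB primaries, D65 white and the
   standard sRGB transfer function — the common default of scientific
   imaging software; the original acquisition convention is not
   recoverable from the data, and any fixed convention only shifts the
   tissue/background separation, which is wide (white background 255 vs
   tissue ≲ 200).
2. **3×3 median filter** on the lightness channel (replicate-edge
   padding; the border rule touches only a one-pixel rim).
3. **Cylinder selection.** Threshold at L ≤ 238 (closed interval — 238
   is tissue, 239 background), 8-connected labelling, keep components
   strictly larger than `min_object_area`. Exactly one component is
   expected; if several qualify (debris, split cores) the largest wins
   and a warning is recorded, because failing the image would make batch
   runs brittle. The selected component is used as-is — no hole filling —
   for the denominator: bright artefacts *inside* tissue (tears) are
   treated as not-cylinder. Whether to fill such holes is a genuinely
   open choice; not filling keeps the denominator definition identical
   to the thresholded object.
4. **Brown channel** `B − 0.3(R+G)`, real arithmetic, rounded half-up,
   clamped to [0, 255]. The formula can reach −153; negatives are
   maximally brown and are clamped to 0 so they fall inside the stain
   window. No full colour-deconvolution (matrix-inversion) unmixing is
   attempted — the single linear translation is the method.
5. **Stain objects.** Brown ≤ 70 (closed interval) intersected with the
   cylinder mask *before* labelling, so numerator and denominator share
   one support; 8-connected labelling; objects strictly larger than
   `min_stain_object_area` (1000 px) survive. The size filter applies to
   the thresholded, *unfilled* object area — it runs before the A/B
   branch.
6. **Method A** sums the brown pixels of the surviving objects. **Method
   B** fills each object's enclosed holes first. A hole is a background
   region with no path to the object's exterior at the complementary
   connectivity (4-connected background for 8-connected objects);
   regions opening onto the boundary are not filled. Filling is
   per-object (on the object's bounding box — an enclosed hole can never
   touch it) and the per-object fills are unioned, which both avoids
   double counting when one object lies inside another's hole and
   resolves the per-object-vs-global ambiguity in favour of the simpler,
   local definition. The union is finally intersected with the cylinder
   mask so `area_B ≤ total_area` holds by construction.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `lightness_threshold_high` | 238 | upper L value (0–255 scale) still counted as tissue |
| `median_size` | 3 | median window (px) on the lightness channel |
| `min_object_area` | 1,000,000 px | minimum cylinder size; calibrated for 2-mm cores at 0.25 µm/px (a 2-mm core is ~5×10⁶ px). Scale it with resolution: desk-scale fixtures (radius ~150 px) use 20,000 |
| `brown_threshold_high` | 70 | upper brown value counted as DAB stain |
| `min_stain_object_area` | 1000 px | speckle/artefact rejection for stain objects |
| `connectivity` | 8 | labelling connectivity (ImageJ particle convention); 4 available |

All thresholds are closed upper bounds; all size filters are strict
(`area > threshold`).

## Agreement statistics

Ratings are a complete n×k grid of percent values (images × raters or
methods). The two-way random-effects decomposition gives mean squares
MSR (subjects), MSC (raters), MSE (error), and the single-rating
absolute-agreement ICC

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

the form in which each individual rater's score is the unit compared;
the average-of-k variant is available via `average=True`. The 95% CI is
the McGraw–Wong F-based construction (Satterthwaite df for the
denominator combination). Interpretation scale: poor < 0.40 ≤ acceptable
< 0.75 ≤ excellent. Bland-Altman uses the sample SD (n−1) and ±1.96
limits. The Kaplan-Meier curve of paired differences involves no
censoring — every difference is observed — so it coincides with the
empirical survival function S(d) = #{|diff| > d}/n; the implementation
goes through a survival fitter and the test suite checks the identity
against direct counting. `compare_all` runs every column pair and flags
pairs whose variances differ by a two-sided variance-ratio F test at
α = 0.05; this is a screening heuristic for the equal-variance premise
of the absolute-agreement ICC, not a formal test recommendation.

## Synthetic scenes

The generator rasterizes: a circular core (tissue RGB (190,185,215);
lightness 195), non-overlapping circular stained regions (DAB RGB
(150,90,60); brown channel clamps to 0), and per-region enclosed holes
(pale lumen gray (225,225,225); lightness 228, brown 90) on a white
background, then optionally adds seeded Gaussian pixel noise (clamped,
rounded). Ground-truth masks and counts come from the pre-noise
rasterization. Scene validation checks every colour constraint *through
the actual pipeline transforms*, not against assumed numbers.

Three deliberate design choices make "pixel-exact ground truth"
well-defined:

* **Median-stable core.** The 3×3 median on a two-class boundary is a
  binary majority vote, which can move a handful of pixels on a raw
  rasterized circle. The generator iterates the majority filter to its
  fixed point (≤ 1 iteration for disks) and draws *that* mask, so the
  pipeline's filtered, thresholded cylinder equals the ground-truth mask
  exactly.
* **Lumen colour is pale gray, not pure white.** Real lumina sit inside
  tissue and scan darker than the empty-glass background; drawing them
  at lightness ≤ 238 keeps them inside the thresholded cylinder
  component, as the 238 operating threshold intends.
* **Holes never fragment a region.** Holes are rejection-sampled to be
  pairwise ≥ 2 px apart and ≥ 2 px inside the region rim. Overlapping
  holes can isolate a tiny stain sliver that falls under the 1000-px
  filter, which would (correctly, per the pipeline's definition) break
  exact recovery; exactness is only promised when every stained
  component exceeds the size filter.

What the generator does **not** emulate: staining-intensity gradients,
texture, chromatic aberration, scanner stitching, irregular core shapes,
out-of-focus regions. Passing the recovery tests therefore demonstrates
the correctness of the segmentation arithmetic and hole topology, not
robustness to real-world stain variability.

Default fixture scale is a 420×420 image with a 150-px core (~70 k core
pixels, sub-second per image) with `min_object_area` at 20,000 —
proportional to the printed 1,000,000 at full scan scale, which a
full-scale smoke test exercises once.

The ratings generator draws value(i,j) = µ + sᵢ + rⱼ + eᵢⱼ with
independent zero-mean Gaussians (clamped to [0, 100]); population
ICC(A,1) = σs²/(σs²+σr²+σe²).

## Numerical notes

* Half-up rounding everywhere a real-valued channel meets an integer
  threshold, so threshold semantics are exact.
* ICC degenerate input (all cells equal) raises rather than returning
  0/0; a perfect-agreement table (MSE = MSC = 0) returns ICC = 1 with a
  collapsed CI.
* The ICC point estimate and CI match pingouin's independent ICC(A,1)
  implementation to its printed precision on random tables.

## Known limitations

* With k = 2 raters the rater mean square has a single degree of
  freedom, and the F-based CI for ICC(A,1) is only well calibrated when
  the rater variance share is small. In simulations at population ICC
  0.8 (n = 200, k = 2), coverage is ≈ 0.95 when σr² is ~2% of total
  variance but drops to ≈ 0.86 at 5% and ≈ 0.71 at 10% (the lower bound
  sits too high). This is a property of the standard construction, not
  of this implementation; the calibration check in the test suite
  therefore uses the small-rater-share regime, and results with large
  systematic rater offsets at k = 2 should be read with caution (the
  `compare_all` variance flag helps identify such pairs).
* The cohort-level agreement figures from any particular clinical image
  set depend on that set; this package reproduces the *procedure*, and
  its tests validate it on synthetic ground truth only.
* No whole-slide de-arraying: inputs must already be one cylinder per
  image.
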