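# tmaquant

Automated quantification of the DAB-brown (e.g. cytokeratin-19) positive
area fraction in digital images of tissue-microarray (TMA) cylinders,
together with the agreement statistics used to compare human raters and
automated methods.

## Who this is for

Pathology image-analysis groups who score immunohistochemistry (IHC) on
TMA cores as a *percent positive area* and want a reproducible, scriptable
alternative to visual estimation — plus the statistical machinery (ICC,
Bland-Altman, Kaplan-Meier difference curves) to quantify how well two
observers or methods agree.

## The method

Each input image is one scanned TMA cylinder (8-bit RGB TIFF/PNG,
nominally 0.25 µm/pixel). Two steps:

**1. Cylinder area (the denominator).** The CIE L\* lightness channel
(sRGB/D65 convention, rescaled to 0–255) is median-filtered with a 3×3
window and thresholded on the closed interval [0, 238]; the connected
component larger than 1,000,000 pixels is the cylinder, and its pixel
count is the total area *T*.

**2. Stained area (the numerator).** A "brown channel" is computed per
pixel as

    brown = B − 0.3 · (R + G)

(clamped to [0, 255]; DAB-stained pixels take low values). Pixels in
[0, 70] inside the cylinder are labelled into objects; objects larger than
1000 pixels survive. Two area variants are reported:

* **method A** — the brown pixels only: enclosed unstained regions
  (gland lumina, nuclei) are *excluded*;
* **method B** — each object's enclosed holes are filled before counting,
  so lumina and nuclei *inside* stained objects are included. B ≥ A
  always, and the gap widens with glandular hole content.

The statistic is `percent_X = 100 · area_X / T`.

**Agreement statistics.** For ratings tables (images × raters/methods):
single-rating absolute-agreement ICC(A,1) from the two-way random-effects
ANOVA, with the McGraw–Wong F-based 95% CI and the interpretation scale
poor (< 0.40) / acceptable (0.40–0.74) / excellent (0.75–1);
Bland-Altman means/differences with ±1.96 SD limits of agreement; and
Kaplan-Meier curves of paired differences (no censoring, so the curve is
the empirical survival function of |difference|).

A seeded synthetic-scene generator produces cylinder images with
pixel-exact ground truth (core, stained regions, enclosed holes, optional
Gaussian noise), so the whole pipeline is testable without patient data.

## Worked example

Simulate a high-positivity glandular core, quantify it, and compare the
result with the generator's ground truth:

```sh
$ tmaquant simulate --preset glandular --seed 42 --out sim
wrote synthetic fixture 'glandular' (seed 42) -> sim

$ cat sim/glandular_42_truth.csv
cylinder_px,stain_px_A,stain_px_B,true_percent_A,true_percent_B
70688,40041,42440,56.6447,60.0385

$ printf 'min_object_area = 20000\n' > cfg.toml   # desk-scale core
$ tmaquant quantify --input sim/glandular_42.tif --config cfg.toml --out results.csv
quantified 1 image(s), 0 failure(s) -> results.csv

$ cat results.csv
image_id,total_area_px,area_A_px,area_B_px,percent_A,percent_B,n_objects,error,warnings
glandular_42,70688,40041,42440,56.6447,60.0385,1,,
```

The cylinder contains 70,688 pixels; 40,041 are brown (method A,
56.64 %), and filling the three gland holes adds 2,399 pixels
(method B, 60.04 %) — matching the ground truth pixel-for-pixel. The
3.4-point A/B gap is the hole content of the stained area.

Agreement analysis of a ratings CSV (one row per image, one column per
rater/method):

```sh
tmaquant compare --ratings ratings.csv --out report/
```

writes `agreement_summary.csv`, `agreement_report.json` and Bland-Altman /
KM plots. The same functionality is available as a library
(`tmaquant.quantify_image`, `tmaquant.compare_all`, ...).

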