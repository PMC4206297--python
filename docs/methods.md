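# Methods

`irifcyto` quantifies, per nucleus and per pixel, how a nuclear repair
protein's fluorescence signal redistributes after ionizing radiation, and
decides between two generative explanations for the appearance of
radiation-induced foci (IRIF): *recruitment* (protein relocates from the
nucleoplasm into foci, total nuclear signal conserved) and
*degradation-with-protection* (the diffuse nucleoplasmic pool is degraded
while focus-bound protein is protected at its pre-irradiation level).
Because no raw image data are available for the original experiments, the
package ships a synthetic-field generator with full ground truth, and every
claim the test suite makes is a property of the pipeline measured against
that truth.

## Generative models

A field is a pair of 12-bit grids (DAPI, target protein).  Nuclei are
non-overlapping random ellipses (semi-axes drawn from `nucleus_radius`,
uniform orientation), placed by rejection sampling with bounding-circle
overlap tests and a retry cap (`CrowdedFieldError` on failure).  Optional
nucleoli are dark disks inside nuclei; foci are disks placed inside the
nucleus, disjoint from nucleoli and from each other by at least one pixel.
With diffuse level `d` (`diffuse_mean`), nucleus signal area `A` (nucleus
minus nucleoli) and focus area `A_f`, the expected target signal is:

| model          | nucleoplasm       | focus pixels                      |
|----------------|-------------------|-----------------------------------|
| unirradiated   | `d`               | — (no foci)                       |
| degradation    | `s·d`             | `d` (protected)                   |
| recruitment    | `(1−r)·d`         | `(1−r)·d + r·d·A/A_f`             |

The recruitment construction conserves the integrated signal `d·A` exactly
on the noise-free expectation grid; the degradation model scales the
nucleoplasm by the survival fraction `s ∈ [0,1]`.  The camera model is
`clip(round(Poisson(signal + background) + N(0, read_noise_sd)), 0, 4095)`.
"Intensities of 0 to 4096" in the plotting convention is interpreted as a
12-bit camera (0..4095); histogram bins are unit width, 4096 bins.

Defaults (chosen once as plausible for a 60x widefield acquisition of a
53BP1-like stain): `diffuse_mean=1000`, `dapi_mean=3000`, `background=50`,
`read_noise_sd=5`, nucleus semi-axes 14–20 px, 5–12 foci of radius
1.5–2.5 px per irradiated nucleus, nucleoli off by default (they are an
optional feature of the unirradiated phenotype; when enabled they darken the
target channel and lower the whole-nucleus reference mean accordingly).
`(config, seed)` fully determines both channels and the ground truth.

The generator deliberately omits PSF blur, chromatin texture, illumination
gradients and cell-cycle heterogeneity.  Hard-edged uniform disks keep every
oracle exact (pixel sets, integrated signal, expected means).  Passing tests
therefore demonstrate the correctness of the measurement pipeline under the
stated noise model, not robustness to optical artifacts of real microscopes.

One scenario needs a modelling note: "irradiation, then proteasome block
while synthesis continues" presents bright foci over a nucleoplasm restored
to the reference level.  The degradation model cannot express it (at `s=1`
focus contrast vanishes), but its signature — conserved total signal with a
small fraction concentrated in foci — is exactly the recruitment model at
small `r`, so that configuration (`r=0.1`) stands in for the
proteasome-block condition in tests.

## Segmentation and masking

Default DAPI pipeline: Otsu threshold → fill holes → distance-transform
watershed (markers from `peak_local_max`, minimum separation
`split_min_distance=15` px) → area filter (`min_area=200`,
`max_area=10000` px) → border exclusion.  Every step is switchable via
`SegmentationParams`.  A constant image yields an empty mask, not an error.
Nucleus sampling (`sample_nuclei`) is uniform without replacement and
seeded, mirroring the protocol of randomly selecting 80–100 cells per
sample.  `mask_target` returns disjoint per-nucleus intensity multisets
whose union is exactly the masked area.

## Pixel-histogram cytometry

Histograms pool all pixels of all sampled nuclei of a condition
(per-nucleus histograms remain available by passing single collections).
Comparisons are computed from the histograms alone: medians and quantiles as
lower empirical quantiles on the integer grid, the two-sample
Kolmogorov–Smirnov distance as `sup |CDF_A − CDF_B|`, the share of
irradiated pixels strictly above the unirradiated `q`-quantile (default
`q=0.99`), and the share below the baseline median.

## Focus detection and intensity records

Per nucleus, pixels outside the mask are filled with the in-nucleus median,
a white top-hat with a structuring disk of radius 5 (about twice the
expected focus radius) removes the smooth background, and a pixel is a focus
candidate when its response exceeds `k` times the robust noise scale of the
nucleoplasm (`k=5`).  The noise scale is `1.4826 × MAD` of the raw
in-nucleus intensities computed from downward deviations only, because foci
contaminate the bright tail.  Candidates are regularized by hole filling,
then refined at the 1-px boundary: rim pixels join a focus when nearer the
focus level than the nucleoplasm level, and detected pixels return to the
nucleoplasm when nearer the nucleoplasm level *and* more than 3 robust sd
from the focus level.  Every step is an exact no-op on noise-free input, so
simulated focus pixel sets are recovered exactly there; the refinement
exists because at low contrast (survival fraction near 1) per-pixel shot
noise otherwise misassigns a small but systematic number of boundary pixels.
Regions below `min_focus_area=4` px are discarded; zero foci is a valid
result.  Detection is invariant to adding a constant offset to the nucleus.

`mean_foci` pools all focus pixels of a nucleus (area-weighted), rather than
averaging per-focus means; `mean_nucleoplasm` excludes focus pixels; the
exact decomposition `mean_all = (A_f·mean_foci + A_n·mean_nucleoplasm)/A`
holds for every record.  The normalized foci intensity divides `mean_foci`
by a reference diffuse mean, computed as the mean of whole-nucleus means
over the unirradiated cohort (per-nucleus-then-averaged; pooled-pixel
averaging is the alternative and differs only through nucleus-size
weighting).  Under degradation-with-protection this statistic sits at 1;
under recruitment it exceeds 1 by the concentration factor
`(1−r) + r·A/A_f` (up to the 12-bit ceiling).

The survival-fraction estimator subtracts the camera background (median of
extranuclear pixels) from both numerator and denominator:
`ŝ = (mean_nucleoplasm − b̂)/(reference − b̂)`.  The raw ratio
`mean_nucleoplasm/reference` is reported too (the phenotype classifier uses
it), but it is biased upward by the additive background, most visibly at
small `s`.

## Phenotype classification

With `ρ = mean_nucleoplasm/reference` and focus count `F`
(thresholds `F_min=5`, `ρ_lo=0.3`, `ρ_hi=0.7`, all configurable):

* `F < F_min` → **diffuse** (nuclei without a focus pattern can only be
  diffuse, whatever ρ);
* `F ≥ F_min`, `ρ < ρ_lo` → **foci**;
* `F ≥ F_min`, `ρ ≥ ρ_hi` → **diffuse_with_foci**;
* intermediate ρ → the nearer boundary, ties to **diffuse_with_foci**.

The rule is deterministic and monotone in ρ.  The thresholds replace a
visual scoring step that had no published criteria; tests sweep them to show
the simulated conditions are classified stably.  Per-condition fractions are
percentages per replicate (summing to 100 exactly) with SEM across
replicates (`sd/√N`, NaN for a single replicate).

## Model discrimination

For a NoIR/IR histogram pair the rule reports median shift, the fraction of
IR pixels above the NoIR `q=0.99` quantile, and the integrated-intensity
ratio (per-pixel mean IR / mean NoIR), then decides with tolerance
`τ=0.25`:

* **recruitment** if the above-baseline fraction exceeds `(1−q)(1+τ)` and
  the integrated ratio lies in `[1−τ, 1+τ]`;
* **degradation** if the median shift is more negative than a noise floor
  (3 × pooled bootstrap SE of the two medians, 200 seeded multinomial
  resamples) and the above-baseline fraction does not exceed `(1−q)(1+τ)`;
* **indeterminate** otherwise (identical inputs land here).

The margin is a unitless confidence score: for degradation the relative
median drop `|shift|/median_NoIR` (grows as `s` shrinks); for recruitment
the mean IR pixel excess above the baseline quantile divided by the baseline
mean (grows with `r`, and keeps growing even when the brightest foci
saturate the 12-bit range, which a top-quantile ratio would not).

`ttest_two_groups` is the classic unpaired two-tailed t test (pooled
variance by default, Welch via `equal_var=False`), implemented in closed
form with the t distribution from scipy; stars are `*`, `**`, `***` for
p < 0.05, 0.01, 0.001.  Zero pooled variance with equal means returns p = 1.

## Reporter-assay arithmetic

`ddct_efficiency` is the unmodified comparative-CT method:
`ΔΔCT = (CT_target − CT_ref)_sample − (CT_target − CT_ref)_control`,
relative efficiency `2^−ΔΔCT` (control ≡ 1).  Technical-replicate CT values
are averaged before ΔΔCT; SEM is propagated across biological replicates
only.  `gfp_relative` divides the sample GFP-positive fraction by the
control fraction and is scale-invariant.

## Problem sizes and numerical choices

Cohort-level checks use 100 nuclei per condition (four 1024×1024 fields of
25 nuclei); discrimination sweeps use 200 labelled simulations per model
(10-nucleus 512×512 fields over the grid `s ∈ {0.1, 0.2, 0.4}`,
`r ∈ {0.2, 0.3, 0.5}`).  These sizes give standard errors small enough for
the 3-SE parameter-recovery assertions while keeping a full run on one CPU
in a few minutes.  Ties in quantiles resolve to the smallest intensity whose
CDF reaches the target; medians are integers on the intensity grid.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; reruns are byte-identical.

## Known limitations

* No PSF/optics model: detection thresholds tuned for hard-edged disks will
  be conservative on diffraction-blurred spots.
* The 12-bit ceiling clips very bright recruitment foci
  (`r·d·A/A_f` large); conservation then holds on the expectation grid but
  not on the quantized image — exactly as a saturated camera would behave.
* The discrimination rule assumes a stable acquisition between conditions
  (same exposure), as the integrated-intensity ratio is not illumination-
  corrected.
* Phenotype thresholds are operational definitions, not biological
  constants; conclusions should be checked under threshold sweeps (the test
  suite does this for well-separated conditions).
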