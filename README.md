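# irifcyto

Per-cell image cytometry of ionizing-radiation-induced foci (IRIF) in
fluorescence microscopy, built for the question: when a DNA-repair protein
such as 53BP1 appears as bright nuclear foci after irradiation, did the
protein **move** from the nucleoplasm into the foci, or was the diffuse pool
**degraded** while focus-bound protein was protected?

The two hypotheses leave different fingerprints in the per-pixel intensity
distribution of the nuclear stain.  Under recruitment, total nuclear signal
is conserved and a small share of pixels rises *above* the unirradiated
baseline.  Under degradation-with-protection, most pixels lose intensity
(the distribution's median shifts down) and essentially no pixel exceeds the
baseline's upper quantile, while the mean focus intensity stays at the
pre-irradiation diffuse level (normalized foci intensity ≈ 1).

The package provides:

* **`irifcyto.simulate`** — a two-channel (DAPI + target) synthetic field
  generator with full ground truth under three generative models:
  `unirradiated`, `recruitment` (fraction *r* of nuclear signal relocated
  into foci, total conserved) and `degradation` (nucleoplasm scaled by a
  survival fraction *s*, focus pixels protected), with Poisson shot noise,
  Gaussian read noise and a 12-bit camera.
* **`irifcyto.segmentation`** — DAPI nuclear segmentation (Otsu, hole
  filling, watershed splitting, area/border filters), seeded random
  sampling of nuclei, and masking of the target channel into per-nucleus
  pixel collections.
* **`irifcyto.histogram`** — pooled per-pixel intensity histograms (4096
  unit bins), windowing, and distribution comparison (median shift, KS
  distance, above-baseline tail fractions).
* **`irifcyto.foci`** — white top-hat focus detection with a robust
  nucleoplasm-noise threshold, per-nucleus intensity records, and the
  normalized foci intensity `mean_foci / reference_diffuse_mean`.
* **`irifcyto.phenotype`** — per-nucleus classification into
  diffuse / foci / diffuse-with-foci and per-condition percentages
  (mean ± SEM across replicates).
* **`irifcyto.discriminate`** — the recruitment-vs-degradation verdict from
  a NoIR/IR histogram pair, plus the unpaired two-tailed t test with
  `*`/`**`/`***` annotations.
* **`irifcyto.repair`** — comparative-CT (2^−ΔΔCT) repair efficiency and
  relative GFP-positive fractions for reporter assays.
* **`irifcyto` CLI** — `simulate`, `segment`, `histogram`, `foci`,
  `classify`, `discriminate`, `repair` and `run` (end-to-end pipeline from a
  YAML config, writing CSV/JSON plus a full manifest; byte-identical reruns
  under fixed seeds).

See `docs/methods.md` for the models, estimators, decision rules and their
assumptions.

## Worked example

```python
import irifcyto as ic

base = ic.SimulationConfig(model="unirradiated", n_nuclei=10, seed=11)

def analyze(cfg):
    fov, truth = ic.simulate_field(cfg)
    mask = ic.segment_nuclei(fov.dapi)
    hist = ic.pixel_histogram(ic.mask_target(fov.target, mask))
    records = ic.analyze_nuclei(fov.target, mask)
    return hist, records

hist_noir, rec_noir = analyze(base)
hist_ir, rec_ir = analyze(base.with_(model="degradation",
                                     survival_fraction=0.2, seed=12))

reference = ic.reference_diffuse_mean(rec_noir)
nfi, sem = ic.summarize_normalized(ic.normalized_foci_intensity(rec_ir, reference))
res = ic.discriminate_model(hist_noir, hist_ir, seed=1)
print(f"reference diffuse mean: {reference:.1f}")
print(f"normalized foci intensity: {nfi:.3f} +/- {sem:.3f}")
print(f"median shift: {res.median_shift}, verdict: {res.verdict}")
```

Output:

```
reference diffuse mean: 1049.8
normalized foci intensity: 1.002 +/- 0.001
median shift: -797, verdict: degradation
```

Read: the unirradiated diffuse level is ~1050 gray values (1000 signal +
50 background).  After irradiation under the degradation model with s = 0.2,
focus pixels still average the pre-irradiation diffuse level (normalized
foci intensity ≈ 1 — foci are not *brighter*, the surroundings got dimmer),
the pixel-distribution median drops by ~800 gray values, and the verdict
correctly identifies degradation.  A recruitment simulation instead yields a
conserved integrated intensity, an elevated fraction of pixels above the
unirradiated 99th percentile, and the verdict `recruitment`.

The same pipeline runs from the shell:

```sh
irifcyto run --config pipeline.yaml --seed 1 --out results/
```

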