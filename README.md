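# ctdetect

Statistical machinery for quantifying how cfDNA recovery "priming" affects
circulating-tumor-DNA detection from SNV fingerprint panels:

* **Data model & IO** (`ctdetect.data`) — fingerprint panels (BED-like TSV),
  per-sample/per-site duplex count tables (`t` total, `n` mutant molecules),
  sample metadata, and sensitivity grids; all plain TSV with lossless
  round-trips.
* **Synthetic cohorts** (`ctdetect.simulate`) — Poisson-lognormal depth law
  with `n_ij ~ Binomial(t_ij, f_i)` mutant counts, matched control/primed
  arms, configurable priming fold and tumor-fraction shift.
* **Detection statistics** (`ctdetect.detection`) — SNV-count classifier
  (positive iff #sites with ≥ 1 mutant duplex ≥ threshold), group
  sensitivity, burden stratification (flux cutoffs 1.5e7 / 1.5e8
  photons/s), the binomial tumor-fraction MLE `Σn/Σt`, relative duplex
  depth z-scores, and an **exact Poisson-binomial detection-probability
  oracle** (dynamic-programming convolution over sites).
* **Resampling** (`ctdetect.resampling`) — bootstrap panel-size
  downsampling (sites drawn with replacement, one draw per replicate shared
  across samples), binomial tumor-fraction down-scaling holding observed
  depths fixed, and a parametric-bootstrap goodness-of-fit check of the
  binomial count model. Each grid cell reports the mean and SE (SD of
  replicate sensitivities) over replicates (default 100).
* **Scenario runner** (`ctdetect.runner`) — simulate → detect → resample →
  summarize, with a JSON manifest (config, seed, versions, per-stage wall
  times, sha256 of every output) and optional plots.

## CLI

```sh
ctdetect simulate scenario.yaml --outdir cohort/ --seed 1
ctdetect detect cohort/counts.tsv --panel cohort/panel.tsv --threshold 2 --out detections.tsv
ctdetect sensitivity cohort/counts.tsv cohort/metadata.tsv --out sens.tsv
ctdetect oracle --depths 40,10,25 -f 0.01 --threshold 2
ctdetect downsample-panel cohort/counts.tsv cohort/metadata.tsv --plan plan.yaml --out grid.tsv
ctdetect downscale-fraction cohort/counts.tsv cohort/metadata.tsv --plan plan.yaml --out grid.tsv
ctdetect model-check cohort/counts.tsv --out check.tsv
ctdetect run run.yaml --outdir out/        # full pipeline from one YAML
```

`run.yaml` combines both configs:

```yaml
scenario:
  panel_size: 1822
  n_samples_per_arm: 8
  true_fraction_grid: [1.0e-3]
  mean_depth: 1000
  depth_dispersion: 0.5
  priming_fold: 19.0
  fraction_shift: 1.0
  seed: 1
resampling:
  panel_sizes: [10, 100, 1822]
  thresholds: [2, 3, 4, 5, 6, 7, 8, 9, 10]
  fractions: [1.0e-6, 1.0e-5, 1.0e-4]
  n_replicates: 100
  seed: 1
```

## Conventions

* Panel files are 0-based half-open BED-like TSV; `site_id` is the join key.
* Missing (sample, site) pairs are treated as `t=0, n=0` dropouts with a
  logged warning.
* "Positive" uses the weak inequality: detected SNVs ≥ threshold.
* Relative duplex depth uses the population (n-denominator) SD.
* All randomness flows from explicit integer seeds; fixed seeds give
  bit-identical outputs.
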