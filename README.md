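# sproutspec

NIR aquaphotomics chemometrics toolkit for sprouting-quality analysis:

- **spectra_core** (`sproutspec.spectra`) — wide-CSV spectral data model
  (samples × wavelengths with per-sample metadata), wavelength-window
  truncation, scan/replicate aggregation.
- **preprocess** — Savitzky–Golay smoothing (polynomial edge handling,
  exact on polynomials up to the fitted order) and standard normal
  variate (sample-sd convention), chained as truncate → SG → SNV.
- **chemometrics** — PCA by SVD on mean-centred data, canonical LDA on
  leading PC scores with nearest-centroid classification and
  replicate-3-fold / grouped k-fold cross-validation (per-fold refits,
  no leakage), PLS1 via NIPALS with RMSECV-driven latent-variable
  selection (smallest count within 2 % of the minimum RMSECV), and
  loading-based important-wavelength extraction.
- **aquaphotomics** — the 12 first-overtone water matrix coordinates
  (C1–C12, configurable display wavelengths) and aquagram computation
  (per-band z-scores across samples, averaged per group).
- **wetlab** (`sproutspec.wetlab`) — gravimetric water content,
  iodometric standardization chain (iodate → thiosulfate → iodine),
  ascorbic acid mass via the 88.065 mg/meq equivalent weight
  (176.13 / 2), and mg ↔ mg/100 g ↔ mg/L unit conversions.
- **stats_univariate** (`sproutspec.stats`) — one-way ANOVA from
  (mean, sd, n) summaries, Duncan's multiple range test with compact
  letter display (studentized-range quantiles at the Duncan protection
  level, no lookup tables), Durbin–Watson.
- **synthetic_data** (`sproutspec.simulate`) — seeded generators for
  extract spectra (21 germination-time classes × 3 replicates × 5
  scans; Gaussian water bands drifting with time, Beer–Lambert analyte
  bands anchored to the published titration trajectory, multiplicative
  scatter + baseline + iid noise), six-level standard-solution spectra,
  and raw quality triplicates around the published summary anchors
  (`sproutspec.reference`).
- **pipeline_cli** (`sproutspec.pipeline`, `sproutspec.cli`) — one-config
  orchestration and a `sproutspec` command-line tool.

## CLI

```sh
sproutspec simulate --kind extract --seed 1 --out spectra.csv --truth-out truth.csv
sproutspec preprocess spectra.csv --out proc.csv --window 1300 1600
sproutspec classify --seed 1 --out runs/classify
sproutspec predict --target water_pct --seed 1 --out runs/water
sproutspec aquagram --seed 1 --out runs/aquagram
sproutspec titration volumes.csv --normality 0.01 --out titres.csv
sproutspec stats summary.csv --out letters.csv      # label,mean,sd,n columns
sproutspec full-run --seed 1 --out runs/full        # consolidated bundle
```

Exit codes: 0 success, 2 configuration error, 3 data error. Each run
directory contains `metrics.csv`, fitted-model JSON where applicable,
and a `run.log` recording seed, config hash and the preprocessing chain.

## Conventions worth knowing

- SNV divides by the sample (n−1) standard deviation.
- SG edge points are evaluated from the one-sided local polynomial fit,
  so polynomials up to the fitted order are reproduced exactly
  everywhere; non-uniform grids are filtered in index space.
- PCA is not column-autoscaled (SNV already row-normalizes).
- Grouped k-fold CV deals whole germination-time points into folds
  round-robin after a seeded shuffle; replicate 3-fold CV holds out one
  replicate per fold.
- Simulator band centres, widths, amplitudes and slopes are tuning
  constants of the generator, not measured facts.
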