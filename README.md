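# tropref

Age-, sex- and renal-function-stratified upper-reference-limit analysis for
a highly sensitive cardiac troponin assay, packaged as a reusable, tested
pipeline. Because the underlying individual-level cohort data are not
publicly available, the package ships a calibrated synthetic cohort
generator with analytically known stratum quantiles, so every stage of the
analysis is verifiable at desk scale.

## What it does

1. **Synthetic cohort generation** (`tropref.synthetic`) — draws subjects
   with age-, sex- and renal-function-dependent troponin, creatinine,
   NT-proBNP and HbA1c values. Troponin is log-normal given age and sex,
   with knots solved so that every stratum-level median and 99th percentile
   of the mixture matches the published calibration targets exactly.
   `true_stratum_quantile` inverts the analytic mixture CDF (to 1e-6 ng/L),
   providing exact ground truth for recovery tests.
2. **Exclusion cascade** (`tropref.filtering`) — cardiac disease →
   age-dependent NT-proBNP / HbA1c limits → eGFR cutoff, producing study
   cohort 2 (cardiac-healthy) and cohort 1 (additionally preserved renal
   function) with a per-stage audit report.
3. **eGFR** (`tropref.renal`) — 2009 CKD-EPI from creatinine (µmol/L), age
   and sex; race coefficient off by default.
4. **Quantile engine** (`tropref.quantiles`) — detection-floor transform
   (values < 3 ng/L set to 3), linear-interpolation percentiles, and exact
   distribution-free order-statistic confidence intervals (minimal-width
   binomial construction, no interpolation).
5. **Stratified reference tables** (`tropref.reference`) — per-sex
   median/P99 tables over age, creatinine and eGFR bins, with the
   ≥300-subjects rule for the creatinine/eGFR tables.
6. **Floating curves and surface** (`tropref.curves`) — sliding-window
   median/percentile curves (age ±5 y, creatinine ±15 µmol/L, eGFR
   ±10 mL/min/1.73 m²), the 97–99.4 percentile band (±10 y), and the 2-D
   floating-P99 surface over (age, creatinine).
7. **Associations** (`tropref.association`) — Spearman correlations
   (mid-ranks, t-approximation) and the Mann–Whitney sex-difference test.

## CLI

```sh
tropref simulate --n 9882 --seed 1 --out cohort.csv
tropref filter --in cohort.csv --out-cohort1 c1.csv --out-cohort2 c2.csv --report report.json
tropref egfr --in c1.csv --out c1_egfr.csv
tropref reference-table --in c1.csv --scheme age --out table_age.csv
tropref curves --in c1.csv --axis age --stat p99 --out curves.csv
tropref surface --in c2.csv --out surface.csv
tropref correlate --in c1.csv --x age --out corr.json
tropref run --outdir out --seed 1          # full pipeline, all outputs
```

`tropref run` accepts `--config cfg.yaml`; with no config, the defaults
reproduce the reference procedure on synthetic data. All CSVs are UTF-8,
comma-separated, "." decimals, with a mandatory header; every pipeline
output is stamped with a hash of the resolved configuration (as a leading
`# config=...` comment line in CSVs).

## Layout

```
src/tropref/        synthetic, filtering, renal, quantiles, reference,
                    curves, association, pipeline, cli, io, errors
tests/              unit + property tests, test_acceptance.py
scripts/acceptance.py
```
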