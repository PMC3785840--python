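# osteorisk

Kernel-density Bayes modelling of late osteolysis risk after cemented total
hip arthroplasty, built as a fully reproducible pipeline:

- **`osteorisk.cohort`** — synthetic subject cohorts calibrated to published
  group-level statistics (283 control / 180 osteolysis subjects; log-normal
  total wear, moment-matched truncated normals for age, height, BMI and
  implant survival time; exact sex counts).
- **`osteorisk.kde`** — fixed-bandwidth multivariate KDE with the standard
  Gaussian kernel, plus the normal-reference bandwidth rule
  `h = (4/(3n))^(1/5) * sigma` and its MAD-robust variant
  `h = (4/(3n))^(1/5) * MAD / 0.6745`.
- **`osteorisk.classifier`** — the kernel Bayes classifier: log transform of
  wear rate, pooled z-score standardization, frequency (or fixed) priors, one
  class-conditional KDE per outcome, Bayes posteriors, MAP decisions, and
  posterior curves/surfaces with companion training-density grids.
- **`osteorisk.evaluation`** — stratified 5-fold cross-validation, repeated
  random permutations, sex-stratified subgroup analyses, and the bandwidth
  sensitivity sweep (default grid h = 0.1 … 10.0, step 0.1).
- **`osteorisk.pipeline`** / **`osteorisk.cli`** — config-driven end-to-end
  runs writing CSV/JSON artifacts plus a manifest with per-artifact SHA-256
  checksums; identical configs reproduce every artifact bit-identically.

## CLI

```sh
# generate the default calibrated synthetic cohort
osteorisk simulate --seed 7 --out cohort.csv

# fit the bivariate wear + age model with the headline bandwidth
osteorisk fit --cohort cohort.csv --features annual_wear,age_at_surgery \
    --h 0.7 --out model.json

# posterior for one subject
osteorisk predict --model model.json --wear 0.2 --age 60

# repeated stratified 5-fold cross-validation, sexes separately
osteorisk crossval --cohort cohort.csv --h 0.7 --k 5 \
    --permutations 100 --seed 0 --by-sex --out cv.json

# bandwidth sensitivity sweep
osteorisk sweep --cohort cohort.csv --h-min 0.1 --h-max 10 --h-step 0.1 \
    --permutations 100 --seed 0 --out sweep.csv

# full pipeline from a JSON config (see osteorisk.pipeline.default_run_config)
osteorisk run --config run.json
```

`osteorisk surface` and `osteorisk curve` export the numeric grids behind
posterior surfaces/curves as CSV; plot rendering is intentionally out of
scope.

## Fidelity notes

Variables are drawn independently within each class; within-class
correlations are not published, so cross-validated misclassification rates
on synthetic cohorts approximate rather than reproduce the original ones.
The sex-specific height offset (default 0.05 m) is user-tunable and
preserves each class's overall height mean and s.d.
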