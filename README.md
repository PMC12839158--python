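# faindex

Plasma fatty-acid biomarker analysis as a tested, reusable pipeline:
molar-percent profiles, conventional and composite lipidomic indices
(including the omega-6/3 balance index `(AA * sqrt(EPA*DPA)) / (AdA * DHA)`),
ROC diagnostics with DeLong inference and Youden mid-plateau cut-offs,
Cliff's delta effect sizes, the published two-predictor logit diagnostic
function, LASSO-based model development with optimism-corrected internal
validation, and a synthetic cohort generator calibrated to the published
group distributions so that every stage runs without external data.

## Layout

| module | role |
| --- | --- |
| `faindex.core` | analyte panel (24 analytes, built-in molecular weights), cohort/panel file I/O, concentration → molar-percent conversion with below-LOQ exclusion |
| `faindex.indices` | the ten per-sample indices/ratios (`omega3_status`, `aa_epa`, `omega6_3`, `c18_ratio`, `aa_ada`, `dgla_aa`, `epa_dpa`, `epa_dha`, `dpa_dha`, `o63bi`) |
| `faindex.diagnostics` | DeLong AUC + Wald CI, Youden mid-plateau cut-offs with Wilson CIs, Cliff's delta with consistent-variance CI |
| `faindex.group_stats` | Shapiro–Wilk/Levene test-selection tree (ANOVA / Welch ANOVA / Kruskal–Wallis / Welch t / Mann–Whitney), Tukey and Dunn+Holm post hocs, Holm and Benjamini–Hochberg adjustment, two-group power arithmetic (d = 2f) |
| `faindex.model` | published logit function (intercept 5.254, coefficients −0.145 / −11.544), LASSO logistic development with CV-chosen penalty, discrimination/calibration/classification metrics, Riley feasibility, stratified k-fold CV + optimism bootstrap |
| `faindex.synthetic` | moment-matched group generators (lognormal / truncated-normal marginals, Gaussian copula) on the analyte scale, plus Gaussian index-scale simulation; back-conversion to concentrations |
| `faindex.cli` | `faindex` command-line pipeline and report bundle (table1…table7, model.json, manifest.json) |

## CLI

```sh
faindex simulate --seed 1 --out out/                  # synthetic cohort CSV
faindex indices  --cohort out/cohort.csv --out out/indices.csv
faindex compare  --indices out/indices.csv --out out/comparisons.csv
faindex roc      --indices out/indices.csv --out out/roc.csv
faindex fit      --indices out/indices.csv --seed 1 --out out/model.json
faindex validate --indices out/indices.csv -B 200 -k 10 --seed 1 --out out/validation.json
faindex report   --seed 1 --out out/                  # full bundle in one run
```

`report` accepts `--mode ingest --cohort path.csv` to analyse an existing
cohort file (wide CSV, header `sample_id,group,<analyte...>`, empty cells or
`<LOQ>` marking below-LOQ values) and `--config config.yaml` to override
markers, group moments, model candidates, and validation settings.

## Notes

* Classification with the logit score calls a sample diseased when
  `logit_score >= cutoff`; disease scores are higher under the published
  coefficients, which is the only direction consistent with the reported
  sensitivity 0.840 / specificity 0.729.
* The printed confusion matrix (TN=35, FP=13, FN=8, TP=42) yields
  MCC ≈ 0.573; the source text prints 0.62. The standard formula is used
  here; the discrepancy is surfaced, not tuned away.
* Group labels are free strings; `Control` / `Atorvastatin` /
  `Rosuvastatin` / `NoStatin` are defaults of the simulation config, not
  hard-coded behaviour.
* Indices are always computed per sample and averaged afterwards; the mean
  of a ratio is not the ratio of means.
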