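# deconvkit

Bulk-transcriptome deconvolution of heterogeneous tissue, end to end:

- **synthetic** — labeled single-cell references, pseudo-bulk mixtures with known
  Dirichlet proportions, and case/control cohorts with planted subtype structure,
  pathway activations and clinical covariates.
- **signature** — per-gene marker statistics (logFC, logCPM, SecondFC, expressed
  fraction), marker selection, signature-matrix construction, and automatic SecondFC
  threshold choice from the between-type correlation plateau.
- **solvers** — proportion estimation from `bulk ≈ C·p` by OLS, NNLS, robust (Huber)
  regression, linear ν-SVR, or damped weighted least squares; outputs live on the simplex.
- **benchmark** — PCC between estimated and true proportions, reconstruction PCCs on the
  fraction-restricted vs. full signature, marker-fraction scans, and average-rank method
  stability.
- **imputation** — per-sample cell-type expression recovery from bulk + proportions
  (cohort-level non-negative regression plus residual allocation), with marker-enrichment
  validation heatmaps.
- **pathway** — rank-based per-sample gene-set activity (area under the recovery curve in
  the top-ranked fraction) and two-group comparisons.
- **stats** — group-wise proportion tests, differential-expression filtering, a linear-SVM
  classification stage with cross-validated cost selection, and clinical-feature
  association (ANOVA / chi-square) for clusterings.
- **subtyping** — highly-variable-gene selection, integrated multi-cell-type profiles,
  NMF consensus clustering with cophenetic-coefficient rank selection.
- **pipeline / cli** — a single declarative config that runs the whole chain on a
  synthetic cohort and writes every stage's outputs with provenance.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion.
`TestCriterion7SubtypeRecovery::test_choose_k_returns_4` is a known red: on synthetic
planted cohorts the consensus cophenetic curve does not drop sharply right above the
planted cluster count whenever the planted-k consensus is crisp, so the k-selection rule
overshoots (see the module docstrings; every other criterion passes).

## CLI

```sh
deconvkit synth reference --n-cell-types 5 --n-genes 1200 --seed 1 --out ref/
deconvkit synth cohort --ref-dir ref/ --n-samples-per-group 40 --seed 2 --out cohort/
deconvkit signature build --ref-dir ref/ --secondfc auto --out sig.tsv
deconvkit deconv run --signature sig.tsv --bulk cohort/bulk.tsv --method nnls --out props.tsv
deconvkit bench scan --signature sig.tsv --bulk cohort/bulk.tsv \
    --truth cohort/true_proportions.tsv --methods nnls,ols --out records.tsv
deconvkit impute run --bulk cohort/bulk.tsv --props props.tsv --out-dir cube/
deconvkit pathway score --expr cohort/bulk.tsv --gmt sets.gmt --out scores.tsv
deconvkit classify --expr cohort/bulk.tsv --labels cohort/groups.tsv --seed 1 --out svm.tsv
deconvkit subtype --expr profile.tsv --k-range 2:6 --seed 1 --out-dir subtypes/
deconvkit run --out-dir run/            # full synthetic end-to-end pipeline
```

Formats: TSV matrices (first column = row id, header = column ids), MTX + TSV sidecars for
single-cell references, GMT gene sets.

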