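# pniexpr

Expression-profiling pipeline for perineural invasion (PNI) risk in head
and neck cutaneous squamous cell carcinoma (HNcSCC), built for
nCounter-style probe-count data.

Clinically significant (extensive) PNI drives recurrence and treatment
failure in HNcSCC, but telling it apart from incidental focal PNI on
histology is hard. One line of attack profiles tumor expression on a
targeted codeset (endogenous genes + housekeeping genes + spike-in
controls), asks which genes separate extensive-PNI tumors from
focal/non-PNI tumors, and compresses the answer into a small gene panel
usable as a risk score. `pniexpr` implements that entire analysis as a
reusable, tested library and CLI:

* **Simulation** — a synthetic-cohort generator (9 Non / 11 Focal /
  25 EXT samples on a 740 + 30 gene codeset) with planted effects, lane
  factors and ground truth, so the whole pipeline is testable without
  any external data.
* **Normalization** — background correction from negative controls,
  positive-control normalization, housekeeping (codeset-content)
  normalization, with per-sample factor QC.
* **Differential expression** — per-gene two-group fits with
  empirical-Bayes variance moderation: the moderated t-statistic
  `t̃_g = Δ_g / (s̃_g √(1/n₁+1/n₂))` with posterior variance
  `s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)`, hyperparameters (d₀, s₀²) by
  method of moments on log s², and Benjamini–Hochberg FDR control.
* **Clustering** — gene-standardized Euclidean hierarchical clustering
  of samples with cohort-segregation scoring.
* **Panel scoring** — the 10-gene risk score: per-gene thresholds at the
  95th centile (type-7) of the Non+Focal training samples; a sample
  scores 1 per gene strictly above threshold; totals > 2.5 are called
  EXT-risk; evaluated by sensitivity/specificity and a tie-corrected
  ROC/AUC.
* **Enrichment** — hypergeometric over-representation P(X ≥ k) of DEG
  lists against GMT gene sets within the codeset universe.
* **Cohort statistics** — chi-square / Student-t comparisons of the
  clinical covariate table.

Formats: counts TSV, annotation CSV, minimal NanoString RCC lanes, GMT.

## Worked example

```python
from pniexpr.evaluate import run_cohort_analysis
from pniexpr.simulate import GeneratorConfig

print(run_cohort_analysis(GeneratorConfig(seed=1)))
```

```
{'n_samples': 45, 'n_deg_fc2': 144, 'n_deg_fc3': 71,
 'n_focal_vs_non_significant': 0, 'sensitivity': 1.0, 'specificity': 0.9,
 'tp': 25, 'fn': 0, 'tn': 18, 'fp': 2, 'auc': 1.0}
```

Reading the numbers: on this simulated cohort the EXT-vs-Focal/Non
contrast finds 144 genes past the 2-fold filter and 71 past the 3-fold
filter at adjusted p < 0.01 (the generator plants 70 strong + 74
moderate effects, so both tiers are recovered with one borderline
extra); the Focal-vs-Non contrast finds nothing, as designed; and the
10-gene score at cutoff 2.5 calls all 25 EXT samples (sensitivity 1.0)
with 2 of 20 control samples false-positive (specificity 0.90), AUC 1.0.

The same analysis from the shell:

```sh
pniexpr run-all --seed 1 --outdir out/
# stage artifacts: counts.tsv, normalized.tsv, deg_*.tsv, panel.tsv,
# scores.tsv, roc.tsv, panel_metrics.json, manifest.json, ...
pniexpr enrich out/deg_EXT_vs_FOCAL_NON.tsv --gmt examples/pathways_synthetic.gmt \
    --universe out/normalized.tsv --out enrichment.tsv
```

`examples/pathways_synthetic.gmt` is a synthetic gene-set fixture over
the generator's gene identifiers.

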