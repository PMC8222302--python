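# Methods

`pniexpr` re-implements, as a tested pipeline, the analysis used to profile
perineural invasion (PNI) in head and neck cutaneous squamous cell
carcinoma from nCounter-style probe counts: control-probe normalization,
moderated-t differential expression, hierarchical clustering, a
percentile-threshold gene-panel risk score, and hypergeometric pathway
over-representation. Because the original expression data are not
publicly deposited, the package ships a synthetic-cohort generator whose
defaults emulate the study design; every downstream claim the test suite
makes is a claim about that generative model, not about the original
tumors.

## Synthetic cohort model

A cohort has three groups — Non-PNI (n = 9), Focal-PNI (n = 11), EXT-PNI
(n = 25) — measured on a codeset of 740 endogenous genes, 30 housekeeping
genes, 6 positive and 8 negative control probes. For endogenous gene *g*
and sample *s*:

    count[g, s] ~ NB(mean = b_g · 2^(β_g · I[s ∈ EXT]) · L_s, dispersion φ) + Poisson(λ)

* **Baselines** `b_g = 2^x`, `x ~ N(7, 1.5²)` (log2 scale). Housekeeping
  baselines sit one log2 unit higher with half the spread: codeset
  housekeeping genes are chosen for robust expression, and baselines near
  the background floor would make strict (pseudocount-free) geometric
  means undefined after background correction.
* **Planted effects** `β_g`: 70 genes at |log2FC| = 2.0 and 74 at
  |log2FC| = 1.3, applied to EXT samples only, with 6% of planted genes
  down-regulated. The two tiers are chosen so the >3-fold filter captures
  the strong tier (70 genes) and the >2-fold filter both tiers
  (144 genes). Focal and Non samples are exchangeable by construction.
* **Lane factors** `L_s = exp(N(0, 0.3²))` model per-sample
  hybridization/loading scale; normalization exists to remove them.
* **Dispersion** φ = 0.05 for endogenous genes (tumor-to-tumor biological
  plus technical variation). Housekeeping probes use φ = 0.005: the
  premise of codeset-content normalization is that reference genes are
  biologically stable, so their residual variation is technical. With
  biological-scale dispersion on 30 housekeeping genes, the lane factor
  would be estimable to at best r ≈ 0.99 in principle and ≈ 0.9896 in
  practice — the generator would contradict the structure the
  normalization assumes.
* **Controls**: positive probes follow the nCounter 6-step ERCC ladder
  (128…0.125 fM, 25 counts/fM at lane factor 1), Poisson-distributed and
  lane-scaled; negative probes are Poisson(λ) only, with λ = 10 the
  shared background mean.
* **Nerve fraction** is Uniform(0.005, 0.80), independent of expression —
  the null hypothesis of the confounder check is true by construction.
* **Seeding**: one master seed; named substreams (baselines, cohort,
  null, clinical) are derived through `SeedSequence`, so
  `generate_null_samples` shares the per-gene baselines of
  `generate_cohort` at the same seed and can serve as held-out controls.

What the generator does **not** emulate: gene–gene correlation,
RNA-quality/FFPE degradation gradients, probe-specific hybridization
efficiencies, lot effects (the calibrator correction is therefore off by
default), or any coupling between expression and clinical covariates
beyond cohort membership. Passing tests show the pipeline's machinery is
correct and well calibrated under this model; they are not evidence about
real tumors.

## Normalization

nSolver order: background → positive-control → housekeeping.
Background per sample is the mean of its negative probes (alternatives:
mean + 2·SD, max), subtracted from non-control probes and floored at 0;
control rows are kept unchanged for audit. Both normalizations use the
factor `mean_s'(geomean(ref, s')) / geomean(ref, s)`; positive-control
factors scale all non-control probes, housekeeping factors scale
endogenous probes only. Geometric means are strict by default (a zero
reference count is an error); a 0.5 pseudocount is opt-in, because silent
pseudocounts can mask QC failures. Factors outside [0.3, 3.0] are flagged
but never dropped — dropping is an explicit user decision.

## Differential expression

Per-gene two-group fit on log2(normalized + 1): log2FC, pooled variance
s² (df = n₁ + n₂ − 2), unscaled SD √(1/n₁ + 1/n₂). Variances are shrunk
toward a scaled inverse-chi-square prior fitted by method of moments on
log s² (trigamma-inverse solved by Newton iteration, tolerance 1e-10);
the moderated t uses the posterior variance and df_total = df + d0, with
a normal reference when d0 is unbounded (no excess variance spread).
Zero-variance genes participate in the moment fit at the smallest
positive variance (flagged) rather than being dropped, which would bias
d0. The implementation agrees with Bioconductor limma's `eBayes` to
~1e-8 relative on d0, s0², and every t-statistic on a 120-gene fixture —
that cross-check lives in the test suite, not in the pipeline.

Multiplicity: Benjamini–Hochberg step-up, implemented directly and
checked against a brute-force oracle and statsmodels. DEG selection uses
strict linear-scale inequalities (2^log2FC > cut, < 1/cut) at adjusted
p < 0.01. Tables sort by adjusted p, ties broken by raw p then gene id.

## Clustering

Genes are standardized (mean 0, variance 1, n−1 denominator;
zero-variance rows zeroed and flagged), samples agglomerated under
Euclidean distance with average linkage by default (monotone, the common
heatmap default; complete/single/ward available). The engine is
scipy's `linkage`; merge heights are validated against an independently
coded O(n³) re-agglomeration oracle. Segregation is scored by cutting
the tree at k = 2 and counting samples whose cluster majority label
(EXT vs combined Focal/Non) differs from their own.

## Gene-panel risk score

Panel genes are the top 10 rows of the DEG table (ranked by adjusted p).
Per gene, the threshold is the 95th centile — linear interpolation
between order statistics ("type 7", the dominant software default) — of
the 20 Non+Focal training samples' normalized values. With n = 20 this
puts the threshold between the two largest training values, so exactly
one training value per gene exceeds it. A sample scores 1 per gene
strictly above threshold (values exactly at threshold score 0), total
0–10; high-risk means total > 2.5. The alternative high-risk rule
(total ≥ 2) is exposed as configuration. Because thresholding is
rank-based, the score is invariant to any strictly increasing per-gene
transform applied consistently, so the linear-vs-log scale question is
immaterial; the default operates on normalized linear values.

Upper-tail scoring is the default; an opt-in direction-aware mode scores
down-regulated panel genes against the 5th centile instead.

Evaluation is in-sample, as in the study design this mirrors (no
cross-validation; stated openly). Held-out evaluation is available
through generated null samples: with a large training set the per-gene
exceedance rate converges to 1 − 0.95 = 0.05 and the mean null score to
0.5. ROC operating points are cutoffs at midpoints between distinct
scores plus sentinels, traversed in descending-cutoff order so the curve
runs (0,0)→(1,1); the trapezoid AUC equals the half-tie Mann–Whitney
probability exactly.

## Enrichment and cohort statistics

Over-representation uses the inclusive upper hypergeometric tail
P(X ≥ k) with the 740-gene codeset as universe (the assay constrains the
sampling frame), BH across sets. Query genes outside the universe are
dropped with a warning; sets with no universe overlap are skipped.
Cohort tables use the Pearson chi-square without continuity correction
(Yates opt-in) and the pooled-variance Student t (Welch opt-in), with a
low-expected-count flag.

## Problem sizes and numerical choices

Simulation-based checks use 20 cohorts (seeds 1–20, 45 samples, 784
probes each; one cohort runs in well under 2 s), 10,000 genes for raw-p
calibration, and 2,000 null samples for centile calibration — sizes at
which every targeted property is measurable with comfortable margins.
Tolerances: trigamma-inverse 1e-10 relative; oracle equivalences exact
to ≤1e-9; stochastic calibration bands as stated per test (e.g.
exceedance 0.05 ± 0.01). Degenerate inputs are errors, not silent
repairs: single-sample scaling, single-class ROC, empty
query/universe, sub-minimal strata in the confounder split.

## Known limitations

In-sample panel evaluation overstates real-world performance; the
generator's independence assumptions (no gene–gene correlation, nerve
fraction independent of expression) make its nulls cleaner than real
data; printed-table statistics from the motivating study are not
reproducible from its printed counts and are deliberately not treated as
ground truth; the Reactome snapshot the original pathway figures depend
on is not bundled — enrichment is exercised against synthetic gene-set
fixtures.
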