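# Methods note

This note records the statistical model, the defaults and their rationale,
what the synthetic generator does and does not emulate, the numerical choices,
and the open design decisions. No empirical claims are made here beyond what
the test suite and `scripts/acceptance.py` compute.

## Synthetic study model

A study consists of `n_groups` comparison groups (case/control cohorts matched
by tissue and smoking status). For gene *i*, group *g*, subject *j*:

```
x_{igj} = baseline_i + batch_{gi} + 1[case_j] * sign_{gi} * effect_i + eps,   eps ~ N(0, noise_sd^2)
```

- `baseline_i ~ N(8, 2)` on the log2 scale.
- `batch_{gi} ~ N(0, batch_sd^2)` — an additive per-(group, gene) offset
  emulating cross-platform location shifts; default `batch_sd = 0.5`.
- Gene roles: **planted** genes carry one common nonzero sign in every group;
  **decoy** genes flip sign in exactly one randomly chosen group; **null**
  genes have no shift. `effect_i` is the shift in within-group SD units
  (default scalar 1.0).
- Covariates: FEV1 % predicted `N(95, 12)` in controls with a −35 case shift,
  age `N(64, 8)`, gender Bernoulli(0.5), pack-years `N(45, 15)` plus +10 in
  cases. Reference defaults: 3 groups, 500 genes, 30 planted, 10 decoys,
  40 cases + 40 controls per group.

The per-gene truth stream is derived solely from the config seed, so an
external validation cohort generated from the same config shares gene-level
truth (baselines, signs, effects) while drawing fresh subjects, batch offsets
and noise.

**What the generator does not emulate:** probe-level cross-hybridization,
gene–gene correlation beyond what the shared case/control shift induces,
platform-specific intensity response curves, missingness, or realistic
covariate–expression coupling (covariates are associated with the label, not
directly with expression).

## Probe-level normalization chain

Applied consecutively: normexp background correction → quantile normalization
→ probe filtering/collapse → log2.

- **normexp**: each array is fit by a Normal(μ, σ²) + Exponential(α)
  convolution via the method of moments (α = cbrt(m₃/2), σ² = v − α²,
  μ = m − α) and intensities are replaced by the posterior expected signal
  E[S | X = x] = σ·h(z) with z = (x − μ − σ²/α)/σ and h(z) = z + φ(z)/Φ(z).
  For z < −6 the asymptotic expansion h(z) ≈ (1 − 2/z²)/(−z) is used to avoid
  catastrophic cancellation. Method-of-moments estimation is deliberate
  (simple, deterministic); it is noisier than maximum likelihood, which bounds
  the achievable per-array accuracy.
- **Quantile normalization**: columns are mapped to the cross-column means of
  the order statistics; tied values within a column receive the mean of the
  target values their rank run spans, making the transform well defined and
  idempotent under ties.
- **Probe collapse**: control probes and probes without a gene id are removed;
  per gene the probe with the highest mean intensity across samples is kept
  (first in input order on ties).

## Differential testing and consistency voting

Per group, each gene gets a two-sample t-test on log2 values (Student pooled
by default; Welch available) with Benjamini–Hochberg q-values reported
alongside. A gene is a consistent DEG when, at level `alpha = 0.05`, at least
`min_groups = 3` groups are simultaneously significant and same-signed
(**joint** mode, default). **independent** mode counts the significance and
sign votes separately; joint ⊆ independent always, and the two coincide when
exactly 3 groups are tested. Joint is the default because it is the stricter
reading and the two rules agree on 3-group tissues.

## PC1 discriminant

Each group's genes are min–max rescaled to [0, 1] (constant genes map to 0.5),
subjects are row-concatenated across groups, and PCA (mean centering only, no
scaling — the rescale already bounds every gene) is fit by SVD. Sign
convention: the largest-magnitude loading of each component is positive.
PC1 scores are `(X − μ)·L`; external subjects are projected with the stored
`μ` and `L`, and rescaled with the *training* score min/max so all subjects
share one scale (whether to rescale with training or pooled ranges is an open
question; training-range is the choice recorded here). An orientation sign
makes cases score high for ROC purposes.

Separation testing outside the search uses a Lilliefors normality gate
(α = 0.05, both labels) with Mann–Whitney fallback; inside the RDFS objective
the pooled t-test is always used so the search minimizes one continuous
objective. ROC points come from the full threshold sweep with trapezoid AUC
(equal to tie-corrected U/(n₁·n₂)); the operating threshold maximizes the
F-score (harmonic mean of TPR and PPV) with ties broken toward the larger
score margin.

## RDFS reduction

From the full candidate set, a uniformly random untried gene is tentatively
removed; the PC1 t-test p-value on the reduced set is recomputed, and the
removal is accepted iff p strictly decreases, after which the untried pool is
reset (a previously rejected gene may become removable after the set changes).
The iteration stops at a local optimum (no single removal improves p) or at
`min_set_size = 2`. Protocol: `n_runs = 10` runs, each with a fresh
90/10 split stratified by group × label, `n_iterations` independent searches
per run (pipeline default 50) sharing the run's training subjects; the
iteration with the lowest final p is the run's best set, evaluated by AUC on
training and held-out subjects. The **persistent** genes are the intersection
of all runs' best sets; a prefix-intersection curve over runs is exported.

Numerical choices: the training matrix is centered once and its covariance
cached; a gene subset's covariance is a submatrix, so each tentative removal
costs one slice plus a warm-started power iteration (tolerance 1e-13, exact
symmetric eigensolver fallback) for the top eigenvector — verified against a
full PCA refit to 1e-8. Randomness uses hierarchical `SeedSequence` spawning
(per run, per iteration), making every result bit-reproducible.

## External validation

A validation cohort is min–max rescaled within itself and projected through
the stored model. Genes missing from the validation platform are imputed from
the training cohorts: `label_mean` (default) fills with the training mean of
subjects sharing the validation subject's disease label — kept as the default
for procedural fidelity, but label-leaking, so every artifact produced under
this mode carries an explicit leakage warning; `overall_mean` is the leakage-safe
alternative. Direction concordance compares validation log2FC signs with the
reference up/down calls; a zero fold change is non-concordant by convention
(conservative).

## Covariate regression

Gene log2 expression is regressed (OLS with intercept) on one exposure
(FEV1 % predicted or % emphysema — never both when their pairwise VIF
exceeds 2.0) plus adjustment covariates; categorical covariates are
dummy-coded (drop-first). VIF = 1/(1 − R²) is computed per predictor from an
auxiliary least-squares fit with intercept, reporting +∞ for perfect
collinearity. A categorical candidate is an effect modifier iff its stratum
slopes differ in sign or only a strict subset of strata is significant, AND
at least one stratum has p < 0.05 — the slope-difference condition is an
operationalization recorded as a design decision. No multiple-testing correction gates this
stage; BH q-values are emitted for transparency. Strata with fewer than
(predictors + 2) subjects are skipped with a warning.

## Pipeline

Stages (simulate → preprocess → degs → select → pc1 → rdfs → persist →
validate → regress) each write TSV/JSON artifacts into a run directory and
record parameters plus SHA-256 output hashes in `manifest.json` (no
timestamps), so a rerun with the same config and seed is byte-identical.
`PipelineConfig` fields and defaults: `alpha = 0.05`, `min_groups = 3`,
`mode = "joint"`, `test_variant = "student"`, `rdfs_runs = 10`,
`rdfs_iterations = 50`, `test_fraction = 0.1`, `min_set_size = 2`,
`imputation_mode = "label_mean"`, `validation_cases/controls = 20`,
`probe_level = false` (probe-level chain off by default since the simulator
emits gene-level log2 data), `regression_covariates = (age, gender, group)`,
plus the embedded simulation config.

## Limitations

- All quantitative behavior is established on synthetic data; absolute
  numbers from real cohort studies are not reproducible without the original
  platform data.
- The RDFS objective optimizes a training p-value; with strong planted
  effects the held-out AUC saturates near 1.0 for reduced and full candidate
  sets alike, so "reduced beats full" comparisons are uninformative in that
  regime.
- `label_mean` imputation is intentionally label-leaking (kept for fidelity,
  loudly flagged); use `overall_mean` for honest external evaluation.
- Method-of-moments normexp is less efficient than maximum likelihood.
- OLS only: no robust/clustered standard errors or mixed effects.
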