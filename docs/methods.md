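# Methods

This note documents the models implemented in `pcclock`, the synthetic
testbed they are validated on, and the numerical and design choices that were
genuinely open.

## PC decomposition and projection

Training centers each probe by its mean beta and decomposes the centered
matrix by SVD, keeping all K = min(n_train, n_probes) components. Probes are
*not* scaled to unit variance: beta values share the common [0, 1] scale, and
scaling would inflate near-constant probes into the leading components. With
centering, the final component is rank-deficient (its singular value is at
machine-noise level) and is excluded from every downstream regression.

Scores for any cohort are S = (X − μ_train) V, with probes aligned to the
training order by id. Singular-vector signs are fixed by forcing the
largest-magnitude entry of each rotation column positive, so repeated fits and
serialization round-trips are bit-identical. Projection refuses missing probes
by default; the `fill_with_center` policy substitutes the training mean
(contributing exactly zero to every score) and reports coverage, for cohorts
measured on a reduced array.

Invariants enforced by tests: rotation orthonormality (1e-8), zero-mean
training scores (1e-8), var(S_k) = d_k²/(n−1) (1e-8), and exact
self-projection.

## Elastic-net clock

Age is regressed on PC scores under the objective

    (1/2n) Σ (y − γ₀ − s·γ)² + λ Σₖ [α|γₖ| + (1−α)γₖ²/2],   α = 0.5.

Three conventions matter and are pinned here:

- **Predictor standardization.** PC score variances span orders of magnitude;
  penalizing raw scores would effectively discard low-variance PCs.
  Predictors are standardized internally and coefficients returned on the raw
  score scale.
- **Response standardization.** The canonical coordinate-descent
  implementation of this model family also rescales the response to unit
  variance internally (λ is reported on the original response scale). This
  determines the relative weight of the ridge term along the path and is not
  cosmetic: without it the minimum-CV-error solution is several times denser.
  Our implementation reproduces the reference behavior; on a shared test
  problem the selected λ, active-set size and CV error agree with the
  R reference implementation (1.19 / 33 / 43.6 here vs 1.19 / 33 / 44.0).
- **Path and selection.** 100 log-spaced λ values from λ_max (smallest
  all-zero penalty) down to λ_max·10⁻² when n < p, 10⁻⁴ otherwise; 10-fold CV
  with folds dealt from a seeded shuffle (`cv_seed`, recorded in the model
  container); λ at minimal mean CV squared error, with no one-standard-error
  rule.

The solver is scikit-learn's coordinate descent; the final refit at the
selected λ is solved to near machine precision (its KKT residuals are a test
surface, checked to 1e-6), while CV path fits use a looser stop since they
only rank penalties.

## Sex-stratified consensus and the core clock

Three clocks are fit on one shared decomposition: all training samples, males
only, females only. The **core PCs** are the exact intersection of the three
selected PC index sets. The final clock refits the elastic net on both sexes
with every non-core PC zeroed out — literally zeroing the score columns, which
is algebraically identical to dropping them (verified to 1e-10) but keeps PC
numbering stable. An empty intersection is a valid, warned outcome.

On the default synthetic cohort the consensus behaves as the design intends:
the PC aligned with the sex-independent age factor reaches all three
selections in every tested seed, while the matched "ablated" clock built from
all non-core PCs selects an empty model (constant prediction) — the aging
signal lives in the core. Because λ is chosen at minimal CV error, a few of
the ~250 pure-noise PCs per cohort enter the three-way intersection by chance
(per-PC rate ≈ 0.4%, vs ≥ 95% for the age PC); min-CV-error selection is
known to over-include, and the consensus shrinks but cannot eliminate this.

## Synthetic cohorts

The generator produces beta matrices with known structure:

    z_ik   = a_k·age_i + s_k·sex_i + g_k·patho_i + o_k,region(i) + N(0, η_k)
    logit_ij = μ_j + Σ_k L_jk z_ik + N(0, σ_e),   β_ij = logistic(logit_ij)

with sex coded ±1/2 and sparse loadings L (per-factor density × N(0, scale)).
Factor 0 is the cell-composition factor: its score is a deterministic affine
map of the sample's neuron proportion, which declines linearly with age
(slope −0.002/year around 0.61, noise sd 0.05) and is written to the sample
sheet. It receives the largest loading-density × variance product so that PC1
aligns with cell composition, as observed on real brain arrays where cell
composition, not age, dominates methylation variance.

Defaults (the study conditions used throughout the tests): 2,000 probes,
ages uniform on [20, 90], three age-linked factors with latent slopes
0.10/0.07/0.05 per year and factor noise sd 0.8 — chosen so the combined
latent age information supports a held-out prediction correlation near 0.95,
the level reported for well-trained brain clocks — one sex factor (effect 2.0,
noise 1.0), a pathology flag (prevalence 0.3) loading on one age factor with
effect 0.8, baseline logits N(0, 1.5), residual logit noise σ_e = 0.5, and
technical rescan noise σ_t = 0.02 on the beta scale. Replicate pairs are
β + N(0, σ_t) clamped to [0, 1]; multi-region cohorts share individuals and
subject-level factor scores, with per-region offsets o_kr and idiosyncratic
region noise (sd 0.3).

What the generator does *not* emulate: probe-type chemistry, chip/batch
effects, genomic autocorrelation, realistic probe annotations, or non-linear
age trajectories. Passing tests therefore demonstrate correctness of the
machinery and qualitative reproduction of the method's claims (core
sufficiency, reliability gain, pathology association), not quantitative
transfer to any particular real cohort.

One consequence of the logistic link is worth noting: a latent factor is
spread over several principal components (nonlinear harmonics), so PCs with
weak linear correlation to any factor can still be genuinely structural. Tests
that need a "pure noise" judgment therefore compare each PC's score variance
against its variance in the noiseless reconstruction (< 10% surviving =
noise) rather than screening on factor correlations.

## Age acceleration

OLS acceleration regresses predicted age on chronological age and neuron
proportion (intercept included; additional covariates optional) and returns
the residuals, which are orthogonal to the design to 1e-8 by construction.
Samples with missing covariates are dropped listwise with an explicit report
— silent phenotype imputation would corrupt the group tests downstream.

For multi-region designs the model is

    ŷ = β₀ + β₁·age + β₂·neuron + u_region + ε,  u ~ N(0, σ_b²), ε ~ N(0, σ_ε²).

The variance ratio θ = σ_b²/σ_ε² is profiled out of the (RE)ML deviance
(block compound-symmetric covariance; closed forms per group) and minimized
by Nelder–Mead on log θ from four start points plus the θ = 0 boundary.
REML is the default criterion (the convention of the standard mixed-model
software), ML is available. Acceleration is the **conditional** residual
y − Xβ̂ − û, i.e. the region BLUP is subtracted. Marginal and conditional R²
follow the usual variance-partition definitions. The fit agrees with an
independent mixed-model implementation to ~1e-3 in fixed effects and a few
percent in variance components, recovers (σ_b, σ_ε) = (2, 1) within 20% at
n = 600 over 3 regions, and its optimum beats a 100-point grid over θ.

Group comparisons report per-level means ± SEM, one Kruskal–Wallis omnibus
p per (stratum × grouping) cell, and Benjamini–Hochberg adjustment across the
full grid by default (`per_stratum` available — the appropriate family is a
judgment call the caller can make), flagging adjusted p < 0.05.

## Statistical primitives

- **Pearson test**: r with the two-sided t-test on n − 2 df (scipy).
- **bicor**: biweight midcorrelation with raw MAD (no 1.4826 factor), the
  9·MAD tuning divisor, Tukey biweights (1 − u²)²·1{|u| < 1}, and Pearson
  fallback (warned) on zero MAD — the canonical definition, with no
  outlier-cap parameter.
- **Kruskal–Wallis**: mid-ranks, tie correction, chi-square p on g − 1 df
  (scipy); all-identical values return H = 0, p = 1 by convention.
- **BH**: step-up adjusted p-values in input order (scipy).
- **ICC(C,1)**: two-way ANOVA without interaction;
  (MS_BS − MS_E)/(MS_BS + (k−1)MS_E); asymmetric CI by inverting
  F = MS_BS/MS_E with (n−1, (n−1)(k−1)) df. Perfectly consistent raters
  (MS_E = 0) return exactly 1.

## Ranked lists for enrichment

Per-PC CpG scores are |loading| × sd. Two sd conventions are found in
practice and both are implemented: `cpg_sd` (default) uses each CpG's sd in a
reference cohort; `pc_sd` uses the projected PC score sd, a scalar, reducing
the ranking to |loading|. The top 10% (ceiling) is kept, ties broken
lexicographically by probe id. Gene mapping drops unannotated probes and keeps
each gene's first (highest-ranked) occurrence; the background list is all
unique annotated genes. Running the enrichment itself is out of scope.

## Serialization

Models are stored in a single `.npz` container (probe ids, centers, rotation
columns, singular values, clock coefficients and metadata, format-version
tag). Storing only the clock's rotation columns is supported and yields
identical predictions, since unselected PCs never enter the predictor.
Corrupted or version-mismatched containers fail loudly with no partial model.

## Problem sizes

Test and acceptance runs use 300 training / 150 held-out samples × 2,000
probes (20 seeds for the recovery, consensus and reliability claims), 30
replicate pairs, and n = 600 over 3 regions for the mixed model — sizes at
which every multi-seed experiment completes in a few minutes on one CPU while
leaving the claimed effects clearly resolvable.

## Known limitations

- The elastic-net path, fold assignment and response scaling match the
  reference software family's defaults, but exact PC selections are still
  CV-fold dependent; only seed-pinned runs are bit-reproducible.
- The LME implementation supports a single random intercept (the model the
  multi-region analysis needs), not crossed or nested random effects.
- `harmonize_probes` trusts the user-supplied annotation for sex-chromosome
  exclusion; no array manifest ships with the package.
- The CpG-clock applier takes user-supplied coefficient tables; published
  clock weights are not bundled.
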