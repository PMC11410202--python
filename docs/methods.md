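# Methods

## Model and estimator

The package targets the one-sample Mendelian-randomization structural model

    Y = Xβ + ε_y,    X = Gα + ε_x,    (ε_x, ε_y) ~ N(0, σ²[[1, ρ], [ρ, 1]]),

with an N×p additive dosage matrix G, scalar exposure X and outcome Y, and
confounding encoded by the error correlation ρ. β is the causal effect of
interest.

MR-SPLIT estimates β by adaptive 2-fold sample splitting. For a random
partition {I₁, I₂} (sizes ⌊N/2⌋ and N − ⌊N/2⌋), and for each half I_k:

1. **Selection** on the complement I_kᶜ: sure-independence screening ranks
   SNPs by absolute marginal correlation with X and keeps `sis_keep` of
   them (default: half the training-half size, capped at p); a LASSO with
   penalty chosen by seeded 5-fold cross-validation (CV-error minimizer)
   picks the instruments and supplies effect estimates α̂.
2. **Classification**: each selected instrument gets a partial-F value —
   the F-test of dropping it from the full OLS model of X on all selected
   instruments plus intercept, computed via the t² identity — and is
   labelled major (F > threshold, default 30) or weak.
3. **Composite instrument** on I_k: Ĝ_W = Σ_j ω_j G_j over the weak set,
   with ω_j = α̂_j / Σ|α̂_j| (signed, L1-normalized). Major instruments
   enter individually; dosages are used unstandardized.
4. **Cross-fitted exposure**: X̂ on I_k is the OLS fit of X on
   [1, majors, Ĝ_W] within I_k. The two halves are stacked in original
   sample order.
5. **Second stage**: β̂ = (X̂′X̂)⁻¹X̂′Y with an intercept over the full
   sample. The standard error follows the standard 2SLS convention — the
   error variance is estimated from residuals Y − b₀ − X β̂ computed with
   the *observed* exposure — with t-based two-sided p-values and 95% CIs.
   A binary outcome switches the second stage to logistic regression of Y
   on [1, X̂] with Wald inference (predictor substitution); LIML refuses
   binary outcomes.

The split is repeated L times (default 50; ~50 splits is where power
stabilizes at small N in the stability study). Per-split p-values are
aggregated with the equal-weight Cauchy combination rule, which tolerates
arbitrary dependence between splits; the aggregated β̂ is the mean of the
successful splits' estimates. Splits in which either half selects nothing
are marked failed and excluded with the weights renormalized; fewer than
min(10, L) successes is an error rather than a silent re-draw, because
re-drawing conditions on selection success and would bias the aggregate.
No CI is attached to the multi-split aggregate; per-split CIs are retained.

### Comparators

* **2SLS / LIML**: instruments selected on one random half (same SIS+LASSO
  machinery), estimation on the other half using all selected instruments
  without the major/weak distinction. LIML is the k-class estimator with
  κ the smallest eigenvalue of the generalized eigenproblem on the centered
  (Y, X) cross-product matrices with and without the instrument projection;
  forcing κ = 1 reproduces 2SLS exactly, and the just-identified case
  coincides with 2SLS and the Wald ratio.
* **CFMR**: K-fold (default 10) cross-fitted instrument. Per fold, a LASSO
  exposure-prediction model is trained on the complement (predictions, not
  re-weighted selected SNPs — the model's fitted polygenic score); its
  predictions on the fold form the stacked single instrument G̃, followed
  by ordinary 2SLS of Y on X instrumented by G̃ on the full sample. Folds
  with empty selections contribute their training mean (constant).

### Selector variants

`selector="dlasso"` replaces the penalized selection by a desparsified
LASSO (nodewise-residual projection): each LASSO coefficient is debiased
by the projection z_j′(y − Xβ̂)/(z_j′X_j) where z_j is the nodewise-LASSO
residual of column j, with standard error σ̂‖z_j‖/|z_j′X_j|; SNPs with
two-sided normal p ≤ 0.05 are retained with their debiased effects. In an
orthogonal design this reduces to per-column OLS inference. It is the
selection used in the case-study analyses of the source method and is
slower than the plain LASSO (p nodewise fits per call).

## Synthetic data

`simulation.SimConfig` fixes the study conditions: N samples, p = 300
independent SNPs with dosages Binomial(2, maf = 0.3), five causal SNPs,
bivariate-normal errors with unit (or σ² = 5 for the wide-error scenario)
marginal variances and correlation ρ, and X, Y from the structural model.

**Effect-size calibration.** The causal pattern entries are per-SNP
*shares of the genetic variance* — the unequal pattern
(0.4, 0.4, 0.1, 0.05, 0.05) and the equal pattern (0.2, …, 0.2) each sum
to one — so SNP j receives α_j = ω₀√a_j with

    ω₀ = sqrt( h²σ² / ((1 − h²) · Σ_j a_j · 2·maf·(1 − maf)) ),

making the causal SNPs jointly explain exactly h² of Var(X). This share
reading, rather than treating the entries as raw coefficients, is what
reproduces the published identification rates quantitatively: under it the
fourth SNP's partial-F noncentrality on a half-sample at h² = 0.5,
N = 2000 is ≈ 50, matching the ≈ 90% major-classification rate at F > 30,
whereas raw-coefficient scaling would give a noncentrality of ≈ 15 and a
rate near 4%.

**What the generator does not emulate:** linkage disequilibrium (SNPs are
independent), varying allele frequencies, pleiotropic instruments,
covariates, and non-normal errors. Passing tests therefore demonstrate the
estimator's selection/weak-instrument behavior under the study's idealized
conditions, not robustness to LD-induced instrument correlation or invalid
instruments.

## Study harnesses and problem sizes

`run_estimator_study` draws one dataset per replicate and runs every
requested method on it (shared data, so method contrasts are paired);
it reports |β − mean β̂|·100, the mean estimated SE and the empirical SD
(both, since either can serve as the SE summary), 95% CI coverage, and the
rejection rate at the 0.05 level. `run_major_iv_study` selects on a random
half-sample per replicate — the same sample size at which the split
pipeline sees data — and tabulates per-SNP major-classification rates and
the mean number of major-classified noise SNPs. `run_split_count_study`
runs max(L) splits once per replicate and evaluates each requested L on
the prefix, so the stability curves are computed on identical randomness.

The shipped test suite and acceptance script run these harnesses at
100–300 replicates per cell with tolerance bands ±3·sqrt(q(1−q)/reps) for
proportions and ±3·SD/√reps for means; replicate seeds derive from a
single master seed (`seed_rep = master + 1000003·cell + 7001·rep`, kept
below 2³¹) so any cell or replicate is re-runnable in isolation.

## Numerical choices

* Intercepts are included in every regression (selection, partial F, both
  2SLS stages); the partial F is therefore location/scale-free in the
  exposure.
* Partial-F degrees of freedom use the full-model residual df
  (N − k_full − 1), making the single-added-variable F equal the squared
  full-model t-statistic exactly.
* SIS ties are broken by ascending SNP index; zero-variance columns are
  excluded with a warning.
* LASSO cross-validation folds are seeded from the split-level seed
  (split seed = master + split index), so the whole pipeline is
  reproducible; fold assignment follows within-half row order, which is
  the one source of (seeded) non-invariance under row permutation.
* A selection exceeding the partial-F df limit (more instruments than
  n − 2 in the half) is truncated to the strongest effects.
* Endpoint p-values are clamped just inside (0, 1) before the Cauchy
  transform (tan is singular at the endpoints).
* Rank-deficient first-stage designs fall back to the minimum-norm
  least-squares fit with a logged warning.
* Degenerate empty selections mark the split failed (status, not
  exception); structural errors (dimension mismatches, binary outcome for
  LIML) raise.

## Design choices on genuinely open points

* Composite weights use the selector's own penalized (or debiased) effect
  estimates; a post-selection OLS refit is available via `refit_alpha`.
* The CV penalty is the CV-error minimizer, not the 1-SE rule: selection
  feeds estimation on independent data, so mild over-selection is benign —
  extra weak instruments are absorbed into the composite.
* Composite weights keep the sign of α̂ (a negative weight flips a
  negatively associated dosage), and the signed weights L1-normalize.
* The whole-sample univariate pre-filter used for speed in the source
  method's case study reuses full data before splitting and is therefore
  off by default (`select_ivs` exposes no such filter; it can be applied
  upstream).
* Phenotypes are used as provided — no automatic transformation.

## Known limitations and deviations

* **Comparator magnitudes.** With the CV-minimizing LASSO, a training half
  of 500 selects ~10–30 instruments. The published comparator magnitudes
  at the weak-instrument cells (2SLS |bias|·100 ≈ 9.45 with inflated type
  I error, LIML SE ≈ 0.17) are reproduced only when ~100 instruments per
  half enter the estimators; no standard penalty choice (CV-min or 1-SE,
  5- or 10-fold, verified against R glmnet) retains that many. This
  package keeps the documented CV-min selection, so its half-sample 2SLS
  is *less* biased (|bias|·100 ≈ 3) and not measurably inflated under the
  null at these settings; the qualitative orderings (MR-SPLIT least
  biased, best coverage, highest power; LIML intermediate) are unchanged.
* LIML's k-class variance can be non-positive under extremely weak
  instruments; this raises rather than returning a spurious SE.
* K-fold (K > 2) variants of the split estimator are not implemented;
  2-fold balances selection and estimation data and is the recommended
  design. CFMR's fold count is free (default 10).
* Genotype QC (missing-rate/MAF/HWE filters, LD pruning) is out of scope;
  inputs are assumed PLINK-cleaned. Missing dosages are rejected unless
  per-SNP mean imputation is requested explicitly.
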