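# Methods

## Data model

The unit of analysis is a fungal strain with eight phenotypes. D₁₀ and the
four metal tolerances span orders of magnitude and are log₁₀-transformed;
T_max (°C) and the two binary phenotypes enter untransformed; phylum is
recoded as a binary *Ascomycota* indicator. Genus — the grouping variable
for the mixed models — is the first whitespace token of the species name,
which places the one *Saccharomyces* hybrid in *Saccharomyces*. The builtin
panel (95 strains, 67/28 by phylum, 34 *S. cerevisiae*) ships as a plain
CSV with a `uncertain_fields` provenance column (empty for every row) so
that any future curation of individual cells can be flagged without a
schema change. Missing values are rejected rather than imputed: the panel
is complete, and silent imputation on a 95-row table would be worse than an
error.

## Correlation screen

One product-moment matrix covers all variables; binary ones enter as 0/1,
so mixed cells are point-biserial and binary-binary cells are phi
coefficients. Two-sided p-values use t = r√((n−2)/(1−r²)) on n−2 df. No
multiplicity correction is applied; instead the result object carries a
note that with ~30 simultaneous pairs only the three-star (p < 0.001) level
is a strong signal. A constant column yields flagged NaN cells rather than
an exception, since a subset (e.g. one phylum) can legitimately make an
indicator constant. The r matrix is made bitwise-symmetric by mirroring the
upper triangle.

## Logistic regression

Maximum likelihood by IRLS from β = 0; convergence when max|Δβ| < 1e-8 or
the relative deviance change < 1e-10, capped at 100 iterations. The
covariance is the inverse Fisher information at the optimum (observed =
expected under the canonical logit link). AIC = −2ℓ + 2k and
AICc = AIC + 2k(k+1)/(n−k−1); AICc is undefined (NaN, flagged) when
n − k − 1 ≤ 0. Wald intervals use the fixed normal multiplier 1.959964.

**Separation.** A converged fit whose linear predictor exceeds 30 in
absolute value is flagged as (quasi-)separated: beyond that bound the
fitted probabilities are within 1e-13 of 0/1 and the coefficients are
drifting toward infinity at machine precision. Flagged fits are still
returned — with `wald()` marking them unreliable — mirroring the behavior
of standard GLM software.

**Collinearity.** Two VIF variants are implemented for a predictor in a
multi-predictor fit: the GLM-native generalized VIF from the correlation
structure of the non-intercept coefficient covariance (ratio-of-determinants
form), and the classical OLS design-matrix VIF 1/(1−R²). They answer
slightly different questions and disagree on the builtin panel (4.19 vs
2.66 for the phylum indicator); the covariance form is the default because
collinearity in a GLM manifests in exactly that coefficient covariance.

**ROC.** The empirical curve is evaluated at every distinct score; AUC is
computed by midranks, which equals both the trapezoidal area and the
tie-corrected concordance probability. The 95% CI uses the DeLong
U-statistic variance from per-score structural components, normal
approximation, truncated to [0,1]; a stratified percentile bootstrap
(2000 draws) is available as an alternative.

## Multi-model inference

All 2^m main-effect subsets (intercept-only included) are fitted; requested
interaction terms are admitted only into subsets containing both parents
(marginality). Weights are the Akaike softmax over AICc; exact AICc ties
share weight naturally. Importance is the summed weight of containing
models. Two averaging conventions are provided:

- **full** (default): a model omitting the term contributes β = 0, SE = 0 —
  the shrinkage estimator;
- **conditional**: weights renormalized over containing models — the
  natural average.

Both use the unconditional SE Σᵢ wᵢ√(SEᵢ² + (βᵢ − β̄)²), which folds
between-model spread into the interval.

By default non-convergent and separation-flagged fits stay in the weighted
set (flag-propagating) and are counted in the diagnostics; `strict=True`
drops them before normalization. The distinction matters on small panels:
in the 28-strain Basidiomycota subset, 51 of 128 candidate models perfectly
separate the outcome and would otherwise absorb 98% of the weight with
meaningless infinite-coefficient fits. The packaged paper-reproduction flow
therefore runs MMI with `strict=True, averaging="conditional"`; with those
settings the per-phylum analyses single out logCrCl₃ (Ascomycota) and T_max
(Basidiomycota) as the only predictors whose averaged CIs exclude zero, and
the logCrCl₃ × T_max interaction CI covers zero. Model-averaged *point
estimates* on this panel are convention-sensitive and should be read
qualitatively; the importance scores and CI-vs-zero conclusions are the
stable outputs.

## Noise-benchmarked boosted trees

Split-gain relative influence from a gradient-boosted classifier
(Bernoulli deviance, scikit-learn) has no significance scale, so decoy
features are injected per repeat: standard-normal columns plus within-column
permutations of randomly chosen real predictors (same marginals, no
association). Defaults: 5 + 5 decoys, 20 repeats, 500 trees, depth 3,
learning rate 0.05, 75% subsampling, no early stopping — fixed tree counts
keep the report bitwise-reproducible from the config seed, with per-repeat
RNG streams derived as SeedSequence(seed, repeat). The headline exceedance
score — the fraction of repeats in which a predictor beats the *maximum*
decoy influence — is the strictest benchmark; mean influence and mean rank
are reported alongside. Every knob sits in `NoiseBenchmarkConfig` because
no single setting is canonical for panels this size.

## Mixed-effects logistic models

One fixed-effect predictor x with correlated per-genus random intercept and
slope: η = β₀ + β₁x + b₀g + b₁g x, (b₀, b₁) ~ N(0, Σ). Σ is parameterized
by its Cholesky factor with nonnegative diagonal, so the optimizer can
reach the Σ → 0 boundary; such fits are flagged singular. The marginal
likelihood uses the first-order Laplace approximation: per-group
conditional modes from a penalized Newton inner loop (tolerance 1e-10 on
the gradient, step-halving), outer L-BFGS-B over (β, chol Σ) with numerical
gradients from two starting scales, keeping the better optimum. Per-genus
"total slopes" are β₁ plus the genus's conditional-mode slope deviation.
Multi-predictor fixed effects are out of scope — on genus-structured panels
this small such models generally fail to converge.

Cross-checks against an independent lme4 fit of the same models (frozen
into the test suite) agree to ~3 decimals in fixed effects and R²; on the
builtin panel the logCrCl₃ model is singular (Σ ≈ 0), which is exactly why
its marginal and conditional R² coincide at 0.312, while the T_max model
has strong genus structure (0.417 vs 0.989). The T_max conditional R² that
close to 1 signals a near-singular boundary fit; treat the per-genus slope
*ordering* as the robust output there, not the magnitudes.

R² uses the binary-GLMM latent-scale decomposition with distribution-
specific variance π²/3; the fixed-effect variance is the sample variance
(ddof = 1) of the fixed linear predictor, and the random-effect variance
averages zᵀΣz over observations with z = (1, x).

## Synthetic data

Continuous predictors come from a correlated multivariate normal (an
eigendecomposition square root, so positive semi-definite targets with zero
eigenvalues are legal); binary predictors threshold latent normals at the
quantile of the requested rate, which preserves latent-scale correlation
targets but attenuates realised point-biserial correlations — tests
therefore check signs and convergence, not exact binary-continuous r.
Genus labels are round-robin; genus effects are drawn per (seed, replicate,
genus) so earlier replicates never shift when more are drawn. `fixture_like`
emits a 95-row panel with the builtin table's shape (67/28 phyla, 34-strain
dominant species, positive metal columns) for integration tests that must
not touch the real measurements — it mimics structure, not values.

What passing synthetic tests demonstrate: correct likelihoods, weights,
coverage and recovery under the generator's assumptions (logistic outcome,
normal latents, exchangeable genus effects). What they cannot demonstrate:
robustness to real-data features the generator omits — phylogenetic
correlation beyond genus, measurement discreteness of the dose series,
informative strain selection.

## Problem sizes and determinism

All headline analyses run on the 95-row panel in seconds. Simulation-backed
tests use: Wald coverage 200 replicates at n = 500; boosted-tree checks 20
repeats at n ≤ 300; mixed-model recovery 30 replicates of 40 genera × 25
strains — sizes at which Monte-Carlo error is small enough for 2-SE
assertions while the whole suite stays desk-scale. Every stochastic
component draws from an explicit seed; reruns are byte-identical.

## Known limitations

- No penalized (Firth) logistic fallback under separation; flagged fits are
  reported as-is.
- Model-averaged point estimates depend on the averaging convention; only
  importance and CI-vs-zero conclusions are treated as stable.
- The Laplace approximation can bias variance components for very small
  groups; the builtin panel's genus sizes (1–34) are adequate for the
  reported models but boundary fits are common and flagged.
- The correlation screen reports unadjusted p-values by design.
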