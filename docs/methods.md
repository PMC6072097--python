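# Methods

## Models

Both models describe a semicontinuous outcome Y ∈ [0, 1) as a mixture
of a structural zero and a Beta-distributed positive part. Part I is a
logistic regression for the presence probability p_i = P(Y_i > 0),
`logit(p_i) = x_i'α`. The positive part is Beta in mean–dispersion
form, `Beta(μ_i φ, (1−μ_i) φ)`, so E[Y|Y>0] = μ_i and
Var[Y|Y>0] = μ_i(1−μ_i)/(1+φ); φ > 0 is a single shared dispersion
(covariate-dependent dispersion is out of scope).

* Conventional two-part (CTP): `logit(μ_i) = x_i'β`. Coefficients have
  a conditional-on-presence interpretation.
* Marginalized two-part (MTP): `logit(ν_i) = x_i'γ` with ν_i = E[Y_i]
  = p_i μ_i. Coefficients have a marginal (unconditional)
  interpretation; the implied conditional mean is μ_i = ν_i / p_i.

The MTP likelihood is the CTP likelihood reparameterized, restricted to
the region where x'γ < x'α for all rows with positive outcomes (so that
μ_i < 1). Outside that region the log-likelihood is defined as −∞ — a
value, not an exception — so an unconstrained optimizer can retreat;
inside it, the term `−lgamma((1−μ)φ)` already provides a smooth natural
barrier as μ → 1.

Zeros are detected by exact equality `y == 0`; rounding tiny positive
abundances to zero is the caller's responsibility. Outcomes equal to or
above 1 are outside the support and rejected at construction (no
squeezing transforms). The data model permits different covariate sets
for the two parts (used internally by the restricted null fits); the
public defaults use identical sets in both parts.

## Estimation

Starting values follow the standard recipe: α₀ from the logistic MLE of
1(y>0) on X (Newton–Raphson with step halving), β₀ and φ₀ from the
Beta-regression MLE on the positive outcomes (BFGS from an OLS-on-logit
start with a moment-based φ). For the MTP model γ₀ := β₀, with the
intercept shifted down by the minimal constant (+1e-3) restoring strict
feasibility when some observed row violates x'γ < x'α.

The joint likelihood is maximized by BFGS over (α, γ or β, log φ) —
log φ keeps the search unconstrained; estimates and covariance are
reported on the natural scale with a delta-method transform for the φ
row/column. Gradients are analytic (the score of the Beta part in μ and
φ involves digammas only) and are cross-checked against central finite
differences in the tests. Analytic rather than numerically
differentiated gradients are the default because the convergence
criterion below sits at the noise floor of forward-difference
gradients, and because the replicate studies perform thousands of fits.

Convergence is declared when the relative gradient

    max_j |g_j θ_j| / max(|ℓ|, 1)  ≤  1e-8

falls below tolerance (the raw max-gradient norm is also stored). BFGS
is followed by Newton polish steps — Newton directions from a central
finite-difference Hessian of the analytic gradient (step
h = ε^(1/3)·max(|θ_j|, 1)) with backtracking — which drive the
criterion well past 1e-8 whenever the optimum is interior. Up to five
jittered restarts (multiplicative N(0, 0.1²) noise on the starting
values, fixed internal seed) precede a non-convergence flag; flags are
never silent.

The covariance matrix is the inverse of the negative finite-difference
Hessian at the optimum. A non-positive-definite Hessian triggers a
warning and a pseudo-inverse fallback, flagged on the fit. The CTP
likelihood factorizes into its logistic and Beta blocks, so the joint
CTP fit must coincide with the two standalone fits — asserted in the
tests at 1e-6 and against statsmodels' `Logit` and `BetaModel` as
independent oracles.

**Boundary maxima.** Under quasi-separation of the presence indicator
(e.g., a covariate group with no zeros) the likelihood is maximized at
‖α‖ → ∞: flat enough to satisfy the gradient criterion, but with no
interior MLE and an uninformative covariance. Fits whose logit-scale
SEs exceed 100 are therefore flagged non-converged. At the reference
simulation condition this affects roughly one replicate in a thousand;
study metrics are computed over converged replicates with the excluded
count reported.

## Inference on the marginal mean

* MTP: the effect of covariate j on logit E[Y] is exactly γ_j; the LRT
  of H0: γ_j = 0 refits with the covariate removed from the γ-equation
  only (the α-equation keeps it), 1 df. A stricter joint variant
  (α_j = γ_j = 0, 2 df) is available but non-default.
* CTP: the surrogate test H0: α_j = β_j = 0 removes the covariate from
  both equations, 2 df. The actual marginal effect is computed as
  c₁α_j + c₂β_j with c₁ = (1−p)/(1−pμ) and c₂ = (1−μ)/(1−pμ) for a
  continuous covariate, and as the exact logit difference
  α_k + β_k + b₁ + b₂ + b₃ (log-partition corrections) for a binary
  one. Both identities are verified against numerical derivatives /
  direct differences in the tests. Delta-method SEs use the full joint
  covariance (the weights depend on every coefficient); the evaluation
  covariate vector defaults to the caller-supplied row — in
  multi-covariate designs there is no canonical choice, so it is
  explicit in the API.
* Comparators: the pooled-variance two-sample t-test and the Wilcoxon
  rank-sum test on the raw outcomes including zeros. Wilcoxon uses the
  exact null distribution for small untied samples and the
  tie-corrected, continuity-corrected normal approximation otherwise
  (zeros guarantee ties in practice).
* Multiplicity: Bonferroni only (`min(1, m·p)`), with m = the number of
  features actually tested by each method — adjusting for hypotheses a
  method never tested is indefensible, though it means m can differ
  across methods when degenerate OTUs are skipped.

Wald intervals use the quantile 1.959964.

## Simulation engine

`gen_two_part_beta` draws from the MTP process itself; its defaults are
the reference study condition: n = 200, one Bernoulli(0.5) covariate,
α = (1.5, 1), γ = (−2.5, 1), φ = 1 — a taxon present in ~82–92% of
samples with marginal mean abundance ~0.08–0.18 and strongly
right-skewed positive values. Infeasible configurations (x'γ ≥ x'α at
an attainable covariate value) are rejected before any draw by checking
the covariate-box corners (predictors are linear, so corners suffice).
Beta draws that underflow to exactly 0 (or round to 1) would corrupt
the zero/positive dichotomy and are redrawn, with the count logged.

`gen_zero_inflated_binomial` is the misspecification design: a
Uniform(0, 1) covariate, α₀ = 2, γ₀ = −0.5, and positive outcomes
Bin(100, μ_i)/100 on the lattice {0.01, …, 0.99}. Lattice draws of 0 or
100 are regenerated by rejection and counted; at these defaults
P(Bin = 0) = (1−μ)^100 < 1e-4, so the rejection rate is negligible (the
logged count makes that verifiable).

Replicate r of a study derives its generator from
`SeedSequence(master_seed).spawn`, making studies exactly reproducible
and replicate streams independent. Rejection studies tally per-method
rejection fractions at levels 0.01 and 0.05; the estimator study
reports, per parameter: Est (mean estimate), SE (SD of estimates), SEM
(mean of per-fit SEs), CP (95% Wald coverage), MSE. Non-converged
replicates are excluded with their count reported; a failure rate above
20% aborts the study.

What the generator does *not* emulate: compositional coupling across
taxa (each OTU is drawn independently), overdispersion beyond the Beta
law, library-size variation, and covariate-dependent dispersion.
Passing tests therefore demonstrate correctness of the estimator and
tests under the stated mixture mechanisms, not robustness to every
feature of real sequencing data (the scaled-Binomial design probes one
specific misspecification).

## Numerical choices

* All density computations on the log scale (`gammaln`, `log1p`,
  `log_expit`); μ = ν/p computed as `exp(log_expit(g) − log_expit(a))`.
* μ that rounds to exactly 1.0 (or underflows to 0) in floating point
  is treated as out of support even when the log-scale inequality
  holds.
* Finite-difference Hessian step: cube-root machine epsilon scaling;
  near-boundary non-finite evaluations shrink the step by 100×.
* The intercept-only MTP fit satisfies α̂₀ = logit(positive fraction)
  and the digamma score balance ψ(μ̂φ̂) − ψ((1−μ̂)φ̂) = mean logit of the
  positives; expit(γ̂₀) is therefore close to, but not exactly, the
  sample mean (Beta ML balances the logit scale, not the arithmetic
  mean).

## Problem sizes in the shipped studies

The acceptance script runs the estimator study at its published size
(1000 replicates at n = 200 and n = 400). The test suite uses
scaled-down tiers chosen as the smallest sizes at which the
Monte-Carlo bands are still informative: 200 replicates for estimator
summaries, 300–400 for type-I error bands (99% binomial bands around
the nominal level), 100–200 for power, 500 for the p-value uniformity
KS check.

## Known limitations

* No random effects / correlated or longitudinal data.
* Single shared dispersion φ; no covariate-dependent dispersion.
* Bonferroni is the only multiplicity correction.
* The batch pipeline skips all-zero and no-zero OTUs for the two-part
  methods (with a recorded reason); how such taxa should be handled in
  a two-part framework is a genuinely open modeling question.
* Quasi-separated presence patterns yield a flagged non-convergence
  rather than a penalized (e.g., Firth-type) estimate.
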