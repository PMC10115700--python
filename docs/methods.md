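# Methods

## Model

A respondent's latent state is a binary attribute profile α ∈ {0,1}^K.
Profiles are enumerated in binary-counting order with attribute 1 as the
most significant bit, so the all-zero profile has index 0 and the canonical
index of a profile is its binary value. Presentation orderings (e.g. by
number of attributes) are applied only at display time; the internal order
never changes.

Item *j* depends on α only through the sub-vector over its required
attributes (the q-vector row of the Q-matrix), collapsing the 2^K classes
into 2^{K_j} reduced classes indexed the same way (first required attribute
most significant; so for a two-attribute item "0 1" means only the second
listed attribute is present). The saturated G-DINA model gives each reduced
class a free endorsement probability. Reduced models constrain these to be
additive on a link scale — identity (A-CDM), logit (LLM), log (RRUM) — or
to two values (DINA: all-required vs rest; DINO: any-required vs none).
RRUM parameters are stored and compared on the probability scale; the
log-scale coefficients are derived quantities.

The structural component models the joint profile distribution as a
log-linear model with 0/1 dummy coding: order 1 = independence, order 2 =
homogeneous association (a common conditional odds ratio per attribute
pair), order K = saturated. Under dummy coding exp(λ_kl) is the conditional
odds ratio of attributes k and l given the other attributes absent, which
is why the interaction coefficients are reported alongside their
exponentials. Coefficients are estimated on the expected-count scale, so
the intercept is log(N·p_0) and all other coefficients are invariant to the
total.

## Estimation

Marginal maximum likelihood by EM over the 2^K classes:

- **E-step.** Posterior class probabilities from the current item
  parameters and structural prior. All accumulation is in the log domain
  with per-respondent max subtraction, so a 40-item pattern that is
  near-impossible under every class still yields finite posteriors.
- **M-step, items.** Saturated updates are closed-form expected
  success/trial ratios per reduced class, followed by projection onto the
  monotone cone: iterative weighted pooling of violating subset/superset
  pairs (pool-adjacent-violators lifted to the subset partial order), with
  a cumulative-max fallback pass that guarantees weak monotonicity.
  Additive models are maximized numerically on the link scale with
  non-negative attribute effects (which is exactly the monotonicity
  constraint for additive forms), warm-started from the previous iteration.
  A reduced class with zero expected trials keeps its previous value with a
  warning rather than failing — this matters at small N.
- **M-step, structural.** The log-linear model is re-fit to the expected
  class counts each iteration. The multinomial MLE is computed through the
  equivalent Poisson regression (statsmodels GLM), which accepts fractional
  counts; the saturated case is the closed-form proportion vector.
- **Convergence.** Both max |Δ parameter| < 1e-4 and |Δ loglik| < 1e-7,
  max 2000 iterations (values chosen to match common CDM-software
  practice). The log-likelihood trace is recorded and checked to be
  non-decreasing in the test suite. Item probabilities are initialized at
  the item mean ± 0.1 spread in the direction of more attributes, with an
  optional small seeded perturbation; the structural prior starts uniform.

Standard errors use the inverse of the empirical cross-product
(outer-product-of-gradients) information of the incomplete-data
log-likelihood, with per-respondent scores obtained through Fisher's
identity. The covariance spans all item blocks and the structural block
jointly; a pseudo-inverse with a warning replaces the inverse when the
information is singular. Structural λ standard errors reported from the
within-EM multinomial fit ignore classification uncertainty and are
documented as an approximation.

npar counts 2^{K_j} (saturated), K_j+1 (additive), or 2 (DINA/DINO)
parameters per item plus the structural free parameters (design columns
minus the normalization-fixed intercept); AIC = −2ℓ + 2·npar,
BIC = −2ℓ + npar·ln N.

## Q-matrix validation

For candidate q-vector **q**, the GDI is the weighted variance of the
item's class success probabilities after collapsing by **q**'s reduced
profiles; weights are the fitted structural class probabilities (not
posterior-averaged memberships). Class success probabilities are the
nonparametric posterior-weighted success rates per full class, i.e. the
saturated estimate the item would get under an all-attribute q-vector.
PVAF divides by the GDI of the all-attribute vector. The mesa search is
exhaustive over q-vectors (capped at K ≤ 12). Suggestions take the
smallest attribute count whose best PVAF reaches ε (default .95), breaking
ties by higher PVAF then lexicographic order, and are *advisory*: the
workflow applies them only when the user explicitly accepts specific items,
because empirical suggestions can be substantively unjustifiable.

## Model comparison

Item-level Wald tests express each reduced model as constraints on the
saturated item block: additivity is "all interaction contrasts zero" on the
candidate's link scale (rows of the inverse saturated design applied to the
link-transformed probabilities, delta-method covariance), DINA/DINO as
equality of their pooled groups. When several candidates survive at α, the
fewest-parameter one wins, then the largest p — parsimony first. The
selection on single-attribute items is skipped: all models coincide there.

M2 / RMSEA2 uses all univariate and bivariate endorsement margins (the "2"
limits the order), the model-implied margin covariance with exact overlap
corrections, and the optimal weight form Ξ⁻¹ − Ξ⁻¹Δ(Δ'Ξ⁻¹Δ)⁻¹Δ'Ξ⁻¹.
Degrees of freedom subtract the rank of the margin Jacobian, so
rank-deficient parameterizations do not inflate df; margins with negligible
model variance are dropped with a warning. RMSEA2 = √(max(M2−df,0)/(df·N)).

## Classification and lens analysis

MAP ties (exactly equal posterior mass) are broken toward fewer attributes,
then lexicographic order, and counted. The test-level accuracy index is
the mean posterior probability of each respondent's MAP profile; the
attribute-level index is the mean of max(p, 1−p) over EAP attribute
probabilities. "Estimated prevalence" is reported as the posterior-weighted
profile share (mean posterior probability per profile); the prior
probabilities are exported under a separate label, because the two differ
whenever the prior and the data disagree — notably under the independence
prior.

The lens analysis recomputes posteriors under the independence prior (the
product distribution with the prevalence prior's exact attribute marginals)
with item parameters fixed, and summarizes per-attribute differences by
RMSD. A product-form prevalence prior therefore yields RMSD ≡ 0. Jitter in
lens/scatter plots is seeded and applied only at render time.

## Synthetic data

The default scenario reproduces the structure of a published 40-item,
4-attribute mental-health inventory: 23 alcohol-problem items, 6 anxiety,
5 hostility, 6 depression, with five two-attribute items (21: AP+HO; 26,
27, 28: AN+DE; 29: AN+HO); item endorsement probabilities and the joint
profile prevalence are set to the published estimates (prevalences
renormalized to sum exactly to one). Respondent profiles are i.i.d.
categorical draws and responses conditionally independent Bernoulli — the
generator embodies the model's own assumptions. It does not emulate
features of real data such as local item dependence, ordinal response
scales before dichotomization, missingness, or respondent heterogeneity
beyond the 2^K classes, so passing recovery tests demonstrates correctness
of the estimator under the model, not robustness to violations of it.

## Problem sizes and tolerances in the test suite

Recovery checks use one N = 3000 draw with a fixed seed (item-probability
RMSE ≤ .05, joint total-variation ≤ .05; both hold with large margin).
Wald calibration uses 200 replicates at N = 5000 with an additive
two-attribute item (rejection within 4 points of the nominal 5%);
true-model selection uses 3 replicates × 5 reduced forms at N = 5000
(≥ 70% correct). The EM-vs-direct oracle uses K = 2, J = 4, N = 200 with
an analytic-gradient L-BFGS maximizer of the marginal likelihood and
agreement within 1e-3. The acceptance script re-runs the full pipeline at
N = 3000.

## Known limitations

- Polytomous (sequential) response models, attribute hierarchies,
  missing-data EM, and covariate-dependent structural models are out of
  scope; dichotomization is fixed at "any non-zero response".
- OPG standard errors are first-order; no sandwich or supplemented-EM
  variants.
- The poset monotone projection is a heuristic pooling scheme, exact on
  chains and on the K_j ≤ 2 diamond in practice, with a guaranteed-feasible
  fallback; it is not the exact constrained MLE for K_j ≥ 3 in all corner
  cases.
- Structural λ standard errors understate uncertainty because the expected
  class counts are treated as observed.
- EM finds local maxima; the deterministic initialization plus seeded
  perturbation makes runs reproducible but multi-start is left to the user.
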