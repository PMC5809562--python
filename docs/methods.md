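# Methods

`hmpt` fits hierarchical multinomial processing tree (MPT) models. This
note documents the statistical models, the sampler, the numerical
choices, and what the synthetic-data experiments in the test suite do and
do not establish.

## The MPT likelihood

An MPT model maps a parameter vector θ ∈ [0,1]^S to category
probabilities through branch polynomials,

    P(B_ik | θ) = c_ik · ∏_s θ_s^{a_iks} (1 − θ_s)^{b_iks},
    P(C_k | θ)  = Σ_i P(B_ik | θ),

where a_iks and b_iks count occurrences of θ_s and (1 − θ_s) on branch i
of category k and c_ik collects numeric constants. Responses are
product-multinomial: one independent multinomial per tree. Models are read
from EQN text files (first line ignored as a comment; each following line
is `tree category equation`), and equality/constant restrictions collapse
or fix parameters before fitting. For evaluation the model is compiled
into exponent matrices so category probabilities for a whole
participant-by-parameter matrix are two matrix products in log space.
Before taking logarithms, θ is clipped to [1e-9, 1 − 1e-9]; this keeps
the log-likelihood finite for boundary proposals while perturbing
probabilities below sampler resolution.

## Hierarchical population models

Both hierarchical models give every participant p their own parameter
vector θ_p and shrink the individual estimates toward the group
("partial pooling").

**Beta-MPT.** θ_ps ~ Beta(α_s, β_s) independently per parameter. Group
location and spread are reported through the beta moments
E = α/(α+β) and Var = αβ/((α+β+1)(α+β)²). Hyperpriors: α_s, β_s ~
Gamma(shape 1, rate 0.1), which is uniform on the implied group mean and
weakly informative on the group SD. The inverse moment map (mean, sd) →
(α, β) used by the generator requires sd² < mean(1 − mean) (no beta
distribution is more dispersed than the matching Bernoulli).

**Latent-trait MPT.** Probit-transformed parameters are multivariate
normal:

    Φ⁻¹(θ_p) = μ + X_p β + δ_p,   δ_p ~ MVN(0, Σ),

with a scaled inverse-Wishart prior Σ = diag(ξ) Q diag(ξ),
Q ~ InvWishart(V = I_S, df = S + 1), ξ_s ~ Uniform[0, 10], and
μ_s ~ Normal(0, 1), which implies uniform group means Φ(μ_s) on the
probability scale. Normal priors are configured as (mean, sd); BUGS-style
precision notation such as `dnorm(0, 4)` corresponds to sd = 0.5.

Predictors enter the linear term X_p β on the probit scale:

* continuous covariates are z-standardized (population SD) and their
  standardized slopes share a per-parameter variance,
  β_sk ~ Normal(0, g_s), g_s ~ InverseGamma(1/2, v²/2) with v = 1 —
  jointly a multivariate Cauchy prior. Unstandardized slopes
  β/sd(covariate) are reported alongside. Setting `fix_g=True` freezes
  g_s = 1 (plain normal slopes); `v_slope` changes the Cauchy scale.
* fixed factors are sum-to-zero coded with L − 1 columns (the omitted
  level's effect is minus the sum of the others);
* random factors are indicator-coded with L exchangeable columns sharing
  one variance g with the same inverse-χ²(1) prior.

With no predictors the regression model reduces *exactly* to the plain
latent-trait model (verified as a code-path identity test).

## The sampler

The full hierarchical model is sampled by a Metropolis-within-Gibbs scheme
written for this package (no external MCMC engine). Per sweep of the
latent-trait kernel:

1. **Latent probit values z_ps** (componentwise over parameters,
   vectorized over participants): a random-walk Metropolis step with a
   per-(p, s) adapted scale against the exact conditional normal prior
   z_ps | z_p,−s, followed by an independence proposal drawn *from* that
   conditional prior, whose acceptance ratio is the likelihood ratio
   alone. The independence step is what keeps weakly informed components
   (e.g., source memory d when item detection fails) mixing when the
   population SD is large.
2. **Funnel group moves** per parameter: (a) joint translation of
   (μ_s, z·s) — residuals unchanged, acceptance = likelihood ratio ×
   μ-prior ratio; (b) joint rescaling of the residual column at fixed Σ
   (Jacobian c^P); (c) joint rescaling of (ξ_s, residual column) by the
   same factor, for which the prior change and the Jacobian cancel so
   acceptance is the likelihood ratio alone; and (d) joint translation of
   (β_sk, z·s) along each design column. These moves traverse the
   hierarchical funnels that defeat purely componentwise updates; without
   them, σ_s for weakly informed parameters does not converge in
   realistic run lengths.
3. **Conjugate Gibbs blocks**: μ (multivariate normal), β_s (multivariate
   normal given the latent configuration), Q (inverse-Wishart on the
   ξ-standardized residuals), and g (inverse-gamma).
4. **ξ_s**: bounded random-walk Metropolis within [0, 10].

The beta-MPT kernel uses componentwise random-walk Metropolis on
logit(θ_ps) (Jacobian folded into the target) and on log α_s, log β_s.

**Adaptation.** Proposal log-scales follow Robbins–Monro steps
c/⌈i/50⌉ toward a 0.35 acceptance rate, only during burn-in; they are
frozen afterward, so the retained chain is Markov (asserted by a test).
Defaults: 20,000 iterations, 2,000 burn-in, thinning 5, 3 chains.
Per-chain generators derive from `SeedSequence(seed, spawn_key=(chain,))`,
so (seed, settings, kernel) fully determine the output. Convergence is
monitored by split-chain R̂ and an autocorrelation-based effective sample
size (truncated at the first negative pairwise sum); any R̂ ≥ 1.05
triggers a prominent warning, never a silent pass. `extend_run` continues
chains from their stored final states.

**Initialization.** Chains start from the pooled (summed-over-
participants) maximum-likelihood estimate of θ, found by a short
Nelder–Mead search on the logit scale, plus chain-specific noise; μ
starts at the probit of that estimate, Q at the identity, ξ at 1, slopes
at 0. A per-participant moment-matching start was considered but is not
well defined for general trees; the pooled start is cheap and
model-agnostic.

## Homogeneity tests

Fitting a hierarchical model is only warranted if participants are
actually heterogeneous. The χ² test pools category proportions per tree
and sums Pearson residuals over participants, trees and categories; df =
(P − 1) Σ_t (K_t − 1). (For the classic source-monitoring design of 24
participants and three 3-category trees this gives df = 138.) The
permutation test uses the same statistic but simulates its null by
permuting responses across participants independently within each item,
which preserves item effects and therefore stays valid under item
heterogeneity; the p value uses the add-one estimator. Item homogeneity
can be tested by transposing the roles of participants and items in the
long-format input.

## Goodness of fit and model comparison

Posterior-predictive checks use two discrepancy statistics: T1 compares
observed and expected *mean* frequencies in Pearson χ² form; T2 sums
|observed − expected covariance| / (sd_k · sd_l) over category pairs
k < l (off-diagonal only: the statistic targets co-variances; including
the variances would duplicate T1's role). Expected moments per posterior
draw are computed analytically from the multinomial mean/covariance
formulas given that draw's individual parameters — no nested simulation —
with the ddof = 1 convention on both the observed and the expected side
so that a well-specified model gives discrepancies centered at zero. The
PPP value is the share of draws with T_obs < T_pred; it is not uniform
under the true model, only bounded away from the extremes, which is what
the calibration test asserts.

DIC is computed with the *conditional* (individual-θ) likelihood focus:
D̄ + pD with pD = D̄ − D(θ̄). This matches what samplers reporting
individual-level deviance produce, but it penalizes weakly: for a barely
identified alternative (e.g., the unrestricted eight-parameter
source-monitoring model, which has more parameters than free categories)
conditional DIC can favor the larger model, because unidentified
flexibility lowers the mean deviance without raising conditional pD. The
selection test therefore uses an identified nested pair. Marginal-focus
DIC, WAIC and Bayes factors are out of scope.

## Post-fit analyses

* Transformed parameters (differences, ratios, any +−*/ expression) are
  evaluated per draw at the group level (probability-scale means Φ(μ_s))
  or per participant; draws hitting a division by zero are excluded with
  a reported count.
* `probit_inverse` maps a probit-scale normal (μ, σ) to the implied
  probability-scale mean and SD: the mean has the closed form
  Φ(μ/√(1+σ²)); the second moment is an 80-node Gauss–Hermite quadrature.
* Between-subjects comparisons evaluate a user statistic (default x − y)
  on index-paired draws from two independently fitted groups and report
  the one-sided Bayesian p value p_B = P(x < y).
* Covariate correlations are computed per draw between individual
  parameters (probability or probit scale) and each numeric covariate.
  The population-correlation posterior corrects for sampling error: for
  each draw of the sample correlation r, the exact sampling density of r
  given ρ and n (Gaussian hypergeometric form) is combined with a uniform
  prior on ρ over a 2001-point grid, and the per-draw posteriors are
  averaged. This reproduces the behavior of the published
  analytic-posterior procedure (wider than the spread of the r draws;
  collapsing as n grows) without importing its special-function closed
  form; agreement is validated qualitatively, not draw-for-draw.

## Synthetic data and the recovery study

`gen_mpt` draws one multinomial per participant and tree for a fixed θ
matrix. `gen_trait_mpt` draws probit values μ + xβ + δ_p with δ_p ~
MVN(0, diag(σ) R diag(σ)) and an optional standard-normal covariate;
`gen_beta_mpt` draws θ from independent betas matched to requested
moments. A converter from probability-scale (mean, SD) to probit (μ, σ)
inverts the `probit_inverse` moment map by 1-D root finding.

The bundled recovery design mirrors the standard simulation for the
restricted source-monitoring model: 50 participants, 16 items per source
tree and 32 new items; probit means (SDs) a = 0.3 (0.6), b = −0.1 (0.5),
d = 0.6 (1.0), and D = Φ⁻¹(0.62) ≈ 0.31 (0.2) — the D value is fixed by
the design's probability-scale group mean of 0.62; standardized slopes
β^D = −0.3 and β^d = 0.5 on one standard-normal covariate. Per
replication the harness generates data, fits the latent-trait model with
both slopes as continuous predictors, gates on R̂ < 1.05 (re-running with
doubled iterations up to three times, then excluding), and aggregates
posterior means, mean 95% CI bounds, absolute bias, CI coverage, and the
zero-exclusion rate of the slopes.

**Problem sizes.** The package runs this study at 22 replications with
3,000-iteration, 2-chain fits in `scripts/acceptance.py` (10
replications inside the test suite), a size at which the replication
mean of each recovered quantity is stable to about one Monte-Carlo
standard error of a few hundredths; comparisons are made within three
such standard errors. Full-size runs (hundreds of replications, the
20,000-iteration default) are a matter of passing larger `--replications`
and `McmcSettings` values.

**What the synthetic experiments do not show.** The generator draws
exactly from the fitted models' assumed populations (probit-normal or
beta, homogeneous items, no response omissions, known tree structure), so
recovery and calibration results certify the implementation, not the
models' adequacy for any real data set. Item heterogeneity, participant
dropout, and misspecified trees are outside the generator; only the
permutation test's long-format path touches item-level structure.

## Known limitations

* No gradient-based samplers; very large models (S ≫ 10) will mix slowly.
* No crossed participant × item random effects.
* No Bayes-factor model selection; only credible intervals, p_B, PPP and
  conditional-focus DIC.
* The beta-MPT assumes independent parameters; correlations estimated
  from its posterior are prior-dominated in small samples.
* The "zeros-trick" approximately-uniform prior on the beta-MPT group
  moments is not implemented (known to destabilize samplers); a
  reparameterized uniform-on-(mean, SD) prior is possible future work.
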