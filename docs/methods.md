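# Methods

## Model

Paired counts (Y₁ᵢ, Y₂ᵢ), i = 1…n, are modelled as bivariate zero-inflated
Poisson (BZIP): with probability P₀ the pair is a structural zero (0, 0);
otherwise it comes from a bivariate Poisson (BP) distribution built by
trivariate reduction, Y₁ = Z₁ + Z₃, Y₂ = Z₂ + Z₃ with independent Poisson
latents.  The BP pmf is

    f_BP(y₁, y₂) = e^{−(λ₁+λ₂+λ₃)} (λ₁^{y₁}/y₁!)(λ₂^{y₂}/y₂!)
                   Σ_{k=0}^{min(y₁,y₂)} C(y₁,k) C(y₂,k) k! (λ₃/λ₁λ₂)^k,

with marginals Poisson(λₖ+λ₃) and Cov = λ₃.  The BZIP moments are
E(Yₖ) = (1−P₀)(λₖ+λ₃), Var(Yₖ) = E(Yₖ)[1+P₀(λₖ+λ₃)] (overdispersed
whenever P₀ > 0), and Cov(Y₁,Y₂) = (1−P₀)[λ₃ + P₀(λ₁+λ₃)(λ₂+λ₃)] — note
that zero inflation itself induces positive correlation even at λ₃ = 0.

Regression enters through log links, log λ₁ᵢ = xᵢ'β and log λ₂ᵢ = xᵢ'γ,
with one shared design matrix; λ₃ = exp(α) and P₀ are scalars (no covariate
link on either — the fitted model of the motivating study; a logit link on
P₀ is a possible extension, deliberately out of scope).  Priors are
independent: N(0, 1000) on every coefficient and on α ("variance" means
variance, not precision — SD ≈ 31.6), Uniform(0, 1) on P₀.

The comparator families are restrictions: univariate Poisson regression per
response (no P₀, no λ₃), univariate ZIP per response (own scalar
zero-inflation mass), and BP (P₀ = 0).  Two independently fitted univariate
models are scored jointly by summing their (p_D, D̄, DIC) component-wise.

## Numerics

All pmfs are evaluated in log space: log-factorials via `gammaln`, the
inner k-sum via log-sum-exp, the (0, 0) mixture cell via
logaddexp(log P₀, log(1−P₀) − λ).  This keeps rates up to ~50 and counts up
to ~200 finite.  At λ₃ = 0 only the k = 0 term is used, so the pmf reduces
*exactly* to a product of Poissons with no 0⁰ ambiguity.  Linear predictors
are clipped at |η| ≤ 700 before exponentiation (with a logged warning);
clipping at the largest representable exponent means the guard is inactive
anywhere the posterior has appreciable mass.  Oracle tests truncate grids
at mean + 12 SD of each marginal (plus a floor of 15 for sub-unit rates),
bounding the ignored tail mass below the test tolerances.

Random generation uses the trivariate-reduction construction directly
(three Poisson draws per pair, a Bernoulli(P₀) mask for structural zeros):
exact, cheap, and identical to the model's own definition.

## Posterior simulation

The sampler is random-walk Metropolis-within-Gibbs on an unconstrained
scale: β and γ are updated as blocks with multivariate normal proposals,
α and logit(P₀) as scalars (the logit transform's Jacobian is included in
the target).  Design choices:

- **Preconditioning.**  Coefficient-block proposals start from the inverse
  Fisher information of a constant-rate Poisson fit, inv(ȳ·X'X).  Log-link
  coefficient posteriors have scales spanning two orders of magnitude
  (an intercept vs. a coefficient on a covariate with SD 10); an identity
  proposal shape mixes far too slowly to be usable.
- **Adaptation during burn-in only.**  Every `adapt_window` (default 100)
  iterations the scalar step size moves toward a 20–45% acceptance rate,
  and block proposal shapes are refreshed from the burn-in sample
  covariance.  Everything is frozen at the end of burn-in, so the retained
  chain is a genuine Markov chain and ergodicity is untouched.
- **Starts.**  Chain 1 starts at data-informed values (log mean counts for
  the intercepts, zeros elsewhere, P₀ at the observed (0,0) fraction);
  later chains add a jitter of 4 proposal SDs per block.  Jittering in the
  preconditioned space makes the starts overdispersed relative to the
  posterior — required for the Gelman–Rubin diagnostic to mean anything —
  without flinging small-scale coefficients hundreds of posterior SDs away.
- **Protocol.**  Paper-faithful defaults: 2 chains, 5000 burn-in, 30000
  post-burn-in iterations, every 20th draw kept.  The CLI and the test
  suite default to scaled-down protocols (2 × (1000 + 2000), thin 5, and
  similar); all chain lengths are explicit `ChainConfig` fields.

Diagnostics: the corrected (df-adjusted) Gelman–Rubin PSRF, with "close to
one" operationalised as < 1.1; batch-means MC error (⌈√N⌉ batches per
chain) with the rule MC error < 0.1 × posterior SD; per-chain-averaged
autocorrelation.  Summaries (mean, median, SD, equal-tailed 95% interval)
pool chains after thinning; derived quantities (λ₃ = e^α, plug-in
correlations) are always computed per draw and then summarised, never by
transforming summaries.

A practical note on α = log λ₃: when the data carry little information
about λ₃, the posterior of α develops a long flat left tail (any
sufficiently negative α means "λ₃ ≈ 0" and fits equally well; the
motivating study's own λ₃ interval reaches ~10⁻³²).  Chains wander in that
tail, so α itself fails strict PSRF/MC-error rules that λ₃ = e^α passes
easily.  Convergence checks therefore belong on the monitored λ₃ scale,
which is also what the summary tables report.

## DIC

Deviance D(θ) = −2 log L includes all normalising constants (the y! terms),
so DIC values are comparable across families on the same data.
D̄ averages D over retained draws; p_D = D̄ − D(θ̄) plugs in the posterior
mean of each parameter on its sampling scale (coefficients and α as-is, P₀
on (0,1)), matching common practice in general-purpose Gibbs samplers.
With a strongly skewed α this plug-in can land outside the posterior bulk
and make p_D negative — a known DIC pathology; the package warns and
reports it rather than failing.  Ties in the comparison table break
lexicographically by model label.

## Synthetic data

The generator emulates the blood-donation study the model was built for:
n = 864 subjects; covariates sex, centered weight, centered age, marital
status, a 4-level education factor and a 5-level job factor
(reference-coded to 11 design columns — the count implied by the study's
own coefficient table); BZIP responses at per-subject log-link rates.
Generating coefficients sit at the study's reported posterior means;
P₀ = 0.43; λ₃ = 0.05 by default (small but estimable — the study's own
fitted λ₃ ≈ 2·10⁻⁴ is provided as `table_faithful_scenario`, but makes
dependence-recovery tests degenerate).

The covariate marginal distributions are *not* reported anywhere, so they
are stand-ins: Bernoulli(0.8) sex, Bernoulli(0.4) marital, N(0, 10²)
weight, N(0, 8²) age, categorical probabilities (0.50, 0.25, 0.15, 0.10)
for education and (0.04, 0.22, 0.28, 0.28, 0.18) for job.  They were chosen
once so that the realized summary statistics of a default dataset match the
study's reported ones — zero fractions near 0.51 (Y₁) and 0.85 (Y₂), joint
zeros near 0.48, positive rank correlation (realized ≈ 0.33 vs. reported
0.276) — and are configurable.  `make_study_like` enforces bands around
those targets (±0.06 on zero fractions, covering binomial noise at n = 864
plus the mismatch from rounded published coefficients) and regenerates with
an incremented seed, at most 10 times, if a draw falls outside.

What passing tests on this data do and do not show: they validate the
estimation machinery (likelihood, sampler, diagnostics, DIC) under the
model's own generative assumptions at the study's size and zero-inflation
level.  They cannot validate the covariate distributions, the absence of
overdispersion beyond zero inflation, follow-up-time effects, or anything
else about the real clinical data, which the generator does not attempt to
reproduce at the individual level.

## Problem sizes in the test and acceptance runs

Stochastic checks are scaled to desk hardware: credible-interval coverage
uses 20 intercept-only refits at n = 864 (2 × (400 + 800) iterations,
thin 4); DIC-ordering uses 10 replicates at n = 400 with six model fits
each; full-regression recovery uses one n = 864 fit at 2 × (1500 + 3000),
thin 5.  The acceptance script uses comparable sizes and finishes in about
a minute.  Longer, paper-protocol runs tighten the diagnostics but do not
change any qualitative conclusion.

## Known limitations

- The BP construction only produces non-negative dependence (λ₃ ≥ 0);
  negatively correlated pairs need a different family.
- P₀ and λ₃ are scalars; covariate-dependent zero inflation or covariance
  is not implemented.
- No offsets/exposure terms; counts are modelled as totals over a common
  window.
- DIC is the only comparison criterion (no WAIC/LOO), mirroring the
  analysis the package reproduces.
- The random-walk sampler is robust but not fast; 26-parameter fits at
  n = 864 take tens of seconds per thousand iterations.  Gradient-based
  samplers are out of scope.
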