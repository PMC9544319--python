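# Methods

## The model

`robustmeta` implements a Bayesian random effects meta-analysis for
binary outcomes in which each study's effect variance is inflated by a
*study quality* term, and in which that quality term is allowed to be
*set-valued* rather than precise. For K two-arm studies with responder
counts r_ij out of N_ij patients (j = 1 control, j = 2 treatment):

    r_ij | p_ij          ~ Binomial(N_ij, p_ij)
    logit(p_i1) = β_i
    logit(p_i2) = β_i + δ_i
    δ_i | μ, σ²_θ        ~ Normal(μ, σ²_θ / q_i)
    β_i ~ Normal(μ_β, σ²_β),  μ ~ Normal(μ_μ, σ²_μ),  σ²_θ ~ InvGamma(α, λ)

δ_i is the study-specific log odds ratio; μ is the overall effect (the
estimand). The variance of δ_i decomposes as between-study
heterogeneity σ²_θ plus the variance σ²_φi of an additive
study-specific error representing bias from design or execution. The
quality term

    q_i = σ²_θ / (σ²_θ + σ²_φi)  ∈  (0, 1]

is the fraction of a study's total effect variance attributable to
genuine heterogeneity: q_i = 1 means no bias (the model reduces to the
ordinary random effects model), q_i = 0.5 means bias variance equal to
heterogeneity, and small q_i effectively down-weights the study. The
random effect and error are marginalized analytically; only
(β, δ, μ, σ²_θ) are sampled.

Quality terms are treated as *fixed but unknown* quantities that the
analysis deliberately does not learn from data — they encode external
qualitative knowledge about study conduct. Ignorance about them is
represented by a set ℳ of admissible quality vectors; Bayesian updating
is carried out for every q ∈ (a discretization of) ℳ, and uncertainty
in μ is summarized by lower/upper envelopes (robust Bayes bounds) of
each posterior summary: the posterior mean of μ, its percentiles, and
the exceedance probability P(μ > t) for a decision threshold t.

## From risk-of-bias ratings to the quality set

The Cochrane risk-of-bias instrument rates each study low / unclear /
high on six bias domains. For a single domain, ℳ is built by rules:

1. Studies with the same clear rating share one quality value (one
   *group* per clear category).
2. The low-risk group ranges over [0.5, 0.95]; the high-risk group over
   [0.1, 0.5].
3. Each unclear study gets its own free quality, bounded below by the
   high-category lower cut-off (0.1) and above by the low-category
   upper cut-off (0.95), and ordered between the high and low groups
   when those exist.

The cut-offs (0.1, 0.5, 0.95) are deliberately conservative defaults:
0.5 is the midpoint linking the low- and high-risk categories, 0.95
leaves residual doubt even for well-conducted studies, and 0.1 (rather
than 0) keeps the bias variance finite. They are configurable
(`CategoryBounds`). Cross-domain combinations require an explicit
user-supplied specification of groups and order relations, because no
defensible automatic scoring rule exists for aggregating domains.

ℳ is then a polytope of restricted shape: per-group interval bounds
plus pairwise order constraints. Two discretizations are provided:

* **box grid** — when there are no order constraints, the Cartesian
  product of equally spaced values per group (endpoints included);
* **extreme points + simplex lattice** — otherwise, the polytope's
  vertices are enumerated and the grid is the set of convex
  combinations with lattice weights (all weight vectors with
  components in {0, 1/s, …, 1} summing to 1).

Vertex enumeration assigns each group one of the interval endpoint
values (its own or a neighbor's, as propagated along order
constraints), keeps feasible assignments, and retains exactly those
whose active constraints have full rank — genuine vertices rather than
face interiors. This is sound for interval-plus-pairwise-order systems
because every vertex solves a square subsystem of bound and order
equalities, so every vertex coordinate is an interval endpoint
propagated along tight order chains; it is not a general-purpose
vertex enumerator.

All grid construction uses exact rational arithmetic (stdlib
`fractions`, scaled-integer dot products): vertex coordinates are exact
rationals, weights are exact multiples of 1/s, and duplicate grid
points are removed by exact equality. Grid sizes are therefore
reproducible across platforms and independent of floating-point
summation order; published grid sizes for this kind of construction
produced by double-precision pipelines can differ from the exact
counts in either direction (floating-point artifacts both split
mathematically equal points and silently drop weight combinations).

## Posterior computation

Sampling is Metropolis-within-Gibbs. μ and σ²_θ have exact conjugate
full conditionals,

    μ  | ·  ~ Normal(m, 1/τ),   τ = 1/σ²_μ + Σ_i q_i/σ²_θ,
                                m = (μ_μ/σ²_μ + Σ_i q_i δ_i/σ²_θ)/τ
    σ²_θ | · ~ InvGamma(α + K/2, λ + Σ_i q_i (δ_i − μ)²/2),

which removes all tuning for the variance component. Each β_i and δ_i
is updated by a Gaussian random walk whose scale adapts in batches of
50 iterations toward 0.44 acceptance (diminishing adaptation, frozen
after burn-in, so the post-burn-in chain is a genuine Markov chain).
Chains run vectorized; the β updates are mutually independent given
(δ, μ, σ²_θ) because the binomial likelihood factorizes by study, and
likewise for δ, so all K proposals are accepted/rejected in parallel.

Defaults: 4 chains × 10,000 kept iterations after 5,000 burn-in,
thinning 1. Sweeps may reduce per-point effort (the bound envelope is
insensitive to per-point Monte-Carlo error at interior points); an
optional refine pass re-fits only the arg-min/arg-max points at full
effort, since the extremes deserve the smallest Monte-Carlo error.
Convergence is monitored by split-chain R̂ on μ and log σ²_θ (flagged
above 1.01) and bulk effective sample size (arviz); a non-converged fit
flags its record but never aborts a sweep.

Randomness is keyed by (seed, quality vector): each grid point derives
its generator from the base seed plus an integer encoding of q. Two
consequences: sweep results are independent of evaluation order and of
parallelism, and grids that share points (e.g. a coarse box grid nested
in a finer one) reuse *identical* draws at shared points, which makes
the set-monotonicity of bound intervals (larger grid ⇒ wider or equal
interval) hold exactly rather than up to noise.

Percentiles use linear interpolation between order statistics of the
pooled draws; the exceedance probability is the pooled fraction of
draws above t. All computation is on the log-odds-ratio scale; t
defaults to 0 (no effect) and is set per analysis.

## Synthetic data

`simulate` runs the model generatively: given true (μ, σ²_θ, q, β), it
draws δ_i ~ Normal(μ, σ²_θ/q_i) and binomial counts at the implied
response probabilities. By default β_i is drawn from its Normal(0, 10²)
prior truncated to [−4, 4]; untruncated draws routinely yield 0/N or
N/N arms, which are unrealistic and break empirical display statistics.
The generator emulates exactly the fitted model — it shares its
assumptions (no correlation between trials of a study, bias acting only
through symmetric variance inflation, exchangeable studies), so
parameter-recovery tests validate the inference machinery, not the
model's adequacy for any real meta-analysis. The latent truth is
returned (and optionally written as sidecar JSON) for test harnesses.

## Numerical and design choices

* Binomial log-likelihoods are computed via `r·x − N·log(1+eˣ)` with
  `logaddexp` for overflow safety; the log posterior includes all
  normalizing constants so it agrees term-by-term with scipy densities.
* σ²_θ ≤ 0 yields −∞ log posterior (rejected region), not an exception.
* Bound extraction breaks ties by first occurrence in grid order;
  grids are emitted in deterministic lexicographic order.
* The empirical per-study log-OR (display only — never used by the
  model) applies the Haldane–Anscombe 0.5 correction to all four cells
  when any cell is zero.
* Infeasible constraint systems (an interval emptied by order
  propagation) and cyclic order relations are rejected with the
  offending groups named, before any sampling starts.
* Long sweeps can checkpoint finished grid points to a JSON-lines file
  and resume after interruption.
* Forest plots export both the classical log-OR interval and the
  posterior δ_i interval for each study, since both conventions are
  used in practice; robust runs add whiskers for the bound range of
  E(μ) and the outer percentile bounds.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the four-study Rituximab
example end to end: single fits use 4 chains × 10,000 kept draws;
equal-quality sweeps use the full 10-point grid at the same effort; the
all-unclear box (10⁴ points at full resolution) is exercised at 3 and 5
points per axis (81 and 625 fits at 1 chain × 1,500 kept draws), which
suffices to check bound containment and exact grid-refinement
monotonicity. Parameter recovery uses 20 replicates of K = 20 studies
with 500 patients per arm.

## Known limitations

* Bias enters only through symmetric variance inflation; directional
  (mean-shift) bias is not modeled.
* The bounds are grid approximations: they under-cover ℳ from inside,
  and each endpoint inherits the Monte-Carlo error of one MCMC fit —
  extremes over many noisy fits are biased outward, which the refine
  pass mitigates but does not remove.
* The constraint language covers interval bounds, equality groups and
  pairwise orders only — not general linear inequalities.
* Only three risk categories are supported; other appraisal instruments
  need case-by-case mapping.
* With very few studies (K < 3) the between-study variance is driven
  almost entirely by its prior; reports warn but do not refuse.
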