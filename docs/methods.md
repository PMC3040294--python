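# Methods

## Data model

One row per area: an observed count y ≥ 0 and an expected count e > 0
produced by indirect standardization (reference age-specific rates applied to
the area's population), so the implicit null is RR = 1 in every area.
Standardization itself is out of scope — inputs arrive pre-standardized.
Row order of the area table is the canonical ordering; every per-area vector
in the package (p-values, posterior probabilities, truth) aligns to it, and
adjacency structures are re-indexed against it on use.

Adjacency is a symmetric neighbour-set map with no self-loops, read either
from a two-column edge list (symmetrized) or from positional `num`/`adj`
vectors (1-based positions in table order; asymmetry in this dialect is an
error because it encodes both directions explicitly). Neighbourless areas
("islands") are legal in the data model; their treatment is a sampler
decision (below). `validate_map` reports islands, connected components and
id mismatches without mutating anything.

## Frequentist screen

Per-area p-values come from the exact Poisson distribution of Y under
H₀: θ = 1 (no normal approximation): upper tail P(Y ≥ y), lower tail
P(Y ≤ y), and a two-sided value by the doubling rule min(1, 2·min(tails)).
Doubling is chosen over the minimum-likelihood construction because it is
monotone in each tail and simple to invert; at small e it is conservative
(the suite asserts p-values on null maps are stochastically ≥ uniform, and
approach uniformity when expected counts are in the hundreds).

Multiplicity procedures: Bonferroni (p ≤ α/m), the BH step-up with threshold
(k/m)·level/π₀ (π₀ = 1 gives plain BH), Storey's fixed-λ estimator
π̂₀ = #{p > λ}/((1−λ)m) capped at 1 (default λ = 0.5; the spline-smoothed
variant is out of scope), and q-values q₍ᵢ₎ = min_{k≥i} π̂₀·m·p₍ₖ₎/k. The
exceedance count in π̂₀ is floored at one so the estimate stays positive;
the floor only binds when no p-value exceeds λ. Thresholding q-values at γ
rejects exactly the adaptive BH(γ, π̂₀) set; this equivalence is asserted
property-style over random p-vectors. Ties in step-up procedures are
resolved by p-value, never by input index.

Funnel limits plot SMR against precision (= e). At each grid point the
limits are conservative discrete quantiles: the largest y_l with
P(Y ≤ y_l) ≤ α/2 and the smallest y_u with P(Y ≥ y_u) ≤ α/2, divided by e,
so coverage is ≥ nominal (no randomized tests, matching surveillance
practice). Because the support is discrete, the limit curves are only
monotone up to one count: tests assert narrowing within a 1/e granularity
rather than exactly. When a q-value threshold is supplied, the
multiplicity-adjusted band uses the implied per-test cut-off — the largest
observed p with q at or below the threshold — which is data-dependent, so
the returned object records which rule produced each curve. If nothing is
rejected at the threshold the band degenerates to (0, ∞).

## Tri-level mixture model

Level 1: Y_i ~ Poisson(E_i θ_i). Level 2: log θ_i = r_i μ₀ + (1−r_i) μ₁ᵢ
with an exact point mass at μ₀ = 0 (no narrow-slab approximation) and the
alternative component either PG (exp(μ₁ᵢ) ~ Gamma(k, ν)) or BYM
(μ₁ᵢ = u_i + v_i). Level 3: r_i ~ Bernoulli(π_i), π_i ~ Beta(c, d).

Defaults, units and rationale:

| parameter | default | meaning |
|---|---|---|
| c, d | 9.7, 0.3 | Beta hyperprior on π (probability scale); mean 0.97 encodes ≈3% divergent areas |
| π sharing | area-specific | exchangeable π_i; a single common π is available as `pi_sharing="common"` |
| k, ν hyperpriors | Exp(0.1) each | weakly informative, positive support; rates configurable |
| λ_u, λ_v hyperprior | Gamma(0.5, 0.0005) | a long-standing weakly-informative choice for log-scale random-effect precisions |
| chains / burn-in / stored | 2 / 100 000 / 1 000 | long burn-in default; test-scale analyses use 2 × 2 000/2 000 and verify PSRF instead |

The exact hyperprior rates are conventions, not estimates; `beta_prior_summary`
reports the prior mean and percentiles of any Beta(c, d) so the null-mass
belief can be elicited explicitly, and `sensitivity_sweep` refits under a
list of (c, d) pairs with a shared seed and returns ordered classification
probabilities for Q-Q comparison plus a Spearman rank correlation (the
correlation is an added scalar summary, not part of the classical display).

### Sampler

Metropolis-within-Gibbs; all mixture odds on the log scale.

* **r_i**: two-point full conditional with odds
  π_i·Pois(y_i | e_i e^{μ₀}) : (1−π_i)·Pois(y_i | e_i e^{μ₁ᵢ}). No
  trans-dimensional machinery is needed because the alternative parameters
  persist while an area sits at the null; they are refreshed from their
  prior/full conditional there, keeping the chain irreducible.
* **π_i**: conjugate Beta(c + r_i, d + 1 − r_i) (or Beta(c + Σr, d + m − Σr)
  in common mode).
* **PG, exp(μ₁ᵢ)**: conjugate Gamma(k + y_i, ν + e_i) where r_i = 0, prior
  draw Gamma(k, ν) where r_i = 1.
* **PG hyper level**, partially collapsed: (k, ν) are updated given the
  *active* areas' θ₁ only. The null areas' θ₁ are pure prior draws, and
  conditioning on a few hundred of them pins the hyper conditional to the
  current sample statistics, stalling mixing; marginalizing them out (then
  redrawing them from the new prior) is a valid partially-collapsed Gibbs
  scan and removes the bottleneck. Within the update, ν | k is conjugate
  Gamma(1 + n_active·k, ν-rate + Σθ₁) under its exponential hyperprior and
  is drawn exactly; k moves by random-walk Metropolis on the log scale,
  supplemented by a joint rescaling move (k, ν) → (ak, aν) because the two
  are strongly correlated along a posterior ridge. Five refreshes per sweep
  are essentially free (the sufficient statistics are fixed within a sweep).
  Together these keep Gelman–Rubin statistics of all monitored scalars near
  1.00 at the 2 × 2 000 test-scale settings, where a pure componentwise
  random walk did not mix reliably.
* **BYM, u**: conditionally independent across areas; random-walk Metropolis
  against the Poisson likelihood where r_i = 0, exact N(0, λ_u⁻¹) draw where
  the likelihood is inactive.
* **BYM, v**: the ICAR full conditional of v_i is
  N(mean of neighbours, (λ_v n_i)⁻¹). Components are updated over a greedy
  graph colouring: within a colour class no two areas are neighbours, so the
  whole class updates simultaneously (vectorized) while each conditional
  sees fixed neighbours — a valid Gibbs scan. Metropolis where the
  likelihood is active, exact conditional draws where it is not. After each
  sweep the mean of v over non-island areas is transferred into u
  (v ← v − v̄, u ← u + v̄), imposing the ICAR sum-to-zero constraint without
  touching u + v, hence without perturbing the likelihood. Islands keep
  v_i = 0 (their ICAR conditional is improper) with a warning at fit time;
  u_i absorbs their heterogeneity.
* **λ_u**: conjugate Gamma(a + m/2, b + Σu²/2). **λ_v**: conjugate
  Gamma(a + rank/2, b + ½Σ_{i∼j}(v_i−v_j)²) with rank = (non-island areas) −
  (connected components), the rank of the intrinsic precision.
* Random-walk scales adapt in batches toward 0.44 acceptance during burn-in
  only, then freeze, so the recorded chains satisfy detailed balance.

Chains receive independent child seeds spawned from the configured seed; the
full draw store is bit-reproducible and invariant (up to floating-point
summation order) under chain relabelling. Credible intervals use ECDF
(inverted-CDF) quantiles, which are exactly invariant under pooling
duplicate chains.

Classification probabilities are across-draw means of r_i pooled over
chains; the posterior functional reported as "classification" is the mean of
r_i, while the mean of π_i is exposed separately (`pi_mean`). Convergence is
summarized by the classic (non-split) Gelman–Rubin PSRF on monitored scalars
(k, ν or λ_u, λ_v, Σr, mean μ₁), floored at 1 since values below 1 are
estimation noise, plus Geyer initial-monotone effective sample sizes.

### Validation oracles

The kernels are checked against closed forms rather than other MCMC codes:
with the null disabled and (k, ν) fixed the PG posterior is exactly
Gamma(k + y, ν + e) per area (mean and variance asserted, with a
simultaneity allowance of one 3-SE exceedance across 50 areas — a correct
kernel produces one such exceedance about half the time); in prior-only mode
the long-run mean of π must return c/(c+d); the ICAR conditional moments are
verified on a path graph by direct sampling.

## Synthetic maps

The generator emulates a regional mortality register at desk scale: a
17 × 17 rook-contiguity lattice minus 2 cells (287 areas, neighbour counts
2–4), expected counts log-uniform on [0.5, 200] (heavy mass on small areas,
reproducing the wide-mouthed funnel geometry of real municipal data; the
range is configurable), a truly divergent fraction of 3% by default, and
two-sided fixed-RR effects (half the divergent areas at RR, half at 1/RR).
`effect_model="cluster"` instead grows one contiguous divergent patch
breadth-first from a random lattice cell, to exercise the spatially
structured alternative; `"lognormal"` draws dispersed effects around the
null. Truth uses the convention r_i = 1 for null areas, whose θ_i is exactly 1.

What the generator does **not** emulate: real municipal geography and
population sizes, age-structure effects (expected counts are drawn, not
standardized), covariate-driven risk gradients, and spatial correlation
*within* the null component. Passing tests therefore demonstrate
correctness of the procedures under an idealized Poisson world, not
performance guarantees on any particular registry.

`evaluate_fdp` scores flags against truth (V, R, FDP = V/R with FDP = 0 when
R = 0, sensitivity), and `replicate_study` repeats generate → test → score
over independently seeded maps, reporting mean FDP with its Monte-Carlo
standard error.

## Problem sizes and numerical choices

Test-scale analyses use 287 areas, 2 chains × 2 000 burn-in + 2 000 stored
draws (thin 1) for the mixture fits, 200 replicates for the FDR-control
simulation, 500 vectors for the q/BH equivalence property, and 2 × 10⁵
draws for conditional-moment oracles; these sizes keep the full suite and
the reproduction script to a few minutes while leaving Monte-Carlo error
well inside the asserted tolerances. Degenerate inputs are handled
explicitly: empty p-value lists, π̂₀ = 0 (floored), q-bands with no
rejections (band → (0, ∞)), islands (v pinned at 0), p = 0 in log Q-Q
transforms (capped with a warning), and undefined specific agreement when
neither procedure flags anything (an error in the library, `null` in
pipeline output).

## Known limitations

* The two-sided exact p-value uses the doubling rule; the
  minimum-likelihood two-sided construction is not implemented.
* Storey's π̂₀ uses a single fixed λ; with only a few hundred tests the
  estimate is noisy (often capped at 1), which is precisely the regime the
  informative Bayesian hyperprior is designed for.
* The BYM variant shares one Gamma hyperprior setting for both precisions;
  alternative spatial priors (Leroux, proper CAR) and model comparison
  (DIC/WAIC) are out of scope, as is decision analysis with loss functions.
* Funnel limit curves are step functions of the discrete support; plotting
  them as smooth lines overstates their resolution at small e.
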