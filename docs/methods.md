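# Methods

## Model

The simulator couples two deterministic-plus-stochastic processes on an
n × n lattice of lanes (rows: cities V, columns: visiting orders k).

**Controller.** The bounceback rule illuminates lanes whose growth would
violate TSP constraints. Each iteration it computes, from an observed
occupancy vector X (optionally noise-perturbed), the conflict input
u_Vk = Σ_Ul W_{Vk,Ul}·σ_{35,0.6}(X_Ul) and sets L_Vk = 1 −
σ_{1000,−0.5}(u_Vk). Because the outer sigmoid is effectively a step, the
binarized pattern is equivalent to the rule "illuminate iff u < θ", with
θ = −0.5. The inner sigmoid (gain 35, threshold 0.6) makes only
substantially grown branches exert inhibition. All lanes update
synchronously from the same snapshot; the update never mutates the state.

**Branch dynamics.** Occupancies start at 0. Per iteration, in this
order: (1) the observation is formed (X plus i.i.d. uniform noise on
[−d, d] when d > 0 — the noise enters only the controller's view, never
the stored state); (2) illumination is computed and binarized at 0.5
(strict); (3) every illuminated lane loses Δout, clamped at 0, the
withdrawn resource destroyed; (4) a constant inflow Δin is deposited into
the non-illuminated lanes, clamped at 1 with excess destroyed, and
extinguished entirely if every lane is lit; (5) the iteration counter
advances. The observe-first order means the controller always reacts to
the previous iteration's completed state; tests pin this order.

Two inflow schemes are provided. The default, `single_random_lane`, gives
the whole Δin to one lane chosen uniformly among non-illuminated lanes:
it is the minimal scheme that is constant-rate, breaks the initial
symmetry stochastically, and preserves the n/Δin lower bound on the
iterations needed to assemble a tour (total occupancy ≈ n against a total
inflow of Δin per iteration). `random_weights` splits Δin across all dark
lanes proportionally to i.i.d. uniform weights and is kept as a
configurable alternative; the choice of scheme is a genuine design
freedom of the model class.

**Solution detection.** A trial succeeds when the binarized pattern has
been identical for `stability_window` consecutive iterations (default 30,
the analogue of "unchanged for 3 minutes" at one update per 6 s) *and*
the lattice decodes to a feasible tour — lanes at X ≥ 0.6 forming exactly
one city per order and one order per city. Requiring both is the
conservative reading; either alone can trigger early. The search time is
`search_iters` = (first iteration the finally accepted tour was
represented) − (first iteration any lane lit). Both totals and search
iterations are recorded; the growth phase before first illumination is
quadratic in n (all n² lanes must grow to the inhibition-sensitive region
≈ 0.55 at a shared rate Δin), so bounds of the form "≥ 1000·n iterations"
hold for the total iteration count of successful trials.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ, μ | 0.5 | inhibition weights of the revisit / simultaneity constraints (dimensionless) |
| ν | 0.988·ν\* | distance-coupling coefficient, per map (1/length) |
| θ | −0.5 | illumination threshold of the outer step sigmoid |
| inner sigmoid | γ=35, θ=0.6 | sensitivity of inhibition to occupancy |
| outer sigmoid | γ=1000, θ=−0.5 | step-like binarization of the conflict input |
| Δin, Δout | 0.001 | per-iteration inflow / per-lane outflow rates (occupancy units) |
| d | 0 | half-width of uniform observation noise |
| solution threshold | 0.6 | occupancy counting as "sufficiently elongated" (reuses the inner sigmoid threshold) |
| stability window | 30 iterations | pattern-stability criterion for success |
| max iterations | 20 000·n | failure cutoff, ≈ 20× the inflow-rate floor |

ν\* is computed exactly by maximising dist(V,V′) + dist(V′,V″) over
ordered triples of distinct cities (implemented as, per middle city, the
sum of its two largest distances; a brute-force triple loop serves as the
test oracle). The ratio 0.988 keeps ν strictly below ν\* with the ~1%
margin implied by the published eight-city pair (ν = 0.0081 against
ν\* ≈ 0.008197); per-map ν values cannot be ported directly because the
original maps are not published, so only the ratio policy is.

**Order adjacency.** Read literally, the distance clause |k−l| = 1 omits
the closing edge between orders n and 1. The default here is cyclic
adjacency (|k−l| mod n ∈ {1, n−1}), which charges every edge of the
closed tour; the literal variant is kept behind
`ControlParams(adjacency="literal")`. The tour/illumination fixed-point
property holds under both, and tests assert it for both.

## Map generators

**Experiment-mode maps (n = 4…10).** Raw distances are i.i.d. uniform on
[50, 150]; the affine rescale d′ = a·d + b pins the enumerated extreme
tour lengths to (100, 200) exactly (tour lengths are sums of n distances,
so the 2×2 linear system a·min + n·b = 100, a·max + n·b = 200 does it);
a candidate is accepted iff all rescaled distances are positive, both
extremes are uniquely attained (relative tolerance 1e−9), the mean tour
length lies within ±2 of 150, and the tour-length histogram is unimodal
(plateaus merged). The histogram uses min(10, round(√#tours)) bins: with
only 3 (n = 4) or 12 (n = 5) tour lengths a fixed 10-bin histogram is
mostly gaps and would reject every candidate, so the bin count scales
with the sample size. Uniform raw sampling keeps the acceptance rate of
the rejection loop practical (budget 10 000 attempts) while producing the
required unimodal, symmetric-ish length distributions.

These maps emulate the *structure* of the published study maps — same
extremes, same mean, same unimodality — but not the maps themselves,
whose distance matrices were never printed. Statistics tied to a specific
unpublished map (e.g. its exact mean tour length or per-map ν) can only
be emulated distributionally.

**Simulation-mode maps (n ≥ 4, used up to 20).** Distances are i.i.d.
normal(100, 20) with values below 10 redrawn (truncation by rejection,
keeping the mean honest), resampled until the sample mean is within ±2 of
100. Because every edge appears in the same number of tours, the mean
feasible tour length is exactly n × mean distance ≈ 100·n, which the
analysis layer uses as the estimate wherever enumeration is out of reach.

**Enumeration.** Tours are canonicalised (smallest label first, direction
with the lexicographically smaller second city), giving exactly
(n−1)!/2 representatives. The brute-force cap is n = 10 (181 440 tours,
seconds on one CPU); larger maps never enumerate.

## Scoring

Per-n batches are scored by: success rate 100·S/T (failures stay in the
denominator), mean/SD of search iterations, best/worst/mean found tour
length L_exp, the quality ratio L_exp/L_mean against the mean feasible
length (exact by enumeration below the cap, 100·n above it, flagged
`estimated`), and "top quality" — the percentile position
100·|{ℓ ≤ L_exp}|/count of L_exp in the full tour-length distribution.
The percentile reading of top quality reproduces the only externally
checkable reference entry (a four-city distribution {100, 159.9, 200}
scores 33.3% at L_exp = 142.0) and is documented as an interpretation.
Search-time scaling is an ordinary least-squares fit of mean search
iterations on n. The random-choice null — tours drawn uniformly from the
enumeration — scores a quality ratio statistically indistinguishable
from 1 and is implemented as `random_tour_baseline`.

Display rounding follows the one-decimal convention of the published
score tables; all comparisons in code and tests use full precision.

## Numerical choices

- Sigmoids are evaluated with `scipy.special.expit`; at gain 1000 a naive
  `exp` overflows, `expit` saturates cleanly.
- Equality of extreme tour lengths uses relative tolerance 1e−9;
  float-exact ties are not expected from continuous sampling but the
  tolerance makes uniqueness checks well-defined.
- A `BoundaryProximityWarning` fires when any conflict input is within
  1e−3 of θ: with λ = μ = 0.5, two fully grown lanes conflicting only
  with each other produce u = −0.5·σ_{35,0.6}(1) ≈ θ + 3.8e−7, so their
  illumination rests on the inner sigmoid's saturation slack. This is a
  real degeneracy of the parameterisation, not a numerical artefact: a
  pair of same-order winners can freeze into an absorbing infeasible
  state. Such deadlocks are the dominant failure mode of noise-free
  trials (a few percent of runs at n = 8) and are reported as failures at
  the iteration cap.
- Clamps: occupancy is hard-clamped to [0, 1]; both clamp overflows
  (inflow above 1, outflow below 0) destroy the excess resource. A
  per-state ledger (`total_influx`, `total_destroyed`) makes the
  conservation identity X·sum = influx − destroyed exactly testable.
- One RNG per trial (numpy `Generator`, seeded via
  `SeedSequence([master, n, trial])`); observation noise and inflow
  allocation draw from the same stream in a fixed order, so whole
  experiments are bit-reproducible functions of their configuration.

## Problem sizes used in the shipped reproductions

The behavioural test suite runs 100 trials per size at n = 4…8 on one
fixed map per n (the one-map-per-size design of the original study),
noise-free, plus 100 trials at d = 0.05 on the 8-city map. These sizes
keep the full factorial enumeration exact and make the Monte-Carlo sweep
a few minutes of single-CPU work; the same harness scales to the n =
10…20 / 500-trial simulation regime by switching to simulation-mode maps
(`ExperimentConfig(instance_mode="simulation", trials_per_n=500, ...)`).

## Known limitations

- The model deliberately carries no spatial or temporal correlations in
  its fluctuations: inflow lanes are drawn independently each iteration
  and observation noise is white. Consequently uncorrelated observation
  noise barely perturbs it — at the converged pattern the inner sigmoid
  is saturated and ξ ∈ [−0.05, 0.05] changes nothing, while during growth
  the noise merely randomises which lane crosses threshold first, much as
  the allocation draw already does. The biological finding that noise
  *degrades* performance is tied to disrupting the living searcher's
  correlated oscillations, which this model does not contain; the shipped
  noise-comparison test documents that divergence rather than papering
  over it.
- The threshold degeneracy at λ = μ = 0.5 (above) means a small fraction
  of noise-free trials end in absorbing infeasible states.
- Wall-clock CPU time per iteration grows with the n⁴-element weight
  matrix; the simulator is faithful to the model's iteration counts, not
  to any physical parallel implementation's run time.
- No wet-lab aspects are modelled: chip geometry, optics, oscillation
  phases and volume conservation of a real plasmodium are all out of
  scope.
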