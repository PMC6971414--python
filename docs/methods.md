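# Methods

## The forward model

The conducting airway is idealized as a rigid cylinder of length
*l* = 25 cm and volume *V* = 100 ml (radius *r* = √(V/πl) ≈ 1.13 cm),
child-scaled values; the alveolar compartment behind it is treated as
perfectly mixed with concentration C_A_NO that is constant over the few
seconds of one exhalation. The lumen concentration *c*(*z*, *t*) obeys

    ∂c/∂t = −v(t) ∂c/∂z + d ∂²c/∂z² + (2p/r)(C_aw_NO − c)

where the wall-exchange term (2p/r)(C_aw_NO − c) relaxes the lumen toward
the tissue concentration at rate 2p/r ≈ 0.071 s⁻¹. Coordinates run from
the alveolar boundary (z = 0) to the mouth (z = l); during exhalation
v(t) = Q(t)/(πr²) ≥ 0, the alveolar end carries the Dirichlet inflow
condition c = C_A_NO, and the mouth end a zero-diffusive-flux (one-sided)
outflow condition. The sensor is placed at the mouth node by default; its
position is configurable because instrument plumbing offsets are not
modelled.

Parameters, units and defaults:

| parameter | meaning | default | why |
|---|---|---|---|
| l, V | airway length, volume | 25 cm, 100 ml | child-scaled airway |
| p | wall permeability | 0.04 cm/s | fixed, not estimated; two-parameter identifiability |
| d | NO-in-air diffusivity | 0.23 cm²/s | literature value; at Péclet ≈ 10²–10³ the solution is insensitive to ±50% changes |
| σ | measurement-error SD | 5 ppb | deliberately conservative; also stabilizes the sampler (see below) |
| prior box | uniform prior support | caw ∈ [0, 1000], ca ∈ [0, 50] ppb | covers the population 97.5th percentiles (439, 3.88 ppb) with wide margin |

### Numerical scheme

Method of lines on a uniform grid of `n_nodes` = 100 points: first-order
upwind differencing for advection (the upwind direction follows the sign of
v), second-order central differences for diffusion, explicit Euler time
stepping. Between data samples the solver sub-steps with

    dt = cfl_safety / ( |v|/Δz + 2d/Δz² + 2p/r ),    cfl_safety = 0.8,

which makes every update a convex combination of old node values. This is
deliberately stricter than the usual `min(Δz/|v|, Δz²/2d)` advective/
diffusive rule: the combined bound guarantees a monotone scheme, so the
discrete solution obeys the PDE's maximum principle exactly (solutions stay
in [min(initial, C_A), C_aw] when C_A ≤ C_aw) at a cost of at most a factor
~2 in step count. Velocity is interpolated linearly in time and evaluated
at sub-step midpoints.

The initial profile c(z, t₀) is not observable. The default is 0 ppb
(the subject has just inhaled NO-free air, the standard online-protocol
assumption); a uniform value and the zero-flow diffusion–source equilibrium
profile are available as configuration.

**Accuracy.** Against the closed-form constant-flow steady state
c_out = c_w − (c_w − c_A)·exp(−2pl/rv) (itself cross-checked in the tests
by an independent ODE integration along a streamline), the post-washout
plateau agrees to 0.01–0.2% across 30–300 ml/s, and doubling the grid
changes the post-washout series by < 0.05%. A caveat: at exhalation onset
the inflow condition creates a concentration front of magnitude ≈ C_A that
advects to the sensor; like any monotone scheme, first-order upwinding
smears this front over a few cells, so *pointwise* agreement between grid
resolutions during the 1–2 washout seconds is only at the few-percent
level. All reported quantities (likelihoods integrate over the whole
series; plateaus are post-washout) are insensitive to this.

**Affine superposition.** The PDE, its boundary conditions and all three
initial-profile rules are affine in (C_aw, C_A). Each maneuver's sensor
response therefore decomposes exactly as
c(t) = C_aw·A(t) + C_A·B(t) + G(t), with A, B, G obtained from three
forward solves at parameters (0,0), (1,0), (0,1). The MCMC evaluates the
likelihood through this decomposition — a vector operation per iteration
instead of a PDE solve — which is what makes 3 × 5,000-iteration chains
over 70 fits a minutes-scale computation on one CPU. The tests verify the
decomposition against direct solves to 10⁻¹⁰ relative.

## Inference

Gaussian likelihood c̃_ij ~ N(c_ij(θ), σ) with independent observations and
maneuvers; uniform box priors; the unnormalized log posterior is the log
likelihood inside the box and −∞ outside. Three chains start from the
over-dispersed values (100, 1), (200, 2), (400, 4) ppb, each on an
independent `SeedSequence` substream of one master seed, so runs are
bit-reproducible and chains are independent.

Proposals are Gaussian, θ′ = θ + S·u with u ~ N(0, I); after every
iteration the lower-triangular factor S is updated by Vihola's robust
adaptive Metropolis rule

    S S′ ← S ( I + η_k (α − α*) u uᵀ/‖u‖² ) Sᵀ,   η_k = min(1, 2k^(−2/3)),

with target acceptance α* = 0.234 and the realized acceptance probability
α (zero for out-of-box proposals, which are always rejected but still
drive adaptation). The initial proposal scale is 3% of each prior range;
adaptation is never frozen. The 2×2 covariance update is applied by direct
re-factorization, falling back to the previous factor if round-off makes
the update non-positive.

Summaries: the MAP is the best *visited* draw across all chains and
iterations (with uniform priors this approximates the bounded MLE; an
optional `polish` step refines it by box-constrained least squares on the
affine representation, off by default, and the tests confirm the MCMC MAP
lands within a fraction of a posterior SD of that optimum). Posterior SDs
and central 95% credible intervals use the pooled second halves of the
chains ("first half discarded" burn-in, interpreted per chain). Central
rather than highest-density intervals are reported; for the near-Gaussian
posteriors seen here the difference is negligible. Convergence uses the
classic Gelman–Rubin factor on post-burn-in halves (the rank-normalized
variant postdates the approach mirrored here); identical chains give
√((n−1)/n), degenerate zero-variance chains return 1 with a warning. If
either parameter has R̂ ≥ 1.1 the chains are extended once by the original
iteration count and diagnostics recomputed; fits never silently drop the
flag.

σ = 5 ppb overstates the instrument noise by design: it widens credible
intervals (conservative) and keeps the sampler well-mixed. The
sigma-sensitivity check (refitting at σ = 10 and 15) moves MAP estimates by
far less than one posterior SD, because the Gaussian posterior mode does
not depend on σ.

## Synthetic data

The generator stands in for unavailable clinical recordings; what it
emulates, and what it does not, bounds what the simulation results say
about real data.

* **Population.** Individuals' (C_aw_NO, C_A_NO) are produced by mapping
  independent uniforms through monotone inverse quantile functions built on
  published percentile tables for under-20s — (2.5, 5, 25, 50, 75, 95,
  97.5)% = (19, 21, 34, 58, 123, 208, 439) ppb for C_aw_NO and (0.11, 0.61,
  1.52, 2.05, 2.73, 3.59, 3.88) ppb for C_A_NO. A shape-preserving (PCHIP)
  monotone cubic is used rather than an unconstrained smoothing spline,
  which can lose monotonicity and hence fail to be a quantile function;
  tails are clamped at the outer knots (no extrapolation). The two
  parameters are drawn independently — a simplification; any real
  correlation between sources is not represented.
* **Flow profiles.** Each maneuver starts at exactly 0 ml/s, rises to the
  target over `ramp_s` = 1 s (smoothstep), overshoots by 15% with a damped
  bump (decay constant 0.5 s), then holds a plateau with Gaussian jitter of
  5% of target. Durations are 12/10/8/6 s at 30/50/100/300 ml/s at 10 Hz —
  plausible clinic-style maneuvers in which slower flows are sustained
  longer. Real maneuvers additionally show drift, device filtering
  (correlated noise) and subject-specific shape; none of these are
  modelled, so replicate-stability results transfer to real data only
  qualitatively.
* **NO traces.** The forward PDE solution at the true parameters plus iid
  N(0, 5 ppb) noise; the generative noise level is taken equal to the
  fitting σ since no separate value is established. Signal and noise use
  separate seed streams.
* **Scenarios.** Per individual a nine-maneuver battery (2/3/2/2 at
  30/50/100/300) is generated, extended with two extra 50 ml/s replicates
  when the 5@50 protocol is requested. Protocols subset this pool —
  single-flow scenarios take one randomly selected battery replicate, HMA
  one per target — mirroring how archived nine-flow data were subsetted in
  the protocol-comparison analysis this package re-creates.

## The simulation study

`run_simulation_study` fits every individual under every scenario (each fit
with a deterministic sub-seed), recording MAP, posterior SD, R̂ and a
convergence flag per parameter; unconverged fits are flagged, never
dropped, and summaries can be computed with or without them. Error is
signed MAP − truth. Replicate stability refits the first two same-flow
replicates independently; the two fits of a pair share one chain seed
(common random numbers), so identical data give exactly zero difference and
genuine data differences dominate the contrast. The 3@50↔9F relationship is
summarized by OLS on log1p-transformed MAPs (log1p tames the positive skew
of concentration estimates).

Problem sizes: the convergence/recovery study uses 10 individuals × 7
scenarios with the full 3 × 5,000-iteration sampler; the replicate-
stability analysis uses 40 individuals, because medians of |MAP₁ − MAP₂|
over 10 individuals have Monte-Carlo error comparable to the adjacent-flow
contrasts being ordered. Both are desk-scale (tens of seconds to ~2
minutes).

Findings reproduced by the test suite on these synthetic studies: all
fits converge (max R̂ ≈ 1.01 ≪ 1.1); the nine-flow battery estimates
C_aw_NO with smaller median absolute error than any single-flow protocol;
C_aw_NO posterior SD rises monotonically with flow across single-flow
protocols (≈5 → ≈35 ppb from 30 to 300 ml/s); pooling maneuvers improves
precision in the order 9F ≤ HMA ≤ 5@50 for both parameters; replicate MAP
differences grow with flow for C_aw_NO and shrink with flow for C_A_NO.
The last ordering (C_A_NO) is the most delicate: the Fisher information
for C_A_NO under these synthetic profiles varies only mildly with flow
(theoretical MLE SDs ≈ 1.9/2.0/1.8/1.4 ppb at 30/50/100/300), so the
adjacent-flow contrasts at 30–100 ml/s sit close to Monte-Carlo noise even
at 40 individuals, and the ca ≥ 0 boundary truncates low-flow MAP spread;
the high-flow end of the ordering (300 ml/s most replicable) is the robust
part. The C_aw_NO orderings are large and stable.

## Known limitations

* Cylindrical, depth-uniform airway; no trumpet geometry or back-diffusion
  correction — C_aw_NO is interpretable only relative to this geometry.
* p, σ and the geometry are fixed, not estimated; violations (e.g. airway
  disease affecting permeability) bias the source estimates.
* Exhalation only: inhalation and breath-hold NO accumulation are not
  modelled, and the unknown initial profile is a configuration choice.
* The synthetic flow/noise model is idealized (iid noise, no device
  filtering); quantitative levels of error and SD depend on it, the
  qualitative protocol orderings are the transferable result.
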