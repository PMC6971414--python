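# fenodyn

Dynamic two-compartment modelling of exhaled nitric oxide (FeNO), with
Bayesian estimation of its two physiological sources and a simulation
framework for comparing fixed-flow sampling protocols.

Exhaled NO is a standard non-invasive marker of airway inflammation, but a
single FeNO reading conflates two sources: NO diffusing from the epithelial
tissue lining the conducting airway (tissue concentration **C_aw_NO**, ppb)
and NO arriving from the alveolar region (**C_A_NO**, ppb, the inflow
boundary value during exhalation). Because the airway contribution depends
on how long air resides in the airway, FeNO falls as exhalation flow rises —
which is also what makes the two sources separable from flow-resolved data.
`fenodyn` is aimed at researchers designing or re-analysing multiple-flow
FeNO protocols (clinical or epidemiological) who want source-resolved
estimates from time-synchronized flow and NO recordings, including protocols
that classical steady-state methods cannot handle, such as a single maneuver
or repeated maneuvers at one flow.

## Model

The airway is a rigid cylinder (length *l* = 25 cm, volume 100 ml by
default — child-scaled) with lumen NO concentration *c*(*z*, *t*) obeying

```
∂c/∂t = −v(t) ∂c/∂z + d ∂²c/∂z² + (2p/r) (C_aw_NO − c)
```

with linear velocity *v*(*t*) = *Q*(*t*)/(π r²) taken from the measured
volumetric flow *Q*(*t*), molecular diffusivity *d* = 0.23 cm²/s, wall
permeability *p* = 0.04 cm/s (fixed), Dirichlet inflow *c* = C_A_NO at the
alveolar end and zero diffusive flux at the mouth, where the analyzer
samples. The *dynamic* character — using the recorded *v*(*t*) instead of a
constant — is what extracts information from the rise, overshoot and jitter
of real maneuvers.

Observed concentrations are modelled as c̃_ij ~ N(c_ij(θ), σ) with σ = 5 ppb
and θ = (C_aw_NO, C_A_NO); independent maneuvers multiply their likelihoods.
With uniform box priors (default [0, 1000] × [0, 50] ppb) the posterior is
explored by three Metropolis chains of 5,000 iterations started at
(100, 1), (200, 2), (400, 4), whose Gaussian proposal covariance is tuned
on the fly by Vihola's robust adaptive Metropolis recursion (target
acceptance 0.234). The reported point estimate is the MAP (the best visited
draw, equal to the bounded MLE under uniform priors); uncertainty is the
empirical SD of the pooled second halves of the chains; convergence requires
Gelman–Rubin R̂ < 1.1 for both parameters, with one chain-length doubling
allowed otherwise.

Because no FeNO recordings ship with the package, a synthetic-data module
draws individuals from published population percentiles for under-20s
(C_aw_NO median 58 ppb, C_A_NO median 2.05 ppb) via monotone inverse
quantile maps, generates realistic fixed-flow maneuvers at 30/50/100/300
ml/s, and solves the PDE forward (plus Gaussian noise) to produce complete
simulated studies for seven sampling protocols: single maneuvers at each
flow, five at 50 ml/s (5@50), one each at 30/100/300 (HMA), and the full
nine-maneuver battery (9F).

## Worked example

```python
from fenodyn import DynamicFeNOEstimator, build_scenario_dataset

dataset = build_scenario_dataset(n_individuals=1, seed=42)
person = dataset.individuals[0]
print(f"true C_aw_NO = {person.truth.caw_ppb:.1f} ppb, "
      f"true C_A_NO = {person.truth.ca_ppb:.2f} ppb")

est = DynamicFeNOEstimator(seed=0).fit(person.scenario_maneuvers("9F"))
print(f"MAP  C_aw_NO = {est.map_caw_ppb_:.1f} ppb  (posterior SD {est.sd_caw_ppb_:.1f})")
print(f"MAP  C_A_NO  = {est.map_ca_ppb_:.2f} ppb  (posterior SD {est.sd_ca_ppb_:.2f})")
print(f"R-hat = ({est.rhat_caw_:.3f}, {est.rhat_ca_:.3f}), converged = {est.converged_}")
```

prints

```
true C_aw_NO = 178.6 ppb, true C_A_NO = 3.35 ppb
MAP  C_aw_NO = 177.5 ppb  (posterior SD 2.1)
MAP  C_A_NO  = 3.74 ppb  (posterior SD 0.36)
R-hat = (1.003, 1.001), converged = True
```

i.e. fitting the simulated nine-maneuver battery recovers the airway-wall
concentration to about 1 ppb and the alveolar concentration to a few tenths
of a ppb, with both chains' diagnostics well under the 1.1 threshold. The
same workflow is available from the shell (`fenodyn simulate`, `fenodyn
fit`, `fenodyn study`, `fenodyn report`); maneuvers travel as
`time_s,flow_ml_s,no_ppb` CSV files.

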