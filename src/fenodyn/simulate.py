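"""Synthetic population, flow-profile and maneuver generation.

No public FeNO recordings accompany the sampling-protocol study, so this
module generates everything the analysis needs:

* individual (C_aw_NO, C_A_NO) pairs drawn through monotone inverse
  quantile maps built on published population percentiles for individuals
  under 20 years of age;
* realistic fixed-flow exhalation profiles (rise from rest, damped
  overshoot of the target, plateau jitter) at the four clinical target
  flows 30/50/100/300 ml/s;
* noisy NO traces produced by the forward PDE model plus iid Gaussian
  measurement error;
* the named sampling scenarios (single flows, 5@50, 3@50, HMA, 9F) and a
  per-individual maneuver battery they subset, mirroring how the archived
  nine-maneuver protocol was subsetted in the original analysis.

Everything is reproducible from a single integer seed via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .airway import (
    AirwayGeometry,
    ConcentrationSeries,
    DEFAULT_GEOMETRY,
    FlowSeries,
    Maneuver,
    NOSourceParams,
    PDESolveConfig,
    ValidationError,
    solve_pde,
)

__all__ = [
    "PopulationQuantiles",
    "CAW_QUANTILES",
    "CA_QUANTILES",
    "FlowProfileSpec",
    "ScenarioSpec",
    "SCENARIOS",
    "STUDY_SCENARIOS",
    "IndividualData",
    "ScenarioDataset",
    "build_quantile_sampler",
    "draw_population",
    "simulate_flow_profile",
    "simulate_maneuver",
    "build_scenario_dataset",
    "default_profile_spec",
]


@dataclass(frozen=True)
class PopulationQuantiles:
    """Published percentile knots of a population NO-parameter distribution."""

    probs: tuple[float, ...]
    values_ppb: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, float)
        v = np.asarray(self.values_ppb, float)
        if p.size != v.size or p.size < 3:
            raise ValidationError("need >= 3 matching (prob, value) knots")
        if np.any(p <= 0) or np.any(p >= 1) or np.any(np.diff(p) <= 0):
            raise ValidationError("probs must be strictly increasing within (0, 1)")
        if np.any(np.diff(v) < 0):
            raise ValidationError("values must be non-decreasing")


_PROBS = (0.025, 0.05, 0.25, 0.50, 0.75, 0.95, 0.975)

#: Population percentiles (< 20 years) for the airway-wall concentration.
CAW_QUANTILES = PopulationQuantiles(_PROBS, (19.0, 21.0, 34.0, 58.0, 123.0, 208.0, 439.0))
#: Population percentiles (< 20 years) for the alveolar concentration.
CA_QUANTILES = PopulationQuantiles(_PROBS, (0.11, 0.61, 1.52, 2.05, 2.73, 3.59, 3.88))


def build_quantile_sampler(q: PopulationQuantiles) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone inverse quantile map F^{-1}: (0, 1) -> ppb.

    A shape-preserving (PCHIP) monotone cubic through the (prob, value)
    knots, interpolating every printed percentile exactly; probabilities
    outside the outermost knots are clamped to the extreme knot values (no
    tail extrapolation).  An unconstrained smoothing spline can lose
    monotonicity, which would not be a valid quantile function.
    """
    probs = np.asarray(q.probs, float)
    values = np.asarray(q.values_ppb, float)
    interp = PchipInterpolator(probs, values)
    lo, hi = probs[0], probs[-1]

    def sampler(u):
        u_arr = np.asarray(u, dtype=float)
        if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
            raise ValueError("quantile levels must lie strictly inside (0, 1)")
        out = interp(np.clip(u_arr, lo, hi))
        return out if u_arr.ndim else float(out)

    return sampler


def draw_population(
    n: int,
    q_caw: PopulationQuantiles = CAW_QUANTILES,
    q_ca: PopulationQuantiles = CA_QUANTILES,
    seed: int | np.random.SeedSequence = 0,
) -> list[NOSourceParams]:
    """Draw n individuals: independent uniforms through each quantile map."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    f_caw = build_quantile_sampler(q_caw)
    f_ca = build_quantile_sampler(q_ca)
    u = rng.uniform(size=(n, 2))
    # keep draws strictly inside (0, 1); measure-zero edge cases aside, uniform() < 1
    caw = f_caw(np.clip(u[:, 0], 1e-12, 1 - 1e-12))
    ca = f_ca(np.clip(u[:, 1], 1e-12, 1 - 1e-12))
    return [NOSourceParams(float(w), float(a)) for w, a in zip(caw, ca)]


@dataclass(frozen=True)
class FlowProfileSpec:
    """Shape of a fixed-flow exhalation: rise, overshoot, noisy plateau."""

    target_ml_s: float
    ramp_s: float = 1.0
    overshoot_frac: float = 0.15
    jitter_sd_ml_s: float = 0.0
    duration_s: float = 10.0
    sample_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.target_ml_s <= 0:
            raise ValidationError("target_ml_s must be positive")
        if not 0.0 <= self.overshoot_frac < 1.0:
            raise ValidationError("overshoot_frac must lie in [0, 1)")
        if self.duration_s <= self.ramp_s:
            raise ValidationError("duration_s must exceed ramp_s")
        if self.sample_hz <= 0 or self.jitter_sd_ml_s < 0:
            raise ValidationError("sample_hz must be positive, jitter_sd non-negative")


#: Default maneuver durations by target flow (s): slower flows exhale longer.
DEFAULT_DURATIONS_S: Mapping[int, float] = {30: 12.0, 50: 10.0, 100: 8.0, 300: 6.0}


def default_profile_spec(target_ml_s: float) -> FlowProfileSpec:
    """Study-default profile: 1 s rise, 15% overshoot, 5% plateau jitter."""
    duration = DEFAULT_DURATIONS_S.get(int(target_ml_s), 10.0)
    return FlowProfileSpec(
        target_ml_s=float(target_ml_s),
        ramp_s=1.0,
        overshoot_frac=0.15,
        jitter_sd_ml_s=0.05 * float(target_ml_s),
        duration_s=duration,
        sample_hz=10.0,
    )


_OVERSHOOT_TAU_S = 0.5  # decay time of the post-ramp overshoot bump


def simulate_flow_profile(
    spec: FlowProfileSpec, seed: int | np.random.SeedSequence = 0
) -> FlowSeries:
    """Generate one maneuver's flow trace.

    Deterministic skeleton: a smoothstep rise from exactly 0 reaching the
    target at ``ramp_s``, plus a damped overshoot bump peaking at
    ``target * (1 + overshoot_frac)`` shortly after the ramp and decaying
    with time constant 0.5 s.  Gaussian jitter (SD ``jitter_sd_ml_s``) is
    added on the plateau (t >= ramp_s); flow is clipped at 0 from below.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.sample_hz
    t = np.arange(0.0, spec.duration_s + 0.5 * dt, dt)
    x = np.clip(t / spec.ramp_s, 0.0, 1.0)
    base = x * x * (3.0 - 2.0 * x)  # smoothstep: 0 at onset, exactly 1 at ramp_s
    u = np.maximum(t - spec.ramp_s, 0.0) / _OVERSHOOT_TAU_S
    bump = spec.overshoot_frac * u * np.exp(1.0 - u)
    flow = spec.target_ml_s * (base + bump)
    if spec.jitter_sd_ml_s > 0:
        plateau = t >= spec.ramp_s
        flow[plateau] += rng.normal(0.0, spec.jitter_sd_ml_s, int(plateau.sum()))
    flow = np.maximum(flow, 0.0)
    flow[0] = 0.0
    return FlowSeries(times_s=t, flow_ml_s=flow, target_ml_s=spec.target_ml_s)


def simulate_maneuver(
    params: NOSourceParams,
    geometry: AirwayGeometry,
    flow: FlowSeries,
    noise_sd_ppb: float = 5.0,
    solve_config: PDESolveConfig = PDESolveConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> Maneuver:
    """Forward-simulate one maneuver: PDE solution plus Gaussian noise.

    The noiseless component depends only on (params, geometry, flow,
    solve_config); the seed drives the measurement noise alone.
    """
    if noise_sd_ppb < 0:
        raise ValidationError("noise_sd_ppb must be non-negative")
    clean = solve_pde(params, geometry, flow, solve_config)
    no = clean.no_ppb.copy()
    if noise_sd_ppb > 0:
        rng = np.random.default_rng(seed)
        no = no + rng.normal(0.0, noise_sd_ppb, no.size)
    return Maneuver(flow=flow, concentration=ConcentrationSeries(flow.times_s, no))


@dataclass(frozen=True)
class ScenarioSpec:
    """A named sampling protocol: multiset of (target flow, replicate count)."""

    name: str
    maneuvers: tuple[tuple[int, int], ...]

    @property
    def n_maneuvers(self) -> int:
        return sum(k for _, k in self.maneuvers)

    @property
    def targets(self) -> tuple[int, ...]:
        return tuple(t for t, _ in self.maneuvers)


#: The sampling protocols compared in the simulation study plus the 3@50
#: substitute used when only three 50 ml/s replicates exist.
SCENARIOS: Mapping[str, ScenarioSpec] = {
    "30": ScenarioSpec("30", ((30, 1),)),
    "50": ScenarioSpec("50", ((50, 1),)),
    "100": ScenarioSpec("100", ((100, 1),)),
    "300": ScenarioSpec("300", ((300, 1),)),
    "5@50": ScenarioSpec("5@50", ((50, 5),)),
    "3@50": ScenarioSpec("3@50", ((50, 3),)),
    "HMA": ScenarioSpec("HMA", ((30, 1), (100, 1), (300, 1))),
    "9F": ScenarioSpec("9F", ((30, 2), (50, 3), (100, 2), (300, 2))),
}

#: The seven scenarios of the simulation study, in presentation order.
STUDY_SCENARIOS: tuple[str, ...] = ("30", "50", "100", "300", "5@50", "HMA", "9F")

#: Replicate counts of the archived nine-maneuver battery per target.
_BATTERY_COUNTS: Mapping[int, int] = {30: 2, 50: 3, 100: 2, 300: 2}


@dataclass
class IndividualData:
    """Truth and maneuver pool for one simulated individual.

    ``maneuvers`` maps target flow -> replicate list; the first
    ``_BATTERY_COUNTS[target]`` replicates form the nine-maneuver battery
    from which single-flow and HMA scenarios draw.  ``selections`` maps
    scenario name -> list of (target, replicate index).
    """

    individual_id: int
    truth: NOSourceParams
    maneuvers: dict[int, list[Maneuver]]
    selections: dict[str, list[tuple[int, int]]]

    def scenario_maneuvers(self, scenario: str) -> list[Maneuver]:
        return [self.maneuvers[t][i] for t, i in self.selections[scenario]]


@dataclass
class ScenarioDataset:
    """A full simulated study: individuals x scenarios, one seed."""

    individuals: list[IndividualData]
    scenario_names: tuple[str, ...]
    geometry: AirwayGeometry
    noise_sd_ppb: float
    seed: int

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)


def _required_counts(scenarios: Sequence[ScenarioSpec]) -> dict[int, int]:
    counts = dict(_BATTERY_COUNTS)
    for spec in scenarios:
        for target, k in spec.maneuvers:
            counts[target] = max(counts.get(target, 0), k)
    return counts


def build_scenario_dataset(
    n_individuals: int,
    scenarios: Sequence[str] = STUDY_SCENARIOS,
    geometry: AirwayGeometry = DEFAULT_GEOMETRY,
    profile_specs: Mapping[int, FlowProfileSpec] | None = None,
    noise_sd_ppb: float = 5.0,
    solve_config: PDESolveConfig = PDESolveConfig(),
    seed: int = 0,
) -> ScenarioDataset:
    """Simulate a protocol-comparison study dataset.

    Each individual receives a truth pair from the population quantile maps
    and one maneuver pool per target flow, sized to cover every requested
    scenario (the nine-maneuver battery 2/3/2/2 at 30/50/100/300 ml/s, plus
    extra 50 ml/s replicates if 5@50 is requested).  Scenarios subset the
    pool: single-flow scenarios take one seeded-randomly chosen battery
    replicate of their target, HMA one per target in {30, 100, 300}, and
    3@50/9F the battery replicates themselves — mirroring the original
    study's subsetting of archived nine-flow maneuvers.
    """
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    specs = [SCENARIOS[name] if isinstance(name, str) else name for name in scenarios]
    names = tuple(s.name for s in specs)
    counts = _required_counts(specs)

    root = np.random.SeedSequence(seed)
    truth_ss, *indiv_ss = root.spawn(n_individuals + 1)
    truths = draw_population(n_individuals, seed=truth_ss)

    individuals = []
    for i, (truth, ss) in enumerate(zip(truths, indiv_ss)):
        flow_ss, noise_ss, select_ss = ss.spawn(3)
        n_total = sum(counts.values())
        flow_children = flow_ss.spawn(n_total)
        noise_children = noise_ss.spawn(n_total)
        pool: dict[int, list[Maneuver]] = {}
        j = 0
        for target in sorted(counts):
            pool[target] = []
            spec = (profile_specs or {}).get(target) or default_profile_spec(target)
            for _ in range(counts[target]):
                flow = simulate_flow_profile(spec, seed=flow_children[j])
                man = simulate_maneuver(
                    truth, geometry, flow, noise_sd_ppb, solve_config,
                    seed=noise_children[j],
                )
                pool[target].append(man)
                j += 1
        select_rng = np.random.default_rng(select_ss)
        selections: dict[str, list[tuple[int, int]]] = {}
        for spec_s in specs:
            picks: list[tuple[int, int]] = []
            for target, k in spec_s.maneuvers:
                n_battery = _BATTERY_COUNTS.get(target, counts[target])
                if k <= n_battery:
                    # subset of the battery; single picks are random draws
                    if k == 1:
                        picks.append((target, int(select_rng.integers(n_battery))))
                    else:
                        picks.extend((target, r) for r in range(k))
                else:
                    picks.extend((target, r) for r in range(k))
            selections[spec_s.name] = picks
        individuals.append(
            IndividualData(
                individual_id=i, truth=truth, maneuvers=pool, selections=selections
            )
        )
    return ScenarioDataset(
        individuals=individuals,
        scenario_names=names,
        geometry=geometry,
        noise_sd_ppb=noise_sd_ppb,
        seed=seed,
    )
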