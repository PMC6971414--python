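"""Dynamic two-compartment airway model of exhaled nitric oxide.

The airway is a rigid cylinder of length ``l`` and radius ``r`` connecting a
perfectly mixed alveolar compartment (NO concentration ``C_A_NO``, the inflow
boundary value during exhalation) to the mouth, where the analyzer samples.
NO diffuses from the epithelial wall (tissue concentration ``C_aw_NO``) into
the lumen at a rate proportional to the concentration difference, while the
exhaled air column advects lumen gas mouth-ward at the linear velocity
``v(t) = Q(t) / (pi r^2)`` driven by the measured volumetric flow ``Q(t)``.

The lumen concentration ``c(z, t)`` obeys the advection-diffusion-source PDE

    dc/dt = -v(t) dc/dz + d d2c/dz2 + (2 p / r) (C_aw_NO - c)

with a Dirichlet inflow condition ``c = C_A_NO`` at the alveolar end and a
zero-diffusive-flux outflow condition at the mouth.  The *dynamic* character
of the model is that ``v(t)`` is taken from the recorded flow trace of each
maneuver rather than assumed constant; the classical steady-state
two-compartment outlet formula (:func:`steady_state_outlet`) is recovered as
the constant-flow, post-washout limit and serves as an analytic oracle.

Units: lengths in cm, volumes in ml (= cm^3), volumetric flow in ml/s,
linear velocity in cm/s, concentrations in ppb, permeability in cm/s,
diffusivity in cm^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AirwayGeometry",
    "NOSourceParams",
    "FlowSeries",
    "ConcentrationSeries",
    "Maneuver",
    "PDESolveConfig",
    "SolverError",
    "ValidationError",
    "linear_velocity",
    "solve_pde",
    "steady_state_outlet",
    "linear_response",
    "DEFAULT_GEOMETRY",
]


class ValidationError(ValueError):
    """Raised when input data violate a model-type invariant."""


class SolverError(RuntimeError):
    """Raised when the PDE solver produces an inadmissible solution."""


@dataclass(frozen=True)
class AirwayGeometry:
    """Fixed cylindrical airway hosting the PDE.

    The radius is redundant with (length, volume) and must satisfy
    ``pi r^2 l = V``; use :meth:`from_length_volume` to construct a
    consistent geometry.  ``z`` coordinates run from the alveolar boundary
    (``z_alv_cm = 0``) toward the mouth (``z_mouth_cm = length_cm``); the
    sensor sits at the mouth unless configured otherwise.
    """

    length_cm: float
    volume_ml: float
    radius_cm: float
    permeability_cm_s: float = 0.04
    diffusivity_cm2_s: float = 0.23
    z_alv_cm: float = 0.0
    z_mouth_cm: float = field(default=None)  # type: ignore[assignment]
    z_sensor_cm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.z_mouth_cm is None:
            object.__setattr__(self, "z_mouth_cm", self.length_cm)
        if self.z_sensor_cm is None:
            object.__setattr__(self, "z_sensor_cm", self.z_mouth_cm)
        for name in ("length_cm", "volume_ml", "radius_cm", "diffusivity_cm2_s"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.permeability_cm_s < 0:
            # p = 0 (impermeable wall) is admitted as a degenerate limit
            raise ValidationError("permeability_cm_s must be non-negative")
        vol = math.pi * self.radius_cm ** 2 * self.length_cm
        if abs(vol - self.volume_ml) > 1e-9 * self.volume_ml:
            raise ValidationError(
                "inconsistent geometry: pi r^2 l = "
                f"{vol:.12g} ml but volume_ml = {self.volume_ml:.12g}"
            )
        for name in ("z_alv_cm", "z_mouth_cm", "z_sensor_cm"):
            z = getattr(self, name)
            if not 0.0 <= z <= self.length_cm:
                raise ValidationError(f"{name}={z} outside [0, {self.length_cm}]")
        if not math.isclose(abs(self.z_mouth_cm - self.z_alv_cm), self.length_cm):
            raise ValidationError("alveolar boundary and mouth must be at opposite ends")

    @classmethod
    def from_length_volume(
        cls,
        length_cm: float = 25.0,
        volume_ml: float = 100.0,
        permeability_cm_s: float = 0.04,
        diffusivity_cm2_s: float = 0.23,
        z_sensor_cm: float | None = None,
    ) -> "AirwayGeometry":
        """Build a consistent geometry from length and volume."""
        if length_cm <= 0 or volume_ml <= 0:
            raise ValidationError("length and volume must be strictly positive")
        radius = math.sqrt(volume_ml / (math.pi * length_cm))
        return cls(
            length_cm=length_cm,
            volume_ml=volume_ml,
            radius_cm=radius,
            permeability_cm_s=permeability_cm_s,
            diffusivity_cm2_s=diffusivity_cm2_s,
            z_sensor_cm=length_cm if z_sensor_cm is None else z_sensor_cm,
        )

    @property
    def cross_section_cm2(self) -> float:
        return math.pi * self.radius_cm ** 2

    @property
    def wall_exchange_rate_s(self) -> float:
        """Wall-source relaxation rate 2p/r (1/s)."""
        return 2.0 * self.permeability_cm_s / self.radius_cm


#: Child-scale default used throughout: 25 cm long, 100 ml airway,
#: permeability fixed at 0.04 cm/s, NO-in-air diffusivity 0.23 cm^2/s.
DEFAULT_GEOMETRY = AirwayGeometry.from_length_volume()


@dataclass(frozen=True)
class NOSourceParams:
    """The estimand: airway-wall and alveolar NO concentrations (ppb)."""

    caw_ppb: float
    ca_ppb: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.caw_ppb) and np.isfinite(self.ca_ppb)):
            raise ValidationError("NO source parameters must be finite")
        if self.caw_ppb < 0 or self.ca_ppb < 0:
            raise ValidationError("NO source parameters must be non-negative")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FlowSeries:
    """One maneuver's volumetric flow trace, sampled at the device times.

    Exhalation starts from rest, so the first flow sample must be exactly 0.
    """

    times_s: np.ndarray
    flow_ml_s: np.ndarray
    target_ml_s: float | None = None

    def __post_init__(self) -> None:
        t = _as_float_array(self.times_s, "times_s")
        q = _as_float_array(self.flow_ml_s, "flow_ml_s")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "flow_ml_s", q)
        if t.size != q.size:
            raise ValidationError("times_s and flow_ml_s lengths differ")
        if t.size < 2:
            raise ValidationError("a flow series needs at least two samples")
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValidationError(f"times_s not strictly increasing at sample {i}")
        if np.any(q < 0):
            raise ValidationError("flow must be non-negative during exhalation")
        if q[0] != 0.0:
            raise ValidationError("flow must be 0 at exhalation onset")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class ConcentrationSeries:
    """NO concentration (ppb) at the sensor on the same grid as its flow."""

    times_s: np.ndarray
    no_ppb: np.ndarray

    def __post_init__(self) -> None:
        t = _as_float_array(self.times_s, "times_s")
        c = _as_float_array(self.no_ppb, "no_ppb")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "no_ppb", c)
        if t.size != c.size:
            raise ValidationError("times_s and no_ppb lengths differ")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class Maneuver:
    """One exhalation: aligned flow and sensor-concentration series."""

    flow: FlowSeries
    concentration: ConcentrationSeries

    def __post_init__(self) -> None:
        if len(self.flow) != len(self.concentration) or not np.array_equal(
            self.flow.times_s, self.concentration.times_s
        ):
            raise ValidationError("flow and concentration grids are not aligned")

    @property
    def times_s(self) -> np.ndarray:
        return self.flow.times_s


@dataclass(frozen=True)
class PDESolveConfig:
    """Numerical controls for :func:`solve_pde`.

    ``initial_profile`` selects ``c(z, t0)``: ``"zero"`` (NO-free inhaled
    air, the online-protocol default), ``"uniform"`` (constant
    ``initial_value_ppb``) or ``"steady"`` (the zero-flow diffusion-source
    equilibrium profile for the given parameters).
    """

    n_nodes: int = 100
    cfl_safety: float = 0.8
    initial_profile: str = "zero"
    initial_value_ppb: float = 0.0

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValidationError("n_nodes must be >= 10")
        if not 0.0 < self.cfl_safety <= 1.0:
            raise ValidationError("cfl_safety must lie in (0, 1]")
        if self.initial_profile not in ("zero", "uniform", "steady"):
            raise ValidationError(
                "initial_profile must be 'zero', 'uniform' or 'steady'"
            )


def linear_velocity(flow: FlowSeries, geometry: AirwayGeometry) -> np.ndarray:
    """Convert volumetric flow (ml/s) to linear velocity (cm/s), v = Q/(pi r^2)."""
    return flow.flow_ml_s / geometry.cross_section_cm2


def steady_state_outlet(
    params: NOSourceParams, geometry: AirwayGeometry, v_cm_s: float
) -> float:
    """Constant-flow steady-state outlet concentration (plug flow, ppb).

    Along a streamline moving at velocity ``v`` the source ODE
    ``v dc/dz = (2p/r)(c_w - c)`` with inlet value ``C_A`` integrates to

        c_out = c_w - (c_w - c_A) exp(-2 p l / (r v)).

    Diffusion is neglected (Peclet >> 1 at clinical flows); the dynamic
    solver is checked against this closed form after washout.
    """
    if not v_cm_s > 0:
        raise ValueError("steady-state outlet requires v_cm_s > 0")
    g = geometry
    expo = 2.0 * g.permeability_cm_s * g.length_cm / (g.radius_cm * v_cm_s)
    return params.caw_ppb - (params.caw_ppb - params.ca_ppb) * math.exp(-expo)


def _initial_profile(
    params: NOSourceParams,
    geometry: AirwayGeometry,
    config: PDESolveConfig,
    z: np.ndarray,
) -> np.ndarray:
    if config.initial_profile == "zero":
        return np.zeros_like(z)
    if config.initial_profile == "uniform":
        return np.full_like(z, float(config.initial_value_ppb))
    # zero-flow steady state: d c'' + k (c_w - c) = 0, c(0) = c_A, c'(l) = 0
    mu = math.sqrt(geometry.wall_exchange_rate_s / geometry.diffusivity_cm2_s)
    l = geometry.length_cm
    shape = np.cosh(mu * (l - z)) / math.cosh(mu * l)
    return params.caw_ppb - (params.caw_ppb - params.ca_ppb) * shape


def solve_pde(
    params: NOSourceParams,
    geometry: AirwayGeometry,
    flow: FlowSeries,
    config: PDESolveConfig = PDESolveConfig(),
) -> ConcentrationSeries:
    """Solve the dynamic two-compartment PDE for one maneuver.

    Method of lines on a uniform grid from the alveolar boundary (node 0,
    Dirichlet inflow ``c = C_A``) to the mouth (last node, zero diffusive
    flux): first-order upwind advection, central-difference diffusion and
    explicit Euler stepping, sub-stepped so every update is a convex
    combination of old node values (monotone; the discrete solution obeys
    the same maximum principle as the PDE).  Returns the concentration at
    the sensor node at each sample time of ``flow``.
    """
    g = geometry
    n = config.n_nodes
    dz = g.length_cm / (n - 1)
    z = np.linspace(0.0, g.length_cm, n)
    k = g.wall_exchange_rate_s
    d = g.diffusivity_cm2_s

    v = linear_velocity(flow, g)
    t = flow.times_s

    c = _initial_profile(params, g, config, z).astype(float)
    c[0] = params.ca_ppb

    # sensor: nearest grid node to the configured position
    i_sensor = int(round(g.z_sensor_cm / dz))
    i_sensor = min(max(i_sensor, 0), n - 1)

    out = np.empty(t.size)
    out[0] = c[i_sensor]

    diff_coef = d / dz**2
    ca = params.ca_ppb
    caw = params.caw_ppb
    for i in range(t.size - 1):
        dt_data = t[i + 1] - t[i]
        v_max = max(v[i], v[i + 1])
        # combined positivity limit: dt (v/dz + 2d/dz^2 + k) <= cfl_safety
        dt_lim = config.cfl_safety / (v_max / dz + 2.0 * diff_coef + k)
        m = max(1, int(math.ceil(dt_data / dt_lim)))
        dt = dt_data / m
        for s in range(m):
            # velocity at the sub-step midpoint, linear in t between samples
            frac = (s + 0.5) / m
            vs = v[i] + frac * (v[i + 1] - v[i])
            adv = vs * dt / dz
            dif = diff_coef * dt
            src = k * dt
            upw = c[1:] - c[:-1]
            lap = np.empty(n - 1)
            lap[:-1] = c[2:] - 2.0 * c[1:-1] + c[:-2]
            lap[-1] = c[-2] - c[-1]  # ghost node: zero diffusive flux at mouth
            c[1:] += -adv * upw + dif * lap + src * (caw - c[1:])
            c[0] = ca
        out[i + 1] = c[i_sensor]

    if not np.all(np.isfinite(out)):
        raise SolverError("PDE solution is not finite")
    tol = 1e-9 * max(caw, ca, 1.0)
    if np.min(out) < -tol:
        raise SolverError(f"negative sensor concentration {np.min(out):.3g} ppb")
    return ConcentrationSeries(times_s=t.copy(), no_ppb=out)


def linear_response(
    geometry: AirwayGeometry,
    flow: FlowSeries,
    config: PDESolveConfig = PDESolveConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose the sensor response as ``c(t) = caw*A(t) + ca*B(t) + G(t)``.

    The PDE, its boundary conditions and all three initial-profile rules are
    affine in ``(C_aw, C_A)``, so the solution for any parameter pair is the
    superposition of three basis solves: parameters (0, 0) (carries any
    parameter-independent initial condition), (1, 0) and (0, 1).  The
    decomposition is exact up to floating-point round-off and lets the MCMC
    evaluate the likelihood with a dot product per maneuver instead of a PDE
    solve per iteration.
    """
    g_part = solve_pde(NOSourceParams(0.0, 0.0), geometry, flow, config).no_ppb
    a_part = solve_pde(NOSourceParams(1.0, 0.0), geometry, flow, config).no_ppb - g_part
    b_part = solve_pde(NOSourceParams(0.0, 1.0), geometry, flow, config).no_ppb - g_part
    return a_part, b_part, g_part


def model_sensor_series(
    params: NOSourceParams,
    response: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    """Evaluate a precomputed linear response at a parameter pair."""
    a, b, g = response
    return params.caw_ppb * a + params.ca_ppb * b + g


def constant_flow_series(
    target_ml_s: float,
    duration_s: float,
    sample_hz: float = 10.0,
    ramp_s: float = 0.5,
) -> FlowSeries:
    """Idealized maneuver: linear ramp from rest to a constant target flow.

    Convenience for oracle tests and washout experiments; realistic profiles
    (overshoot, jitter) live in :mod:`fenodyn.simulate`.
    """
    t = np.arange(0.0, duration_s + 0.5 / sample_hz, 1.0 / sample_hz)
    q = np.where(t < ramp_s, target_ml_s * t / ramp_s, target_ml_s)
    q[0] = 0.0
    return FlowSeries(times_s=t, flow_ml_s=q, target_ml_s=target_ml_s)
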