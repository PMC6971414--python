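"""File formats and run configuration.

Maneuvers travel as plain CSV (columns exactly ``time_s,flow_ml_s,no_ppb``,
header required, UTF-8, ``.`` decimal); fit results as JSON with a schema
version; run configuration as YAML with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .airway import (
    AirwayGeometry,
    ConcentrationSeries,
    FlowSeries,
    Maneuver,
    PDESolveConfig,
    ValidationError,
)
from .inference import DEFAULT_INITS, FitResult, MCMCConfig
from .simulate import (
    CA_QUANTILES,
    CAW_QUANTILES,
    PopulationQuantiles,
    STUDY_SCENARIOS,
)

__all__ = [
    "MANEUVER_HEADER",
    "read_maneuver_csv",
    "write_maneuver_csv",
    "write_fit_json",
    "read_fit_json",
    "write_chains_csv",
    "RunConfig",
    "load_config",
]

MANEUVER_HEADER = ("time_s", "flow_ml_s", "no_ppb")
FIT_SCHEMA_VERSION = 1


class ParseError(ValidationError):
    """Malformed input file."""


def read_maneuver_csv(path: str | Path) -> Maneuver:
    """Read one maneuver, validating as it parses.

    Errors name the offending line (1-based, header is line 1).
    """
    path = Path(path)
    times: list[float] = []
    flows: list[float] = []
    nos: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        cols = tuple(c.strip() for c in header.split(","))
        if cols != MANEUVER_HEADER:
            raise ParseError(
                f"{path}: line 1: header must be '{','.join(MANEUVER_HEADER)}', "
                f"got '{header}'"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
            try:
                t, q, c = (float(p) for p in parts)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if not all(map(math.isfinite, (t, q, c))):
                raise ParseError(f"{path}: line {lineno}: non-finite value")
            if times and t <= times[-1]:
                raise ParseError(
                    f"{path}: line {lineno}: time {t} not increasing (previous {times[-1]})"
                )
            if q < 0:
                raise ParseError(f"{path}: line {lineno}: negative flow {q}")
            times.append(t)
            flows.append(q)
            nos.append(c)
    if len(times) < 2:
        raise ParseError(f"{path}: needs at least 2 data rows")
    try:
        flow = FlowSeries(np.array(times), np.array(flows))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from None
    return Maneuver(flow=flow, concentration=ConcentrationSeries(np.array(times), np.array(nos)))


def write_maneuver_csv(maneuver: Maneuver, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(",".join(MANEUVER_HEADER) + "\n")
        for t, q, c in zip(
            maneuver.times_s, maneuver.flow.flow_ml_s, maneuver.concentration.no_ppb
        ):
            fh.write(f"{float(t)!r},{float(q)!r},{float(c)!r}\n")


def _nan_to_none(x: float) -> float | None:
    return None if (x is None or not math.isfinite(x)) else float(x)


def write_fit_json(
    result: FitResult, path: str | Path, config: Mapping[str, Any] | None = None
) -> None:
    """Serialize a fit summary (plus config echo and software version)."""
    payload = {
        "schema_version": FIT_SCHEMA_VERSION,
        "software_version": __version__,
        "map_caw_ppb": result.map_caw_ppb,
        "map_ca_ppb": result.map_ca_ppb,
        "sd_caw_ppb": _nan_to_none(result.sd_caw_ppb),
        "sd_ca_ppb": _nan_to_none(result.sd_ca_ppb),
        "rhat_caw": _nan_to_none(result.rhat_caw),
        "rhat_ca": _nan_to_none(result.rhat_ca),
        "ci95_caw_ppb": list(result.ci95_caw_ppb),
        "ci95_ca_ppb": list(result.ci95_ca_ppb),
        "converged": result.converged,
        "accept_rate": list(result.accept_rate),
        "n_iter_total": result.n_iter_total,
        "extended": result.extended,
        "sigma_ppb": result.sigma_ppb,
        "warnings": list(result.warnings),
        "config": dict(config) if config else {},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


_REQUIRED_FIT_KEYS = {
    "schema_version", "map_caw_ppb", "map_ca_ppb", "sd_caw_ppb", "sd_ca_ppb",
    "rhat_caw", "rhat_ca", "ci95_caw_ppb", "ci95_ca_ppb", "converged",
}


def read_fit_json(path: str | Path) -> FitResult:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    missing = _REQUIRED_FIT_KEYS - set(data)
    if missing:
        raise ParseError(f"{path}: missing fields {sorted(missing)}")
    if data["schema_version"] != FIT_SCHEMA_VERSION:
        raise ParseError(
            f"{path}: schema version {data['schema_version']} != {FIT_SCHEMA_VERSION}"
        )

    def _none_to_nan(x):
        return math.nan if x is None else float(x)

    return FitResult(
        map_caw_ppb=float(data["map_caw_ppb"]),
        map_ca_ppb=float(data["map_ca_ppb"]),
        sd_caw_ppb=_none_to_nan(data["sd_caw_ppb"]),
        sd_ca_ppb=_none_to_nan(data["sd_ca_ppb"]),
        rhat_caw=_none_to_nan(data["rhat_caw"]),
        rhat_ca=_none_to_nan(data["rhat_ca"]),
        ci95_caw_ppb=tuple(data["ci95_caw_ppb"]),
        ci95_ca_ppb=tuple(data["ci95_ca_ppb"]),
        converged=bool(data["converged"]),
        accept_rate=tuple(data.get("accept_rate", ())),
        n_iter_total=int(data.get("n_iter_total", 0)),
        extended=bool(data.get("extended", False)),
        sigma_ppb=float(data.get("sigma_ppb", 5.0)),
        warnings=tuple(data.get("warnings", ())),
    )


def write_chains_csv(chains, path: str | Path) -> None:
    """Dump raw MCMC draws: columns chain, iter, caw_ppb, ca_ppb, log_post."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("chain,iter,caw_ppb,ca_ppb,log_post\n")
        for c, (draws, lp) in enumerate(zip(chains.draws, chains.log_post)):
            for i in range(draws.shape[0]):
                fh.write(
                    f"{c},{i},{float(draws[i, 0])!r},"
                    f"{float(draws[i, 1])!r},{float(lp[i])!r}\n"
                )


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration assembled from YAML blocks."""

    geometry: AirwayGeometry
    solver: PDESolveConfig
    mcmc: MCMCConfig
    caw_quantiles: PopulationQuantiles
    ca_quantiles: PopulationQuantiles
    scenarios: tuple[str, ...]
    noise_sd_ppb: float
    seed: int
    out_dir: str


_GEOMETRY_KEYS = {"length_cm", "volume_ml", "permeability_cm_s", "diffusivity_cm2_s", "z_sensor_cm"}
_SOLVER_KEYS = {"n_nodes", "cfl_safety", "initial_profile", "initial_value_ppb"}
_MCMC_KEYS = {
    "n_chains", "n_iter", "inits", "sigma_ppb", "prior_bounds",
    "target_accept", "rhat_threshold", "max_extra_iter",
}
_POP_KEYS = {"caw_probs", "caw_values_ppb", "ca_probs", "ca_values_ppb"}
_TOP_KEYS = {"geometry", "solver", "mcmc", "population", "scenarios", "noise_sd_ppb", "seed", "out_dir"}


def _check_keys(block: Mapping[str, Any], allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValidationError(f"unknown keys in '{name}' block: {sorted(unknown)}")


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a YAML run configuration; absent blocks fall back to defaults."""
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError("config root must be a mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    _check_keys(raw, _TOP_KEYS, "top-level")

    geo = dict(raw.get("geometry") or {})
    _check_keys(geo, _GEOMETRY_KEYS, "geometry")
    geometry = AirwayGeometry.from_length_volume(
        length_cm=float(geo.get("length_cm", 25.0)),
        volume_ml=float(geo.get("volume_ml", 100.0)),
        permeability_cm_s=float(geo.get("permeability_cm_s", 0.04)),
        diffusivity_cm2_s=float(geo.get("diffusivity_cm2_s", 0.23)),
        z_sensor_cm=geo.get("z_sensor_cm"),
    )

    sol = dict(raw.get("solver") or {})
    _check_keys(sol, _SOLVER_KEYS, "solver")
    solver = PDESolveConfig(
        n_nodes=int(sol.get("n_nodes", 100)),
        cfl_safety=float(sol.get("cfl_safety", 0.8)),
        initial_profile=str(sol.get("initial_profile", "zero")),
        initial_value_ppb=float(sol.get("initial_value_ppb", 0.0)),
    )

    mc = dict(raw.get("mcmc") or {})
    _check_keys(mc, _MCMC_KEYS, "mcmc")
    inits = mc.get("inits", DEFAULT_INITS)
    mcmc = MCMCConfig(
        n_chains=int(mc.get("n_chains", len(inits))),
        n_iter=int(mc.get("n_iter", 5000)),
        inits=tuple(tuple(map(float, iv)) for iv in inits),
        sigma_ppb=float(mc.get("sigma_ppb", 5.0)),
        prior_bounds=tuple(map(float, mc.get("prior_bounds", (0.0, 1000.0, 0.0, 50.0)))),
        target_accept=float(mc.get("target_accept", 0.234)),
        seed=int(raw.get("seed", 0)),
        rhat_threshold=float(mc.get("rhat_threshold", 1.1)),
        max_extra_iter=int(mc.get("max_extra_iter", mc.get("n_iter", 5000))),
    )

    pop = dict(raw.get("population") or {})
    _check_keys(pop, _POP_KEYS, "population")
    caw_q = (
        PopulationQuantiles(tuple(pop["caw_probs"]), tuple(pop["caw_values_ppb"]))
        if "caw_probs" in pop
        else CAW_QUANTILES
    )
    ca_q = (
        PopulationQuantiles(tuple(pop["ca_probs"]), tuple(pop["ca_values_ppb"]))
        if "ca_probs" in pop
        else CA_QUANTILES
    )

    return RunConfig(
        geometry=geometry,
        solver=solver,
        mcmc=mcmc,
        caw_quantiles=caw_q,
        ca_quantiles=ca_q,
        scenarios=tuple(raw.get("scenarios", STUDY_SCENARIOS)),
        noise_sd_ppb=float(raw.get("noise_sd_ppb", 5.0)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "fenodyn_out")),
    )


def config_echo(config: RunConfig) -> dict[str, Any]:
    """JSON-serializable snapshot of a run configuration."""

    def as_dict(obj):
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(obj).items()}

    return {
        "geometry": as_dict(config.geometry),
        "solver": as_dict(config.solver),
        "mcmc": as_dict(config.mcmc),
        "scenarios": list(config.scenarios),
        "noise_sd_ppb": config.noise_sd_ppb,
        "seed": config.seed,
        "software_version": __version__,
    }
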