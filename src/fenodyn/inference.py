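"""Bayesian estimation of (C_aw_NO, C_A_NO) from exhalation maneuvers.

The observed NO trace of maneuver ``j`` is modelled as the PDE solution at
the sensor plus iid Gaussian measurement error,

    c~_ij ~ N(c_ij(theta), sigma),        theta = (C_aw_NO, C_A_NO),

with independent maneuvers multiplying their likelihoods.  Priors are
uniform on a bounded box, so the MAP estimator coincides with the bounded
MLE.  The posterior is explored with a Metropolis sampler whose Gaussian
proposal covariance is calibrated on the fly by Vihola's robust adaptive
Metropolis (RAM) recursion; three chains with dispersed initial values are
run and convergence is judged by the Gelman-Rubin potential scale reduction
factor with threshold 1.1, extending the chains once when it is exceeded.

The public surface is :class:`DynamicFeNOEstimator`, a scikit-learn style
estimator (``fit`` on a list of maneuvers, fitted attributes with trailing
underscores, ``get_params``/``set_params`` via ``BaseEstimator``); the
module-level :func:`fit`, :func:`run_mcmc`, :func:`log_likelihood` and
:func:`gelman_rubin` functions are thin wrappers / building blocks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .airway import (
    AirwayGeometry,
    ConcentrationSeries,
    DEFAULT_GEOMETRY,
    Maneuver,
    NOSourceParams,
    PDESolveConfig,
    ValidationError,
    linear_response,
    solve_pde,
)

__all__ = [
    "MCMCConfig",
    "ChainSet",
    "FitResult",
    "DynamicFeNOEstimator",
    "log_likelihood",
    "run_mcmc",
    "gelman_rubin",
    "fit",
    "sigma_sensitivity",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: Default over-dispersed chain initial values (caw, ca) in ppb.
DEFAULT_INITS = ((100.0, 1.0), (200.0, 2.0), (400.0, 4.0))


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    Defaults follow the study protocol: 3 chains of 5,000 iterations started
    at (100, 1), (200, 2) and (400, 4); measurement-error SD sigma = 5 ppb;
    convergence declared at R-hat < 1.1, with one doubling of the chain
    length allowed otherwise.  The prior box [0, 1000] x [0, 50] ppb covers
    the population 97.5th percentiles (439, 3.88 ppb) with wide margin.
    """

    n_chains: int = 3
    n_iter: int = 5000
    inits: tuple[tuple[float, float], ...] = DEFAULT_INITS
    sigma_ppb: float = 5.0
    prior_bounds: tuple[float, float, float, float] = (0.0, 1000.0, 0.0, 50.0)
    target_accept: float = 0.234
    seed: int = 0
    rhat_threshold: float = 1.1
    max_extra_iter: int = 5000

    def __post_init__(self) -> None:
        if self.n_chains != len(self.inits):
            raise ValidationError("n_chains must equal the number of inits")
        if self.n_iter < 2:
            raise ValidationError("n_iter must be >= 2")
        if not self.sigma_ppb > 0:
            raise ValidationError("sigma_ppb must be positive")
        lo_w, hi_w, lo_a, hi_a = self.prior_bounds
        if not (np.isfinite(self.prior_bounds).all() and lo_w < hi_w and lo_a < hi_a):
            raise ValidationError("prior_bounds must be finite with low < high")
        if not 0.0 < self.target_accept < 1.0:
            raise ValidationError("target_accept must lie in (0, 1)")
        for caw, ca in self.inits:
            if not (lo_w <= caw <= hi_w and lo_a <= ca <= hi_a):
                raise ValidationError(f"init ({caw}, {ca}) outside prior bounds")


@dataclass
class ChainSet:
    """Raw MCMC output: one (n_iter, 2) draw array per chain."""

    draws: list[np.ndarray]
    log_post: list[np.ndarray]
    accept_rate: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.draws)

    @property
    def n_iter(self) -> int:
        return int(self.draws[0].shape[0])

    def pooled_post_burn_in(self) -> np.ndarray:
        """Second halves of all chains, stacked (the reporting sample)."""
        half = self.n_iter // 2
        return np.vstack([d[half:] for d in self.draws])


@dataclass(frozen=True)
class FitResult:
    """Posterior summary for one individual x scenario."""

    map_caw_ppb: float
    map_ca_ppb: float
    sd_caw_ppb: float
    sd_ca_ppb: float
    rhat_caw: float
    rhat_ca: float
    ci95_caw_ppb: tuple[float, float]
    ci95_ca_ppb: tuple[float, float]
    converged: bool
    accept_rate: tuple[float, ...]
    n_iter_total: int
    extended: bool
    sigma_ppb: float
    warnings: tuple[str, ...] = ()


def _gaussian_loglik(residuals: np.ndarray, sigma: float) -> float:
    n = residuals.size
    return -0.5 * float(residuals @ residuals) / sigma**2 - n * (
        math.log(sigma) + 0.5 * _LOG_2PI
    )


def log_likelihood(
    maneuvers: Sequence[Maneuver],
    params: NOSourceParams,
    geometry: AirwayGeometry = DEFAULT_GEOMETRY,
    solve_config: PDESolveConfig = PDESolveConfig(),
    sigma_ppb: float = 5.0,
) -> float:
    """Gaussian log-likelihood of the maneuvers at a parameter pair.

    Runs :func:`fenodyn.airway.solve_pde` once per maneuver and sums the
    Normal log-densities of the residuals; independent maneuvers contribute
    additively (product likelihood).
    """
    if len(maneuvers) == 0:
        raise ValidationError("log_likelihood needs at least one maneuver")
    total = 0.0
    for m in maneuvers:
        model = solve_pde(params, geometry, m.flow, solve_config)
        total += _gaussian_loglik(m.concentration.no_ppb - model.no_ppb, sigma_ppb)
    return total


class _LinearizedPosterior:
    """Unnormalized log posterior over the prior box.

    Exploits the affinity of the PDE in (caw, ca): each maneuver is reduced
    to response vectors (A, B, G) with model = caw*A + ca*B + G, so a
    posterior evaluation is a vector operation instead of a PDE solve.  The
    decomposition is exact (see :func:`fenodyn.airway.linear_response`).
    """

    def __init__(self, maneuvers, geometry, solve_config, sigma, bounds,
                 response_cache=None):
        a_list, b_list, r_list = [], [], []
        for m in maneuvers:
            # content-based key: responses depend only on the flow trace
            key = (m.flow.times_s.tobytes(), m.flow.flow_ml_s.tobytes())
            if response_cache is not None and key in response_cache:
                a, b, g = response_cache[key]
            else:
                a, b, g = linear_response(geometry, m.flow, solve_config)
                if response_cache is not None:
                    response_cache[key] = (a, b, g)
            a_list.append(a)
            b_list.append(b)
            r_list.append(m.concentration.no_ppb - g)
        self.a = np.concatenate(a_list)
        self.b = np.concatenate(b_list)
        self.resid0 = np.concatenate(r_list)
        self.sigma = float(sigma)
        self.bounds = bounds
        self.n = self.resid0.size
        self._const = -self.n * (math.log(self.sigma) + 0.5 * _LOG_2PI)

    def in_bounds(self, caw: float, ca: float) -> bool:
        lo_w, hi_w, lo_a, hi_a = self.bounds
        return lo_w <= caw <= hi_w and lo_a <= ca <= hi_a

    def __call__(self, caw: float, ca: float) -> float:
        if not self.in_bounds(caw, ca):
            return -math.inf
        r = self.resid0 - caw * self.a - ca * self.b
        return -0.5 * float(r @ r) / self.sigma**2 + self._const


@dataclass
class _ChainState:
    """Resumable state of one RAM chain (for the extension policy)."""

    theta: np.ndarray
    log_post: float
    chol: np.ndarray  # lower-triangular proposal factor S
    k: int  # adaptation step counter
    rng: np.random.Generator


def _run_chain(
    log_post,
    state: _ChainState,
    n_iter: int,
    target_accept: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Advance one chain n_iter steps with Vihola's RAM adaptation.

    Proposal: theta' = theta + S u, u ~ N(0, I).  After each step the
    Cholesky factor S is updated so that
    S S' <- S (I + eta_k (alpha - alpha*) u u' / |u|^2) S', with step sizes
    eta_k = min(1, 2 k^(-2/3)); out-of-box proposals have alpha = 0 and
    still drive the adaptation (they shrink the proposal).
    """
    draws = np.empty((n_iter, 2))
    lp = np.empty(n_iter)
    theta = state.theta
    cur_lp = state.log_post
    S = state.chol
    rng = state.rng
    n_accept = 0
    for i in range(n_iter):
        state.k += 1
        u = rng.standard_normal(2)
        prop = theta + S @ u
        prop_lp = log_post(prop[0], prop[1])
        if prop_lp == -math.inf:
            alpha = 0.0
        else:
            alpha = min(1.0, math.exp(min(prop_lp - cur_lp, 0.0)))
        if rng.random() < alpha:
            theta = prop
            cur_lp = prop_lp
            n_accept += 1
        draws[i] = theta
        lp[i] = cur_lp
        # RAM rank-one covariance update via 2x2 re-factorization
        eta = min(1.0, 2.0 * state.k ** (-2.0 / 3.0))
        coef = eta * (alpha - target_accept) / float(u @ u)
        Su = S @ u
        M = S @ S.T + coef * np.outer(Su, Su)
        S = _chol2x2(M, fallback=S)
    state.theta = theta
    state.log_post = cur_lp
    state.chol = S
    return draws, lp, n_accept


def _chol2x2(M: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Cholesky of a 2x2 SPD matrix; keep the previous factor if degenerate."""
    a, b, c = M[0, 0], M[1, 0], M[1, 1]
    if a <= 0.0:
        return fallback
    l11 = math.sqrt(a)
    l21 = b / l11
    rest = c - l21 * l21
    if rest <= 0.0:
        return fallback
    return np.array([[l11, 0.0], [l21, math.sqrt(rest)]])


def _initial_chol(config: MCMCConfig) -> np.ndarray:
    # start proposals at ~3% of each prior range; RAM adapts from there
    lo_w, hi_w, lo_a, hi_a = config.prior_bounds
    return np.diag([0.03 * (hi_w - lo_w), 0.03 * (hi_a - lo_a)])


def gelman_rubin(chains: Sequence[np.ndarray], burn_in: float = 0.5) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` holds one 1-d draw sequence per chain; the first ``burn_in``
    fraction of each is discarded.  With m chains of n retained draws,
    within-chain variance W (mean of per-chain sample variances), and
    between-chain variance B = n * Var(chain means),

        R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

    Identical chains give B = 0 hence R-hat = sqrt((n-1)/n) < 1; chains with
    zero within-chain variance return 1.0 by convention (with a warning).
    """
    if len(chains) < 2:
        raise ValidationError("gelman_rubin needs at least two chains")
    kept = []
    for ch in chains:
        ch = np.asarray(ch, dtype=float)
        start = int(math.floor(burn_in * ch.size))
        tail = ch[start:]
        if tail.size < 4:
            raise ValidationError("each chain needs >= 4 post-burn-in draws")
        kept.append(tail)
    n = min(t.size for t in kept)
    kept = np.vstack([t[:n] for t in kept])
    w = float(np.mean(np.var(kept, axis=1, ddof=1)))
    b = n * float(np.var(np.mean(kept, axis=1), ddof=1))
    if w == 0.0:
        warnings.warn("zero within-chain variance; returning R-hat = 1 by convention")
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return math.sqrt(var_hat / w)


class DynamicFeNOEstimator(BaseEstimator):
    """Bayesian dynamic two-compartment FeNO model, scikit-learn style.

    Parameters mirror :class:`MCMCConfig` plus the airway geometry and PDE
    solver controls.  ``fit`` takes a list of :class:`Maneuver` objects (one
    or more exhalations from the same individual on the same occasion) and
    populates the fitted attributes below.

    Attributes
    ----------
    map_caw_ppb_, map_ca_ppb_ : float
        MAP estimates — the stored draw with the highest unnormalized log
        posterior across all chains and iterations (equals the bounded MLE
        under the uniform priors).
    sd_caw_ppb_, sd_ca_ppb_ : float
        Empirical SDs of the pooled post-burn-in (second-half) draws.
    rhat_caw_, rhat_ca_ : float
        Gelman-Rubin statistics on the post-burn-in halves.
    converged_ : bool
        Both R-hat below the threshold after any chain extension.
    result_ : FitResult
        Full posterior summary.
    chains_ : ChainSet
        Raw draws for diagnostics.
    """

    def __init__(
        self,
        geometry: AirwayGeometry = DEFAULT_GEOMETRY,
        solve_config: PDESolveConfig = PDESolveConfig(),
        sigma_ppb: float = 5.0,
        n_chains: int = 3,
        n_iter: int = 5000,
        inits: tuple[tuple[float, float], ...] = DEFAULT_INITS,
        prior_bounds: tuple[float, float, float, float] = (0.0, 1000.0, 0.0, 50.0),
        target_accept: float = 0.234,
        rhat_threshold: float = 1.1,
        max_extra_iter: int = 5000,
        seed: int = 0,
        polish: bool = False,
    ):
        self.geometry = geometry
        self.solve_config = solve_config
        self.sigma_ppb = sigma_ppb
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.inits = inits
        self.prior_bounds = prior_bounds
        self.target_accept = target_accept
        self.rhat_threshold = rhat_threshold
        self.max_extra_iter = max_extra_iter
        self.seed = seed
        self.polish = polish

    def _mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            inits=tuple(tuple(map(float, iv)) for iv in self.inits),
            sigma_ppb=self.sigma_ppb,
            prior_bounds=tuple(map(float, self.prior_bounds)),
            target_accept=self.target_accept,
            seed=self.seed,
            rhat_threshold=self.rhat_threshold,
            max_extra_iter=self.max_extra_iter,
        )

    def fit(self, maneuvers: Sequence[Maneuver], y=None, response_cache=None):
        """Sample the posterior for one individual's maneuvers."""
        if len(maneuvers) == 0:
            raise ValidationError("fit needs at least one maneuver")
        config = self._mcmc_config()
        posterior = _LinearizedPosterior(
            maneuvers, self.geometry, self.solve_config, config.sigma_ppb,
            config.prior_bounds, response_cache,
        )
        chains, states = _sample(posterior, config)
        extended = False
        rhats = _rhats(chains)
        if max(rhats) >= config.rhat_threshold and config.max_extra_iter > 0:
            extra = min(config.max_extra_iter, config.n_iter)
            chains = _extend(posterior, config, chains, states, extra)
            rhats = _rhats(chains)
            extended = True
        self.chains_ = chains
        self.result_ = _summarize(chains, rhats, config, extended)
        if self.polish:
            self._polish(posterior)
        self.map_caw_ppb_ = self.result_.map_caw_ppb
        self.map_ca_ppb_ = self.result_.map_ca_ppb
        self.sd_caw_ppb_ = self.result_.sd_caw_ppb
        self.sd_ca_ppb_ = self.result_.sd_ca_ppb
        self.rhat_caw_ = self.result_.rhat_caw
        self.rhat_ca_ = self.result_.rhat_ca
        self.converged_ = self.result_.converged
        return self

    def _polish(self, posterior: _LinearizedPosterior) -> None:
        """Optional local refinement of the MAP by bounded least squares."""
        from scipy.optimize import lsq_linear

        lo_w, hi_w, lo_a, hi_a = posterior.bounds
        design = np.column_stack([posterior.a, posterior.b])
        sol = lsq_linear(design, posterior.resid0, bounds=([lo_w, lo_a], [hi_w, hi_a]))
        lp = posterior(sol.x[0], sol.x[1])
        best_lp = max(float(np.max(lps)) for lps in self.chains_.log_post)
        if lp > best_lp:
            from dataclasses import replace

            self.result_ = replace(
                self.result_,
                map_caw_ppb=float(sol.x[0]),
                map_ca_ppb=float(sol.x[1]),
            )

    def predict(self, flows) -> list[ConcentrationSeries]:
        """Model NO sensor traces at the MAP estimate for new flow series."""
        params = NOSourceParams(self.map_caw_ppb_, self.map_ca_ppb_)
        return [
            solve_pde(params, self.geometry, fl, self.solve_config) for fl in flows
        ]

    def score(self, maneuvers: Sequence[Maneuver], y=None) -> float:
        """Mean per-observation log-likelihood at the MAP estimate."""
        params = NOSourceParams(self.map_caw_ppb_, self.map_ca_ppb_)
        total = log_likelihood(
            maneuvers, params, self.geometry, self.solve_config, self.sigma_ppb
        )
        n = sum(len(m.flow) for m in maneuvers)
        return total / n


def _sample(posterior, config: MCMCConfig):
    root = np.random.SeedSequence(config.seed)
    substreams = root.spawn(config.n_chains)
    chains_draws, chains_lp, accepts, states = [], [], [], []
    warn_msgs = []
    for c in range(config.n_chains):
        theta0 = np.array(config.inits[c], dtype=float)
        lp0 = posterior(theta0[0], theta0[1])
        if lp0 == -math.inf:
            raise ValidationError(f"initial value {tuple(theta0)} has zero prior density")
        state = _ChainState(
            theta=theta0,
            log_post=lp0,
            chol=_initial_chol(config),
            k=0,
            rng=np.random.default_rng(substreams[c]),
        )
        draws, lp, n_acc = _run_chain(posterior, state, config.n_iter, config.target_accept)
        chains_draws.append(draws)
        chains_lp.append(lp)
        accepts.append(n_acc / config.n_iter)
        states.append(state)
        if accepts[-1] < 0.01:
            warn_msgs.append(f"chain {c}: acceptance rate {accepts[-1]:.3f} < 1%")
    chains = ChainSet(
        draws=chains_draws,
        log_post=chains_lp,
        accept_rate=np.asarray(accepts),
        warnings=warn_msgs,
    )
    return chains, states


def _extend(posterior, config, chains: ChainSet, states, extra: int) -> ChainSet:
    draws, lps, accepts = [], [], []
    for c, state in enumerate(states):
        d2, lp2, n_acc = _run_chain(posterior, state, extra, config.target_accept)
        draws.append(np.vstack([chains.draws[c], d2]))
        lps.append(np.concatenate([chains.log_post[c], lp2]))
        prev_total = chains.accept_rate[c] * chains.n_iter
        accepts.append((prev_total + n_acc) / (chains.n_iter + extra))
    return ChainSet(
        draws=draws,
        log_post=lps,
        accept_rate=np.asarray(accepts),
        warnings=list(chains.warnings),
    )


def _rhats(chains: ChainSet) -> tuple[float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_caw = gelman_rubin([d[:, 0] for d in chains.draws], burn_in=0.5)
        r_ca = gelman_rubin([d[:, 1] for d in chains.draws], burn_in=0.5)
    return r_caw, r_ca


def _summarize(chains: ChainSet, rhats, config: MCMCConfig, extended: bool) -> FitResult:
    all_lp = np.concatenate(chains.log_post)
    all_draws = np.vstack(chains.draws)
    best = int(np.argmax(all_lp))
    pooled = chains.pooled_post_burn_in()
    sds = np.std(pooled, axis=0, ddof=1)
    ci_caw = tuple(np.percentile(pooled[:, 0], [2.5, 97.5]))
    ci_ca = tuple(np.percentile(pooled[:, 1], [2.5, 97.5]))
    r_caw, r_ca = rhats
    return FitResult(
        map_caw_ppb=float(all_draws[best, 0]),
        map_ca_ppb=float(all_draws[best, 1]),
        sd_caw_ppb=float(sds[0]),
        sd_ca_ppb=float(sds[1]),
        rhat_caw=float(r_caw),
        rhat_ca=float(r_ca),
        ci95_caw_ppb=(float(ci_caw[0]), float(ci_caw[1])),
        ci95_ca_ppb=(float(ci_ca[0]), float(ci_ca[1])),
        converged=bool(max(rhats) < config.rhat_threshold),
        accept_rate=tuple(float(a) for a in chains.accept_rate),
        n_iter_total=chains.n_iter,
        extended=extended,
        sigma_ppb=config.sigma_ppb,
        warnings=tuple(chains.warnings),
    )


def sigma_sensitivity(
    maneuvers: Sequence[Maneuver],
    geometry: AirwayGeometry = DEFAULT_GEOMETRY,
    solve_config: PDESolveConfig = PDESolveConfig(),
    mcmc_config: MCMCConfig = MCMCConfig(),
    sigmas: Sequence[float] = (10.0, 15.0),
    response_cache=None,
) -> dict[float, "FitResult"]:
    """Refit with inflated measurement-error SDs and report every fit.

    The assumed sigma affects posterior spread and sampler mixing but not
    the location of the posterior mode, so MAP estimates should be
    essentially unchanged; larger sigmas also lower R-hat, which makes this
    the recommended follow-up for a fit that stays unconverged after chain
    extension.  Returns ``{sigma: FitResult}`` including the original.
    """
    if response_cache is None:
        response_cache = {}
    out = {mcmc_config.sigma_ppb: fit(
        maneuvers, geometry, solve_config, mcmc_config, response_cache
    )}
    for sigma in sigmas:
        cfg = MCMCConfig(
            n_chains=mcmc_config.n_chains,
            n_iter=mcmc_config.n_iter,
            inits=mcmc_config.inits,
            sigma_ppb=float(sigma),
            prior_bounds=mcmc_config.prior_bounds,
            target_accept=mcmc_config.target_accept,
            seed=mcmc_config.seed,
            rhat_threshold=mcmc_config.rhat_threshold,
            max_extra_iter=mcmc_config.max_extra_iter,
        )
        out[float(sigma)] = fit(maneuvers, geometry, solve_config, cfg, response_cache)
    return out


def run_mcmc(
    maneuvers: Sequence[Maneuver],
    geometry: AirwayGeometry = DEFAULT_GEOMETRY,
    solve_config: PDESolveConfig = PDESolveConfig(),
    mcmc_config: MCMCConfig = MCMCConfig(),
    response_cache=None,
) -> ChainSet:
    """Run the adaptive-Metropolis chains and return the raw draws."""
    posterior = _LinearizedPosterior(
        maneuvers, geometry, solve_config, mcmc_config.sigma_ppb,
        mcmc_config.prior_bounds, response_cache,
    )
    chains, _ = _sample(posterior, mcmc_config)
    return chains


def fit(
    maneuvers: Sequence[Maneuver],
    geometry: AirwayGeometry = DEFAULT_GEOMETRY,
    solve_config: PDESolveConfig = PDESolveConfig(),
    mcmc_config: MCMCConfig = MCMCConfig(),
    response_cache=None,
) -> FitResult:
    """Fit one individual: MCMC, convergence check/extension, summary."""
    est = DynamicFeNOEstimator(
        geometry=geometry,
        solve_config=solve_config,
        sigma_ppb=mcmc_config.sigma_ppb,
        n_chains=mcmc_config.n_chains,
        n_iter=mcmc_config.n_iter,
        inits=mcmc_config.inits,
        prior_bounds=mcmc_config.prior_bounds,
        target_accept=mcmc_config.target_accept,
        rhat_threshold=mcmc_config.rhat_threshold,
        max_extra_iter=mcmc_config.max_extra_iter,
        seed=mcmc_config.seed,
    )
    est.fit(maneuvers, response_cache=response_cache)
    return est.result_
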