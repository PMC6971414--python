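"""Tests for the likelihood, RAM sampler, diagnostics and fit summaries."""

import math

import numpy as np
import pytest
from scipy.optimize import lsq_linear
from scipy.stats import norm
from sklearn.base import clone

from fenodyn.airway import (
    ConcentrationSeries,
    DEFAULT_GEOMETRY,
    Maneuver,
    NOSourceParams,
    PDESolveConfig,
    ValidationError,
    constant_flow_series,
    linear_response,
    solve_pde,
)
from fenodyn.inference import (
    DynamicFeNOEstimator,
    MCMCConfig,
    _ChainState,
    _initial_chol,
    _run_chain,
    _sample,
    fit,
    gelman_rubin,
    log_likelihood,
    run_mcmc,
)

from conftest import make_battery


def noiseless_maneuver(params, target=50.0, duration=8.0):
    fl = constant_flow_series(target, duration)
    clean = solve_pde(params, DEFAULT_GEOMETRY, fl)
    return Maneuver(flow=fl, concentration=clean)


class TestLogLikelihood:
    def test_zero_residuals_give_normal_constant(self, median_truth):
        man = noiseless_maneuver(median_truth)
        n = len(man.flow)
        ll = log_likelihood([man], median_truth, sigma_ppb=5.0)
        assert ll == pytest.approx(-n * math.log(5.0 * math.sqrt(2 * math.pi)), rel=1e-12)

    def test_zero_residuals_maximize(self, median_truth):
        man = noiseless_maneuver(median_truth)
        best = log_likelihood([man], median_truth)
        for other in (NOSourceParams(70.0, 2.05), NOSourceParams(58.0, 3.5)):
            assert log_likelihood([man], other) < best

    def test_matches_textbook_gaussian_logpdf(self, median_truth):
        """Residuals (0, 5, -10) at sigma=5 vs an independent Normal log-pdf sum."""
        fl = constant_flow_series(50, 0.2, sample_hz=10)
        clean = solve_pde(median_truth, DEFAULT_GEOMETRY, fl)
        shifted = clean.no_ppb + np.array([0.0, 5.0, -10.0])
        man = Maneuver(flow=fl, concentration=ConcentrationSeries(fl.times_s, shifted))
        expected = float(np.sum(norm.logpdf([0.0, 5.0, -10.0], scale=5.0)))
        assert log_likelihood([man], median_truth, sigma_ppb=5.0) == pytest.approx(
            expected, rel=1e-10
        )

    def test_product_structure_over_maneuvers(self, median_truth):
        man = noiseless_maneuver(median_truth)
        one = log_likelihood([man], NOSourceParams(70.0, 2.0))
        three = log_likelihood([man] * 3, NOSourceParams(70.0, 2.0))
        assert three == pytest.approx(3 * one, rel=1e-12)

    def test_empty_maneuver_list_rejected(self, median_truth):
        with pytest.raises(ValidationError):
            log_likelihood([], median_truth)


BOX = (0.0, 1000.0, 0.0, 50.0)


def run_synthetic_target(log_post, n_iter=8000, seed=5, target_accept=0.234):
    """Drive the RAM chain machinery with an arbitrary 2-d log-density."""
    cfg = MCMCConfig(seed=seed, target_accept=target_accept, prior_bounds=BOX)
    state = _ChainState(
        theta=np.array([300.0, 10.0]),
        log_post=log_post(300.0, 10.0),
        chol=_initial_chol(cfg),
        k=0,
        rng=np.random.default_rng(seed),
    )
    draws, lp, n_acc = _run_chain(
        lambda a, b: log_post(a, b), state, n_iter, target_accept
    )
    return draws, n_acc / n_iter


def flat_log_post(caw, ca):
    lo_w, hi_w, lo_a, hi_a = BOX
    if lo_w <= caw <= hi_w and lo_a <= ca <= hi_a:
        return 0.0
    return -math.inf


class TestRAMSampler:
    def test_flat_target_samples_uniform_box(self):
        """Flat posterior: post-burn-in mean near the box midpoint."""
        draws, _ = run_synthetic_target(flat_log_post, n_iter=20000, seed=5)
        tail = draws[10000:]
        # generous Monte-Carlo bands (correlated draws): 5% of each range
        assert abs(tail[:, 0].mean() - 500.0) < 50.0
        assert abs(tail[:, 1].mean() - 25.0) < 2.5

    def test_gaussian_target_acceptance_near_target(self):
        """RAM calibrates acceptance to ~0.234 on a correlated Gaussian."""

        def log_post(caw, ca):
            if flat_log_post(caw, ca) == -math.inf:
                return -math.inf
            dx = (caw - 500.0) / 50.0
            dy = (ca - 25.0) / 2.0
            return -0.5 * (dx * dx + dy * dy - 1.2 * dx * dy) / (1 - 0.36)

        draws, rate_all = run_synthetic_target(log_post, n_iter=12000, seed=6)
        assert rate_all == pytest.approx(0.234, abs=0.1)

    def test_same_seed_is_bit_identical(self, median_truth):
        man = noiseless_maneuver(median_truth)
        cfg = MCMCConfig(n_iter=300, seed=9)
        c1 = run_mcmc([man], mcmc_config=cfg)
        c2 = run_mcmc([man], mcmc_config=cfg)
        for d1, d2 in zip(c1.draws, c2.draws):
            assert np.array_equal(d1, d2)

    def test_draws_respect_prior_bounds(self, median_truth):
        man = noiseless_maneuver(median_truth)
        cfg = MCMCConfig(n_iter=800, seed=10, prior_bounds=(0.0, 200.0, 0.0, 10.0),
                         inits=((100.0, 1.0), (150.0, 2.0), (50.0, 4.0)))
        chains = run_mcmc([man], mcmc_config=cfg)
        for d in chains.draws:
            assert np.all(d[:, 0] >= 0.0) and np.all(d[:, 0] <= 200.0)
            assert np.all(d[:, 1] >= 0.0) and np.all(d[:, 1] <= 10.0)

    def test_chains_start_at_configured_inits_posterior(self, median_truth):
        man = noiseless_maneuver(median_truth)
        chains = run_mcmc([man], mcmc_config=MCMCConfig(n_iter=50, seed=3))
        assert chains.n_chains == 3


class TestGelmanRubin:
    def test_identical_chains_limit(self):
        """Copies of one sequence: B = 0, R-hat = sqrt((n-1)/n)."""
        seq = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 2.5, 3.5])
        r = gelman_rubin([seq, seq, seq], burn_in=0.0)
        n = seq.size
        assert r == pytest.approx(math.sqrt((n - 1) / n), rel=1e-12)

    def test_hand_computed_two_chains(self):
        """Spreadsheet oracle: W, B, R-hat from explicit arithmetic."""
        c1 = np.array([1.0, 2.0, 3.0, 4.0])
        c2 = np.array([2.0, 4.0, 6.0, 8.0])
        # within-chain variances (ddof=1): 5/3 and 20/3 -> W = 25/6
        # chain means 2.5, 5.0 -> var of means = 3.125 -> B = 4 * 3.125 = 12.5
        # var_hat = 3/4 * 25/6 + 12.5/4 = 25/8 + 25/8 = 25/4
        # R-hat = sqrt((25/4) / (25/6)) = sqrt(1.5)
        w = (5 / 3 + 20 / 3) / 2
        b = 4 * float(np.var([2.5, 5.0], ddof=1))
        expected = math.sqrt(((3 / 4) * w + b / 4) / w)
        assert expected == pytest.approx(math.sqrt(1.5), rel=1e-12)
        assert gelman_rubin([c1, c2], burn_in=0.0) == pytest.approx(expected, rel=1e-10)

    def test_independent_chains_approach_one(self):
        rng = np.random.default_rng(0)
        chains = [rng.normal(size=20000) for _ in range(3)]
        assert gelman_rubin(chains, burn_in=0.5) == pytest.approx(1.0, abs=0.01)

    def test_zero_variance_convention(self):
        with pytest.warns(UserWarning, match="zero within-chain variance"):
            assert gelman_rubin([np.ones(8), np.ones(8)], burn_in=0.0) == 1.0

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValidationError):
            gelman_rubin([np.arange(8.0)])


class TestFit:
    def test_map_is_best_visited_draw(self, median_truth, quick_mcmc):
        """Uniform priors: MAP = the stored draw with max log posterior."""
        man = noiseless_maneuver(median_truth)
        est = DynamicFeNOEstimator(n_iter=quick_mcmc.n_iter, seed=quick_mcmc.seed)
        est.fit([man])
        all_lp = np.concatenate(est.chains_.log_post)
        all_draws = np.vstack(est.chains_.draws)
        best = all_draws[np.argmax(all_lp)]
        assert est.map_caw_ppb_ == best[0]
        assert est.map_ca_ppb_ == best[1]

    def test_no_extension_when_converged(self, median_truth, quick_mcmc):
        man = noiseless_maneuver(median_truth)
        res = fit([man], mcmc_config=MCMCConfig(n_iter=2000, seed=4))
        if res.converged:
            assert not res.extended
            assert res.n_iter_total == 2000

    def test_map_matches_constrained_least_squares(self, battery, geometry):
        """Gaussian likelihood is linear in theta: box-constrained LS oracle."""
        est = DynamicFeNOEstimator(seed=12).fit(battery)
        a, b, g = [], [], []
        for m in battery:
            ai, bi, gi = linear_response(geometry, m.flow)
            a.append(ai), b.append(bi), g.append(m.concentration.no_ppb - gi)
        X = np.column_stack([np.concatenate(a), np.concatenate(b)])
        y = np.concatenate(g)
        sol = lsq_linear(X, y, bounds=([0.0, 0.0], [1000.0, 50.0]))
        assert est.map_caw_ppb_ == pytest.approx(sol.x[0], abs=0.5 * est.sd_caw_ppb_)
        assert est.map_ca_ppb_ == pytest.approx(sol.x[1], abs=0.5 * est.sd_ca_ppb_)

    def test_polish_lands_on_least_squares_solution(self, battery, geometry):
        est = DynamicFeNOEstimator(seed=12, n_iter=1500, polish=True).fit(battery)
        a, b, g = [], [], []
        for m in battery:
            ai, bi, gi = linear_response(geometry, m.flow)
            a.append(ai), b.append(bi), g.append(m.concentration.no_ppb - gi)
        X = np.column_stack([np.concatenate(a), np.concatenate(b)])
        sol = lsq_linear(X, np.concatenate(g), bounds=([0.0, 0.0], [1000.0, 50.0]))
        assert est.result_.map_caw_ppb == pytest.approx(sol.x[0], abs=1e-3)
        assert est.result_.map_ca_ppb == pytest.approx(sol.x[1], abs=1e-3)

    def test_map_inside_own_credible_interval(self, median_truth, geometry):
        """Calibration: the MAP falls inside the fit's central 99% interval."""
        rng = np.random.default_rng(77)
        flows = [m.flow for m in make_battery(median_truth, geometry, seed=1)]
        cache: dict = {}
        for rep in range(5):
            mans = []
            for flw in flows:
                clean = solve_pde(median_truth, geometry, flw)
                no = clean.no_ppb + rng.normal(0, 5.0, clean.no_ppb.size)
                mans.append(Maneuver(flw, ConcentrationSeries(flw.times_s, no)))
            est = DynamicFeNOEstimator(n_iter=1500, seed=100 + rep)
            est.fit(mans, response_cache=cache)
            pooled = est.chains_.pooled_post_burn_in()
            lo_w, hi_w = np.percentile(pooled[:, 0], [0.5, 99.5])
            lo_a, hi_a = np.percentile(pooled[:, 1], [0.5, 99.5])
            assert lo_w <= est.map_caw_ppb_ <= hi_w
            assert lo_a <= est.map_ca_ppb_ <= hi_a

    def test_sklearn_estimator_protocol(self):
        est = DynamicFeNOEstimator(sigma_ppb=10.0, n_iter=123)
        params = est.get_params()
        assert params["sigma_ppb"] == 10.0
        est2 = clone(est)
        assert est2.get_params()["n_iter"] == 123
        est2.set_params(seed=42)
        assert est2.seed == 42

    def test_predict_returns_model_traces(self, median_truth, quick_mcmc):
        man = noiseless_maneuver(median_truth)
        est = DynamicFeNOEstimator(n_iter=quick_mcmc.n_iter, seed=1).fit([man])
        pred = est.predict([man.flow])
        assert len(pred) == 1
        assert len(pred[0]) == len(man.flow)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            MCMCConfig(n_chains=2)  # three inits by default
        with pytest.raises(ValidationError):
            MCMCConfig(sigma_ppb=0.0)
        with pytest.raises(ValidationError):
            MCMCConfig(inits=((2000.0, 1.0), (1.0, 1.0), (1.0, 2.0)))
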