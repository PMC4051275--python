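import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ratedomain import sequential as sq
from ratedomain import synthetic as sy

AR = np.array([0.222, 0.104, 0.076])


def _ar_series(weights, n, seed, mu=0.0, sigma=1.0):
    cp = sy.ConditionParams(mu_u=mu, sigma_u=sigma, error_rate=0.0)
    return sy.generate_block_rates(cp, weights, n, seed=seed,
                                   truncation_bound=-np.inf)[1]


class TestPacf:
    def test_white_noise_within_band(self):
        x = np.random.default_rng(1).normal(size=10_010)
        coeffs = sq.pacf(x, max_lag=20, skip_initial=10)
        assert np.all(np.abs(coeffs) < 3 / np.sqrt(10_000))

    def test_ar1_signature(self):
        x = _ar_series((0.5,), 50_010, seed=2)
        coeffs = sq.pacf(x, max_lag=10)
        assert coeffs[0] == pytest.approx(0.5, abs=0.02)
        assert np.all(np.abs(coeffs[1:]) < 4 / np.sqrt(50_000))

    def test_ar3_printed_weights_lag1(self):
        # Yule-Walker gives rho_1 = PACF(1) = 0.263 for the study weights
        x = _ar_series(AR, 100_010, seed=3)
        rho1 = sq.yule_walker_autocorrelations(AR, 1)[0]
        assert rho1 == pytest.approx(0.2632, abs=1e-4)
        assert sq.pacf(x, max_lag=5)[0] == pytest.approx(
            rho1, abs=3 / np.sqrt(100_000))

    def test_too_short_raises(self):
        with pytest.raises(sq.InsufficientDataError):
            sq.pacf(np.zeros(35), max_lag=20, skip_initial=10)


class TestShuffleControl:
    def test_kills_dependency_and_preserves_histogram(self):
        blocks = [_ar_series(AR, 2000, seed=s) for s in range(8)]
        res = sq.shuffle_control(blocks, seed=4)
        n_eff = 1990
        band = 3 / np.sqrt(n_eff) + 3 * res.stderr
        assert np.all(np.abs(res.coefficients) < band)
        # a permutation cannot change the marginal distribution
        rng = np.random.default_rng(9)
        assert sorted(rng.permutation(blocks[0])) == sorted(blocks[0])

    def test_seeded_reproducibility(self):
        blocks = [_ar_series(AR, 500, seed=s) for s in range(3)]
        a = sq.shuffle_control(blocks, seed=7).coefficients
        b = sq.shuffle_control(blocks, seed=7).coefficients
        assert np.array_equal(a, b)


class TestFitAR:
    def test_ar1_recovery(self):
        x = _ar_series((0.5,), 50_010, seed=5)
        m = sq.fit_ar_ml([x], order=1)
        assert m.weights[0] == pytest.approx(0.5, abs=0.01)

    def test_iid_input_gives_null_weights(self):
        blocks = [np.random.default_rng(s).normal(size=2000)
                  for s in range(5)]
        m = sq.fit_ar_ml(blocks, order=6)
        assert np.all(np.abs(m.weights) < 2.5 * m.stderr + 1e-3)

    def test_study_scale_recovery(self):
        rng = np.random.default_rng(6)
        cp = sy.ConditionParams(2.0, 0.3, 0.0)
        blocks = [sy.generate_block_rates(cp, AR, 200, rng=rng)[1]
                  for _ in range(96)]
        m = sq.fit_ar_ml(blocks, order=6)
        assert np.allclose(m.weights[:3], AR, atol=0.03)
        assert np.all(np.abs(m.weights[3:]) < 0.03)
        assert m.mu_u == pytest.approx(2.0, abs=0.1)
        assert m.sigma_u == pytest.approx(0.3, rel=0.05)

    def test_exact_likelihood_option_agrees(self):
        x = _ar_series((0.4,), 5010, seed=8, mu=1.0, sigma=0.5)
        cond = sq.fit_ar_ml([x], order=1).weights[0]
        exact = sq.fit_ar_ml([x], order=1, method="exact").weights[0]
        assert exact == pytest.approx(cond, abs=0.01)


class TestDecorrelate:
    def test_zero_weights_identity(self):
        x = np.arange(20.0)
        m = sq.ARModel(np.zeros(3))
        assert np.array_equal(sq.decorrelate(x, m), x)

    def test_exact_input_recovery(self):
        cp = sy.ConditionParams(1.0, 0.4, 0.0)
        rng = np.random.default_rng(10)
        u = rng.normal(1.0, 0.4, 500)
        r = np.empty(500)
        for n in range(500):
            r[n] = sum(AR[j] * r[n - 1 - j] for j in range(min(n, 3))) + u[n]
        got = sq.decorrelate(r, sq.ARModel(AR))
        assert np.nanmax(np.abs(got[3:] - u[3:])) < 1e-10
        assert np.all(np.isnan(got[:3]))

    def test_residuals_are_white(self):
        blocks = [_ar_series(AR, 2000, seed=s) for s in range(10)]
        m = sq.ARModel(AR)
        resid = [sq.decorrelate(b, m)[3:] for b in blocks]
        res = sq.pacf_blocks(resid)
        assert np.all(np.abs(res.coefficients) < 3 / np.sqrt(1990) +
                      3 * res.stderr)


class TestArToMa:
    def test_geometric_closed_form(self):
        ma = sq.ar_to_ma(sq.ARModel([0.5]))
        i = np.arange(len(ma.b))
        assert np.allclose(ma.b, 0.5**i, atol=1e-12)

    def test_zero_weights(self):
        ma = sq.ar_to_ma(sq.ARModel(np.zeros(2)))
        assert np.array_equal(ma.b, [1.0])
        assert ma.mean_gain == 1.0 and ma.sd_gain == 1.0

    def test_printed_weights_leading_terms(self):
        ma = sq.ar_to_ma(sq.ARModel(AR))
        assert ma.b[0] == 1.0
        assert np.round(ma.b[1:4], 4).tolist() == [0.2220, 0.1533, 0.1331]

    def test_matches_recursion_oracle_to_200_terms(self):
        ma = sq.ar_to_ma(sq.ARModel(AR), tol=0.0, max_len=200)
        brute = sq.ma_weights_recursion(AR, len(ma.b))
        assert np.max(np.abs(ma.b - brute)) < 1e-10

    def test_complex_pole_pair_gives_real_weights(self):
        # z^2 - 0.5 z + 0.7 has complex roots inside the unit circle
        ma = sq.ar_to_ma(sq.ARModel([0.5, -0.7]))
        assert np.isrealobj(ma.b)
        brute = sq.ma_weights_recursion([0.5, -0.7], len(ma.b))
        assert np.max(np.abs(ma.b - brute)) < 1e-10

    def test_unstable_rejected(self):
        with pytest.raises(sq.InstabilityError):
            sq.ar_to_ma(sq.ARModel([1.2]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-0.3, 0.3), min_size=1, max_size=4))
    def test_property_recursion_and_gain_identities(self, weights):
        # sum |a_j| < 1.2*0.3*4 not guaranteed stable; filter
        w = np.array(weights)
        if np.sum(np.abs(w)) >= 0.95:
            return
        ma = sq.ar_to_ma(sq.ARModel(w))
        brute = sq.ma_weights_recursion(w, len(ma.b))
        assert np.max(np.abs(ma.b - brute)) < 1e-10
        total = sq.ma_weights_recursion(w, 2000).sum()
        assert total == pytest.approx(1.0 / (1.0 - w.sum()), abs=1e-8)


class TestGainsAndStep:
    def test_printed_gain_values(self):
        ma = sq.ar_to_ma(sq.ARModel(AR))
        mean_gain, sd_gain = sq.steady_state_gains(ma)
        assert round(mean_gain, 2) == 1.67
        assert round(sd_gain, 2) == 1.05

    def test_sd_gain_yule_walker_identity(self):
        # sigma_r^2 / sigma_u^2 = 1 / (1 - sum a_j rho_j)
        ma = sq.ar_to_ma(sq.ARModel(AR))
        rho = sq.yule_walker_autocorrelations(AR, 3)
        yw = 1.0 / np.sqrt(1.0 - np.dot(AR, rho))
        assert ma.sd_gain == pytest.approx(yw, abs=1e-6)

    def test_step_response_shape(self):
        ma = sq.ar_to_ma(sq.ARModel(AR))
        step = sq.step_response(ma, 40)
        assert step[0] == 1.0
        assert np.all(np.diff(step) >= 0)
        assert step[-1] == pytest.approx(ma.mean_gain, abs=1e-6)
        # the start-of-block transient is over within 10 trials
        assert step[8] >= 0.99 * ma.mean_gain

    def test_empty_weights_unit_gains(self):
        ma = sq.ar_to_ma(sq.ARModel([]))
        assert sq.steady_state_gains(ma) == (1.0, 1.0)


class TestSteadyStateDensity:
    def test_normal_input_shifts_with_gain(self):
        ma = sq.ar_to_ma(sq.ARModel(AR))
        mu_out = ma.mean_gain * 2.0
        sd_out = ma.sd_gain * 0.3
        grid = np.linspace(mu_out - 8 * sd_out, mu_out + 8 * sd_out, 4096)
        dens = sq.steady_state_density(
            lambda x: stats.norm.pdf(x, 2.0, 0.3), ma, grid)
        mean = np.trapezoid(grid * dens, grid)
        sd = np.sqrt(np.trapezoid((grid - mean) ** 2 * dens, grid))
        assert mean == pytest.approx(mu_out, abs=2e-3)
        assert sd == pytest.approx(sd_out, abs=2e-3)

    def test_truncated_input_smoothed_to_zero_at_origin(self):
        # a zero-truncated Normal input has positive density at 0, but the
        # stationary output density vanishes there exactly
        ma = sq.ar_to_ma(sq.ARModel(AR))
        grid = np.linspace(0.0, 3.0, 4096)
        half = lambda x: np.where(x >= 0, 2 * stats.norm.pdf(x, 0.0, 0.3), 0.0)
        dens = sq.steady_state_density(half, ma, grid)
        assert half(0.0) > 1.0
        assert dens[0] == 0.0
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_single_term_identity(self):
        ma = sq.MASystem(np.array([1.0]), np.array([]), np.array([]), 1.0, 1.0)
        grid = np.linspace(0.5, 3.5, 4096)
        dens = sq.steady_state_density(
            lambda x: stats.norm.pdf(x, 2.0, 0.3), ma, grid)
        assert np.max(np.abs(dens - stats.norm.pdf(grid, 2.0, 0.3))) < 1e-4

    def test_matches_monte_carlo_stationary_draws(self):
        # independent stationary draws r = sum_i b_i u_i vs the numeric density
        ma = sq.ar_to_ma(sq.ARModel(AR))
        rng = np.random.default_rng(12)
        n = 100_000
        u = np.abs(rng.normal(0.0, 0.3, size=(len(ma.b), n)))  # half-Normal
        r = ma.b @ u
        grid = np.linspace(0.0, 3.0, 8192)
        half = lambda x: np.where(x >= 0, 2 * stats.norm.pdf(x, 0.0, 0.3), 0.0)
        dens = sq.steady_state_density(half, ma, grid)
        edges = np.quantile(r, np.linspace(0.005, 0.995, 31))
        obs, _ = np.histogram(r, edges)
        from scipy.integrate import cumulative_trapezoid
        cdf = np.concatenate(([0.0], cumulative_trapezoid(dens, grid)))
        expect = n * np.diff(np.interp(edges, grid, cdf))
        chi2 = np.sum((obs - expect) ** 2 / expect)
        assert stats.chi2.sf(chi2, len(obs) - 1) > 0.01

    def test_coarse_grid_rejected(self):
        ma = sq.ar_to_ma(sq.ARModel(AR))
        grid = np.linspace(3.0, 3.7, 64)  # far too narrow for the output
        with pytest.raises(ValueError):
            sq.steady_state_density(
                lambda x: stats.norm.pdf(x, 2.0, 0.3), ma, grid)


class TestSpatialCode:
    @pytest.mark.parametrize("trans,code", [
        ("RRRR", 0), ("RRAR", 2), ("AARA", 13), ("AAAA", 15), ("RRRA", 1),
        ("ARRA", 9), ("AAAR", 14),
    ])
    def test_transition_codes(self, trans, code):
        assert sq.transitions_code(trans) == code
        # build an explicit side sequence realizing the transitions
        sides = ["L"]
        for ch in trans:
            sides.append(sides[-1] if ch == "R" else
                         ("R" if sides[-1] == "L" else "L"))
        assert sq.spatial_code(sides) == code

    def test_side_sequences(self):
        assert sq.spatial_code("LLLLL") == 0          # all repeats
        assert sq.spatial_code("LRLRL") == 15         # all alternations
        assert sq.spatial_code("RRRRR") == 0

    def test_history_length_enforced(self):
        with pytest.raises(ValueError):
            sq.spatial_code("LRLR")

    @settings(max_examples=32, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("LR"), min_size=5, max_size=5))
    def test_code_range_and_flip_invariance(self, sides):
        # codes live in 0..15 and depend only on transitions, so a global
        # left/right flip leaves the code unchanged
        c = sq.spatial_code(sides)
        assert 0 <= c <= 15
        flipped = ["R" if s == "L" else "L" for s in sides]
        assert sq.spatial_code(flipped) == c


class TestSpatialSummary:
    def test_recovers_injected_effect(self, experiment_table):
        sp = sq.spatial_summary(experiment_table)
        assert sp.p_value < 0.001
        flagged = [1, 9, 14]
        others = [c for c in range(16) if c not in flagged]
        t = sp.table["mean_rate"]
        assert t[flagged].mean() < t[others].mean() - 0.05

    def test_counts_reconcile(self, experiment_table):
        sp = sq.spatial_summary(experiment_table)
        assert sp.table["count"].sum() == sp.n_trials
        assert sp.df_effect == 15

    def test_null_case_not_significant(self):
        cfg = sy.SynthConfig(n_subjects=10, spatial_deltas={}, seed=21)
        sp = sq.spatial_summary(sy.generate_experiment(cfg))
        assert sp.p_value > 0.01
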