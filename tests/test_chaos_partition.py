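import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edmchaos.chaos_partition import (
    classify_fit,
    lyapunov_from_horizons,
    lyapunov_stepwise,
    lyapunov_stepwise_mean,
    partition_error,
    partition_series,
)
from edmchaos.errors import InsufficientDataError, ValidationError
from edmchaos.synthetic_data import simulate_map, simulate_var1


class TestLyapunovRegression:
    def test_exact_exponential_recovers_rate(self):
        tps = np.arange(1, 11)
        est = lyapunov_from_horizons(np.exp(0.5 * tps), tps)
        assert est.lam == pytest.approx(0.5, abs=1e-12)
        assert est.p_value < 1e-10

    def test_constant_mae_gives_zero_slope(self):
        est = lyapunov_from_horizons([0.3] * 6)
        assert est.lam == 0.0
        assert est.p_value == 1.0

    def test_zero_mae_horizons_dropped(self):
        with pytest.warns(UserWarning):
            est = lyapunov_from_horizons([0.0, np.e, np.e**2], [1, 2, 3])
        assert est.n_horizons == 2
        assert est.lam == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(InsufficientDataError), pytest.warns(UserWarning):
            lyapunov_from_horizons([0.0, 0.0, 1.0])


class TestLyapunovStepwise:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [(1.0, 2.0, np.log(2)), (0.5, 0.5, 0.0), (2.0, 1.0, -np.log(2))],
    )
    def test_doubling_constant_halving(self, r1, r2, expected):
        assert lyapunov_stepwise(r1, r2) == pytest.approx(expected)

    def test_sequence_mean(self):
        # rmse doubling each step: every per-step rate is log 2
        assert lyapunov_stepwise_mean([1, 2, 4, 8]) == pytest.approx(np.log(2))

    def test_nonpositive_rmse_rejected(self):
        with pytest.raises(ValidationError):
            lyapunov_stepwise(0.0, 1.0)


class TestPartitionError:
    def test_negative_lambda_forces_zero_chaos(self):
        p = partition_error(1.0, 0.5, -0.3)
        assert p.frac_chaos == 0.0
        assert p.frac_nonlinearity == pytest.approx(0.5)
        assert p.frac_stochasticity == pytest.approx(0.5)

    def test_theta0_optimal_means_no_nonlinearity(self):
        p = partition_error(1.0, 1.0, 0.2)
        assert p.frac_nonlinearity == 0.0

    def test_large_lambda_limit_chaos_absorbs_best(self):
        p = partition_error(1.0, 0.4, 50.0)
        assert p.frac_chaos == pytest.approx(0.4, abs=1e-9)
        assert p.frac_stochasticity == pytest.approx(0.0, abs=1e-9)

    def test_best_above_total_is_floored_and_flagged(self):
        p = partition_error(1.0, 1.2, -1.0)
        assert "best_exceeds_total" in p.flags
        assert p.frac_nonlinearity == 0.0

    def test_chaos_formula_variants(self):
        lam = 0.5
        pp = partition_error(1.0, 0.5, lam, chaos_formula="printed")
        ps = partition_error(1.0, 0.5, lam, chaos_formula="squared")
        assert pp.frac_chaos == pytest.approx(0.5 * (1 - np.exp(-lam)))
        assert ps.frac_chaos == pytest.approx(0.5 * (1 - np.exp(-2 * lam)))

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValidationError):
            partition_error(0.0, 0.0, 0.1)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        total=st.floats(1e-6, 1e3),
        best_frac=st.floats(0, 1.5),
        lam=st.floats(-3, 3),
    )
    def test_fractions_always_valid(self, total, best_frac, lam):
        p = partition_error(total, total * best_frac, lam)
        fr = (p.frac_nonlinearity, p.frac_chaos, p.frac_stochasticity)
        assert all(0 <= f <= 1 for f in fr)
        assert sum(fr) == pytest.approx(1.0, abs=1e-9)
        if lam < 0:
            assert p.frac_chaos == 0.0

    def test_chaos_fraction_monotone_in_lambda(self):
        lams = np.linspace(-1, 3, 25)
        fracs = [partition_error(1.0, 0.5, l).frac_chaos for l in lams]
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestPartitionSeries:
    def test_linear_var_series_has_no_nonlinearity_or_chaos(self):
        s = simulate_var1([[0.7, -0.2], [0.1, 0.6]], noise_sd=0.05, n=400,
                          seed=8)
        p = partition_series(s, mode="multivariate", target_species="x1",
                             theta_grid=(0.0, 0.5, 1.0, 2.0))
        assert p.frac_nonlinearity < 0.1
        # multi-step error accumulation gives any stochastic process a
        # positive lambda_est, so some error lands in the chaos share even
        # for a linear system; stochasticity must still dominate
        assert p.frac_stochasticity > p.frac_chaos
        assert p.frac_stochasticity > 0.5

    def test_noise_increases_stochasticity_fraction(self):
        # expectation over seeds: more process noise, larger noise share
        lo, hi = [], []
        for seed in range(20):
            for sig, acc in ((0.0, lo), (0.2, hi)):
                s = simulate_map("ricker", r=3.0, sigma=sig, n_steps=80,
                                 seed=seed)
                acc.append(partition_series(
                    s, theta_grid=(0.0, 0.5, 2.0), E_grid=(1, 2, 3)
                ).frac_stochasticity)
        assert np.mean(hi) > np.mean(lo)

    def test_deterministic_chaos_dominates_stochasticity(self):
        s = simulate_map("ricker", r=3.0, sigma=0.0, n_steps=150, seed=0)
        p = partition_series(s)
        assert p.lambda_est > 0
        assert p.frac_chaos > p.frac_stochasticity


class TestClassifyFit:
    @pytest.mark.parametrize(
        "mae,sd,label",
        [
            (0.0, 1.0, "good"),
            (0.49, 1.0, "good"),
            (0.51, 1.0, "poor"),
            (0.5, 1.0, "poor"),   # boundary is strict
        ],
    )
    def test_threshold(self, mae, sd, label):
        c = classify_fit(mae, sd)
        assert c.label == label
        assert c.standardized_mae == pytest.approx(mae / sd)

    def test_zero_sd_undefined(self):
        c = classify_fit(0.1, 0.0)
        assert c.label == "undefined"
        assert np.isnan(c.standardized_mae)
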