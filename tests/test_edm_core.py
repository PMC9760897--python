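import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_simplex, brute_smap

from edmchaos.edm_core import (
    EmbeddedBlock,
    EmbeddingSpec,
    embed,
    goodness_of_fit,
    select_E,
    select_theta,
    simplex_forecast,
    smap_forecast,
)
from edmchaos.errors import (
    InsufficientDataError,
    SingularFitError,
    ValidationError,
)
from conftest import random_block


class TestEmbed:
    def test_univariate_row_count(self, make_univariate):
        s = make_univariate(np.arange(10))
        b = embed(s, EmbeddingSpec(E=2, tau=1, tp=1))
        assert len(b) == 8
        # row = (x(t), x(t-1)), target = x(t+1)
        np.testing.assert_array_equal(b.rows[0], [1, 0])
        assert b.targets[0] == 2

    def test_E1_rows_are_scalars(self, make_univariate):
        s = make_univariate([3, 1, 4, 1, 5])
        b = embed(s, EmbeddingSpec(E=1, tp=1))
        np.testing.assert_array_equal(b.rows[:, 0], [3, 1, 4, 1])
        np.testing.assert_array_equal(b.targets, [1, 4, 1, 5])

    def test_multivariate_block_dimension(self, make_series):
        s = make_series([1, 2, 3, 4], [5, 6, 7, 8])
        b = embed(s, EmbeddingSpec(E=2, tp=1, mode="multivariate",
                                   target_species="prey"))
        assert b.dim == 2
        np.testing.assert_array_equal(b.rows[0], [1, 5])
        np.testing.assert_array_equal(b.targets, [2, 3, 4])

    def test_too_short_raises(self, make_univariate):
        s = make_univariate([1, 2, 3])
        with pytest.raises(InsufficientDataError):
            embed(s, EmbeddingSpec(E=4, tp=1))


class TestSimplex:
    def test_exact_match_returns_its_target(self):
        lib = EmbeddedBlock(rows=[[0.0], [1.0], [2.0], [3.0]],
                            targets=[10, 20, 30, 40],
                            row_times=[0, 1, 2, 3])
        q = EmbeddedBlock(rows=[[1.0]], targets=[0.0], row_times=[99])
        f, _diag = simplex_forecast(lib, q)
        # d1 = 0: zero-distance neighbors averaged equally
        assert f[0] == 20

    def test_equidistant_neighbors_average_equally(self):
        lib = EmbeddedBlock(rows=[[0.0], [2.0], [10.0]],
                            targets=[5.0, 7.0, 100.0],
                            row_times=[0, 1, 2])
        q = EmbeddedBlock(rows=[[1.0]], targets=[0.0], row_times=[99])
        f, _ = simplex_forecast(lib, q)
        assert f[0] == pytest.approx(6.0, abs=1e-12)

    def test_matches_bruteforce_on_logistic_map(self):
        x = np.empty(36)
        x[0] = 0.31
        for t in range(35):
            x[t + 1] = 3.9 * x[t] * (1 - x[t])
        lib = EmbeddedBlock(rows=x[:30, None], targets=x[1:31],
                            row_times=np.arange(30.0))
        q = EmbeddedBlock(rows=x[30:35, None], targets=x[31:36],
                          row_times=30.0 + np.arange(5.0))
        f, _ = simplex_forecast(lib, q)
        ref = brute_simplex(lib.rows, lib.targets, lib.row_times,
                            q.rows, q.row_times)
        np.testing.assert_allclose(f, ref, atol=1e-12)

    def test_too_few_library_rows(self):
        lib = EmbeddedBlock(rows=[[0.0], [1.0]], targets=[1, 2],
                            row_times=[0, 1])
        q = EmbeddedBlock(rows=[[0.5]], targets=[0.0], row_times=[9])
        with pytest.raises(InsufficientDataError):
            simplex_forecast(lib, EmbeddedBlock(rows=[[0.5]], targets=[0.0],
                                                row_times=[0]),
                             exclude_same_time=True)
        # 2 rows with dim 1 is exactly E+1: works without exclusion
        simplex_forecast(lib, q)


class TestSMap:
    def test_theta0_equals_global_ols(self, make_univariate):
        rng = np.random.default_rng(3)
        lib, q = random_block(rng, 40, 2, n_queries=7, times_offset=100)
        fit = smap_forecast(lib, q, 0.0)
        X = np.column_stack([lib.rows, np.ones(len(lib))])
        beta = np.linalg.lstsq(X, lib.targets, rcond=None)[0]
        ols = np.column_stack([q.rows, np.ones(len(q))]) @ beta
        np.testing.assert_allclose(fit.forecasts, ols, atol=1e-10)

    def test_exact_linear_map_recovered_any_theta(self):
        x = np.linspace(0, 5, 30) ** 1.3  # irregular spacing in state space
        y = 0.5 * x + 2
        lib = EmbeddedBlock(rows=x[:, None], targets=y,
                            row_times=np.arange(30.0))
        q = EmbeddedBlock(rows=np.array([[1.7], [4.2]]),
                          targets=0.5 * np.array([1.7, 4.2]) + 2,
                          row_times=[100, 101])
        for theta in (0.0, 0.5, 3.0):
            fit = smap_forecast(lib, q, theta)
            np.testing.assert_allclose(fit.coefficients[:, 0], 0.5, atol=1e-8)
            np.testing.assert_allclose(fit.coefficients[:, 1], 2.0, atol=1e-8)
            np.testing.assert_allclose(fit.forecasts, q.targets, atol=1e-8)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        lib, q = random_block(rng, 25, 2, n_queries=6, times_offset=50)
        for theta in (0.0, 0.7, 2.5):
            fit = smap_forecast(lib, q, theta)
            ref_f, ref_c = brute_smap(lib.rows, lib.targets, lib.row_times,
                                      q.rows, q.row_times, theta)
            np.testing.assert_allclose(fit.forecasts, ref_f, atol=1e-12)
            np.testing.assert_allclose(fit.coefficients, ref_c, atol=1e-10)

    def test_degenerate_design_raises(self):
        lib = EmbeddedBlock(rows=np.ones((10, 1)), targets=np.arange(10.0),
                            row_times=np.arange(10.0))
        q = EmbeddedBlock(rows=[[1.0]], targets=[0.0], row_times=[99])
        with pytest.raises(SingularFitError):
            smap_forecast(lib, q, 1.0)

    def test_leave_one_out_equals_manual_removal(self):
        rng = np.random.default_rng(5)
        lib = random_block(rng, 20, 2)
        full = smap_forecast(lib, lib, 1.0, exclude_same_time=True)
        for i in (0, 7, 19):
            keep = np.arange(20) != i
            sub = EmbeddedBlock(rows=lib.rows[keep], targets=lib.targets[keep],
                                row_times=lib.row_times[keep])
            qi = EmbeddedBlock(rows=lib.rows[[i]], targets=lib.targets[[i]],
                               row_times=lib.row_times[[i]])
            manual = smap_forecast(sub, qi, 1.0)
            assert manual.forecasts[0] == pytest.approx(full.forecasts[i],
                                                        abs=1e-12)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    n=st.integers(8, 50),
    dim=st.integers(1, 3),
    theta=st.sampled_from([0.0, 0.5, 2.0]),
    seed=st.integers(0, 10_000),
)
def test_forecasters_match_bruteforce_property(n, dim, theta, seed):
    """Both forecasters agree with explicit-loop re-implementations on
    random instances (oracle equivalence)."""
    rng = np.random.default_rng(seed)
    lib = EmbeddedBlock(rows=rng.uniform(-1, 1, (n, dim)),
                        targets=rng.uniform(-1, 1, n),
                        row_times=np.arange(float(n)))
    q = EmbeddedBlock(rows=rng.uniform(-1, 1, (5, dim)),
                      targets=rng.uniform(-1, 1, 5),
                      row_times=1000.0 + np.arange(5.0))
    fs, _ = simplex_forecast(lib, q)
    np.testing.assert_allclose(
        fs, brute_simplex(lib.rows, lib.targets, lib.row_times,
                          q.rows, q.row_times), atol=1e-12)
    if n > dim + 1:
        fit = smap_forecast(lib, q, theta)
        ref_f, _ = brute_smap(lib.rows, lib.targets, lib.row_times,
                              q.rows, q.row_times, theta)
        np.testing.assert_allclose(fit.forecasts, ref_f, atol=1e-12)


class TestSelection:
    def test_sine_cycle_unfolds_in_two_dimensions(self, make_univariate):
        # a 1-D delay coordinate cannot separate the rising and falling
        # branches of a cycle; adding the second lag collapses the MAE
        t = np.arange(0, 100, 1.0)
        s = make_univariate(np.sin(t) + 2)
        best, table = select_E(s, (1, 2, 3, 4))
        tab = table.set_index("E")["mae"]
        assert tab[1] > 10 * tab[2]
        best12, _ = select_E(s, (1, 2))
        assert best12 == 2

    def test_white_noise_returns_deterministic_argmin(self, make_univariate):
        rng = np.random.default_rng(0)
        s = make_univariate(rng.uniform(1, 2, 80))
        b1, t1 = select_E(s, (1, 2, 3))
        b2, t2 = select_E(s, (1, 2, 3))
        assert b1 == b2
        assert t1.equals(t2)

    def test_linear_series_selects_theta_zero(self, make_univariate):
        # stationary AR(1): globally linear, localization gains nothing
        rng = np.random.default_rng(1)
        x = np.zeros(200)
        for t in range(199):
            x[t + 1] = 0.8 * x[t] + rng.normal(0, 0.05)
        best, prof = select_theta(make_univariate(x + 1.0), E=1,
                                  theta_grid=(0.0, 0.5, 2.0))
        assert best == 0.0

    def test_chaotic_series_selects_positive_theta(self, make_univariate):
        x = np.empty(300)
        x[0] = 0.7
        for t in range(299):
            x[t + 1] = x[t] * np.exp(3.0 * (1 - x[t]))
        best, prof = select_theta(make_univariate(x), E=1)
        assert best > 0

    def test_singleton_theta_grid(self, make_univariate):
        s = make_univariate(np.sin(np.arange(30.0)) + 2)
        best, _ = select_theta(s, E=2, theta_grid=(0.75,))
        assert best == 0.75

    def test_short_series_skips_large_E(self, make_univariate):
        s = make_univariate(np.arange(8.0))
        with pytest.warns(UserWarning):
            best, table = select_E(s, (1, 2, 50))
        assert 50 not in set(table["E"])


class TestGoodnessOfFit:
    def test_perfect_and_mean_predictions(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        d = goodness_of_fit(obs, obs)
        assert d.mae == 0 and d.e2 == 1
        d = goodness_of_fit(obs, np.full(4, obs.mean()))
        assert d.e2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        d = goodness_of_fit([1, 2, 3], [1, 2, 5])
        assert d.mae == pytest.approx(2 / 3)
        assert d.mse == pytest.approx(4 / 3)
        assert d.rmse == pytest.approx(np.sqrt(4 / 3))
        assert d.e2 == pytest.approx(-1.0)

    def test_zero_variance_flags_e2(self):
        d = goodness_of_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert not d.e2_defined and np.isnan(d.e2)
        assert d.mae == pytest.approx(2 / 3)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(shift=st.floats(-100, 100), seed=st.integers(0, 1000))
    def test_e2_shift_invariant_and_bounded(self, shift, seed):
        rng = np.random.default_rng(seed)
        obs = rng.normal(0, 1, 20)
        pred = obs + rng.normal(0, 0.5, 20)
        d0 = goodness_of_fit(obs, pred)
        d1 = goodness_of_fit(obs + shift, pred + shift)
        assert d0.e2 <= 1.0
        assert d1.e2 == pytest.approx(d0.e2, abs=1e-6)
        assert d0.rmse**2 == pytest.approx(d0.mse, abs=1e-12)
        assert d0.mae <= d0.rmse + 1e-12
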