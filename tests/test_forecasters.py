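import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emdcombine import (
    ESModel,
    es_forecast,
    es_select_alpha,
    grnn_fit,
    grnn_forecast,
    grnn_predict,
    narnn_fit,
    narnn_fit_forecast,
    narnn_forecast,
)


class TestExponentialSmoothing:
    def test_constant_series_is_fixed_point(self):
        for alpha in (0.1, 0.5, 1.0):
            np.testing.assert_array_equal(
                es_forecast([5.0, 5, 5], ESModel(alpha)), [5.0, 5, 5]
            )

    @settings(deadline=None, max_examples=30)
    @given(
        arrays(
            float,
            st.integers(min_value=1, max_value=30),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_alpha_one_is_naive_forecast(self, x):
        np.testing.assert_array_equal(es_forecast(x, ESModel(1.0)), x)

    def test_hand_recursion(self):
        # x=(10,20), alpha=0.5, initial 10 -> forecasts (10, 15)
        np.testing.assert_allclose(
            es_forecast([10.0, 20.0], ESModel(0.5)), [10.0, 15.0]
        )

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            ESModel(0.0)
        with pytest.raises(ValueError):
            ESModel(1.5)

    def test_matches_statsmodels_fixed_alpha(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        x = 10 + rng.normal(0, 2, 60)
        alpha = 0.37
        ours = es_forecast(x, ESModel(alpha))
        fit = sm.tsa.SimpleExpSmoothing(
            x, initialization_method="known", initial_level=x[0]
        ).fit(smoothing_level=alpha, optimized=False)
        np.testing.assert_allclose(fit.fittedvalues[1:], ours[:-1], atol=1e-10)

    def test_alpha_selection_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)

        def brute(x):
            best, best_sse = None, np.inf
            for a in grid:
                fc = es_forecast(x, ESModel(float(a)))
                sse = np.sum((x[1:] - fc[:-1]) ** 2)
                if sse < best_sse - 1e-15:
                    best, best_sse = a, sse
            return best

        noise = 20 + rng.normal(0, 1, 300)  # stable -> small alpha
        walk = 50 + np.cumsum(rng.normal(0, 1, 300))  # random walk -> large
        for series in (noise, walk):
            assert es_select_alpha(series).alpha == pytest.approx(brute(series))
        assert es_select_alpha(noise).alpha < 0.2
        assert es_select_alpha(walk).alpha > 0.8

    def test_single_value_grid(self):
        assert es_select_alpha(np.arange(10.0), grid=[0.4]).alpha == 0.4


class TestGRNN:
    def test_single_pattern_returns_its_target(self):
        from emdcombine.forecasters import GRNNModel

        m = GRNNModel(
            patterns=np.array([[2.0, 2.0, 2.0]]),
            targets=np.array([7.0]),
            sigma=0.5,
            lag=3,
            x_mean=0.0,
            x_std=1.0,
        )
        assert grnn_predict(m, np.array([100.0, -3.0, 0.0])) == pytest.approx(7.0)

    def test_equidistant_patterns_average_targets(self):
        from emdcombine.forecasters import GRNNModel

        m = GRNNModel(
            patterns=np.array([[-1.0], [1.0]]),
            targets=np.array([10.0, 20.0]),
            sigma=0.5,
            lag=1,
            x_mean=0.0,
            x_std=1.0,
        )
        assert grnn_predict(m, np.array([0.0])) == pytest.approx(15.0)

    def test_sigma_to_zero_is_nearest_neighbour(self):
        rng = np.random.default_rng(2)
        train = rng.normal(0, 1, 50)
        m = grnn_fit(train, lag=2, sigma_grid=np.array([1e-6]))
        for _ in range(5):
            q = rng.normal(0, 1, 2)
            qz = (q - m.x_mean) / m.x_std
            d2 = ((m.patterns - qz) ** 2).sum(axis=1)
            nn = m.x_mean + m.x_std * m.targets[np.argmin(d2)]
            assert grnn_predict(m, q) == pytest.approx(nn, abs=1e-9)

    def test_constant_series_predicts_constant(self):
        m = grnn_fit(np.full(30, 4.2), lag=5)
        fc = grnn_forecast(m, np.full(12, 4.2))
        np.testing.assert_allclose(fc, 4.2, atol=1e-12)

    def test_prediction_count_matches_embedding(self):
        train = np.sin(np.arange(40) * 0.3)
        m = grnn_fit(train, lag=5)
        assert m.patterns.shape[0] == 40 - 5
        assert grnn_forecast(m, train).size == 40 - 5

    def test_loo_bandwidth_beats_worst_grid_value(self):
        rng = np.random.default_rng(3)
        x = np.empty(120)
        x[0] = 0.0
        for i in range(1, 120):
            x[i] = 0.9 * x[i - 1] + rng.normal(0, 0.05)
        grid = np.array([0.01, 0.3, 50.0])
        m = grnn_fit(x, lag=1, sigma_grid=grid)

        def loo_sse(sigma):
            mm = grnn_fit(x, lag=1, sigma_grid=np.array([sigma]))
            pred = grnn_forecast(mm, x)
            return np.sum((pred - x[1:]) ** 2)

        sses = {s: loo_sse(s) for s in grid}
        assert sses[m.sigma] <= max(sses.values())

    def test_output_within_target_range(self):
        rng = np.random.default_rng(4)
        train = rng.normal(5, 2, 60)
        m = grnn_fit(train, lag=3)
        fc = grnn_forecast(m, rng.normal(5, 2, 30))
        lo = m.x_mean + m.x_std * m.targets.min()
        hi = m.x_mean + m.x_std * m.targets.max()
        assert np.all(fc >= lo - 1e-9) and np.all(fc <= hi + 1e-9)

    def test_printed_ratio_form_differs(self):
        from emdcombine.forecasters import GRNNModel

        m = GRNNModel(
            patterns=np.array([[-1.0], [1.0]]),
            targets=np.array([2.0, 4.0]),
            sigma=0.7,
            lag=1,
            x_mean=0.0,
            x_std=1.0,
        )
        standard = grnn_predict(m, np.array([0.3]))
        transposed = grnn_predict(m, np.array([0.3]), printed_ratio=True)
        assert standard != pytest.approx(transposed)


class TestNARNN:
    def test_constant_series_learned(self):
        m = narnn_fit(np.full(60, 7.0), d=3, hidden_units=5, seed=1)
        fc = narnn_forecast(m, np.full(20, 7.0))
        np.testing.assert_allclose(fc, 7.0, atol=1e-3)

    def test_same_seed_identical_forecasts(self):
        rng = np.random.default_rng(5)
        x = np.sin(np.arange(150) * 0.2) + rng.normal(0, 0.1, 150)
        _, f1 = narnn_fit_forecast(x[:120], x[120:], d=5, hidden_units=10, seed=9)
        _, f2 = narnn_fit_forecast(x[:120], x[120:], d=5, hidden_units=10, seed=9)
        np.testing.assert_array_equal(f1, f2)

    def test_zero_delay_rejected(self):
        with pytest.raises(ValueError):
            narnn_fit(np.arange(50.0), d=0)

    def test_learns_a_smooth_cycle(self):
        x = np.sin(np.arange(200) * 2 * np.pi / 25)
        m = narnn_fit(x[:170], d=5, hidden_units=10, seed=3)
        fc = narnn_forecast(m, x)
        # open-loop one-step error well under the signal amplitude
        rmse = np.sqrt(np.mean((fc[165:] - x[170:]) ** 2))
        assert rmse < 0.15

    def test_forecasts_are_causal_alignment(self):
        # forecast count = N - d, first forecast targets position d
        x = np.arange(30.0)
        m = narnn_fit(np.sin(np.arange(60) * 0.3), d=4, hidden_units=5, seed=0)
        assert narnn_forecast(m, x).size == 30 - 4
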