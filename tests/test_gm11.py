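import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greycast import (
    DegenerateModelError,
    ValidationError,
    ago,
    fit,
    forecast_table,
    iago,
    mean_sequence,
    predict,
    round_half_away,
    time_response,
)
from greycast.gm11 import GM11Params, sequences
from greycast.synthetic import SyntheticSpec, generate_exact

from .conftest import PRINTED_FORECASTS_2025, PRINTED_MODELS

positive_series = st.lists(
    st.floats(min_value=0.01, max_value=1e6, allow_nan=False), min_size=1, max_size=30
)


class TestSequenceOps:
    def test_ago_running_sum(self):
        assert ago([1, 2, 3]).tolist() == [1, 3, 6]
        assert ago([5]).tolist() == [5]

    def test_ago_of_institutions_column(self, builtin):
        assert ago(builtin["Medical institutions"].to_array())[-1] == 183_102

    def test_mean_sequence_neighbour_averages(self):
        assert mean_sequence([1, 3, 6]).tolist() == [2.0, 4.5]
        c = 7.0
        assert mean_sequence([c, 2 * c, 3 * c]).tolist() == [1.5 * c, 2.5 * c]

    def test_mean_sequence_matches_bruteforce_on_real_data(self, builtin):
        x1 = ago(builtin["Medical institutions"].to_array())
        brute = np.array([(x1[i] + x1[i + 1]) / 2 for i in range(len(x1) - 1)])
        np.testing.assert_allclose(mean_sequence(x1), brute)

    def test_empty_and_short_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ago([])
        with pytest.raises(ValidationError):
            mean_sequence([1.0])

    @settings(deadline=None)
    @given(positive_series)
    def test_iago_inverts_ago(self, x):
        # identity up to a few ulps of the running sum (the quantity the
        # rounding happens on), not of the individual elements
        x1 = ago(x)
        tol = 8 * np.finfo(float).eps * float(x1[-1])
        np.testing.assert_allclose(iago(x1), np.asarray(x), rtol=0, atol=tol)

    @settings(deadline=None)
    @given(positive_series)
    def test_z1_between_neighbouring_accumulations(self, x):
        if len(x) < 2:
            return
        seq = sequences(x)
        assert np.all(seq.z1 >= seq.x1_ago[:-1])
        assert np.all(seq.z1 <= seq.x1_ago[1:])


class TestFit:
    @pytest.mark.parametrize("name", list(PRINTED_MODELS))
    def test_reproduces_published_parameters_to_4dp(self, builtin, name):
        a, b, *_ = PRINTED_MODELS[name]
        params = fit(builtin[name])
        assert params.a == pytest.approx(a, abs=5e-5)
        assert params.b == pytest.approx(b, abs=5e-5)

    @pytest.mark.parametrize("name", list(PRINTED_MODELS))
    def test_closed_form_agrees_with_lstsq(self, builtin, name):
        params = fit(builtin[name])
        seq = sequences(builtin[name].to_array())
        B = np.column_stack([-seq.z1, np.ones(seq.z1.size)])
        (a_ref, b_ref), *_ = np.linalg.lstsq(B, seq.x0[1:], rcond=None)
        assert params.a == pytest.approx(a_ref, rel=1e-10)
        assert params.b == pytest.approx(b_ref, rel=1e-10)

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.floats(min_value=-0.3, max_value=0.3, allow_nan=False).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=10.0, max_value=1e4),
        x1=st.floats(min_value=1.0, max_value=1e4),
        n=st.integers(min_value=4, max_value=12),
    )
    def test_closed_form_agrees_with_lstsq_on_random_series(self, a, b, x1, n):
        """Both solvers see the same perturbed near-exponential data."""
        try:
            series = generate_exact(SyntheticSpec(a=a, b=b, x1=x1, n=n, noise_sd=0.0))
        except (ValidationError, DegenerateModelError):
            return
        x0 = series.to_array() * (1 + 0.01 * np.sin(np.arange(n)))  # deterministic jitter
        try:
            params = fit(x0)
        except DegenerateModelError:
            return
        seq = sequences(x0)
        B = np.column_stack([-seq.z1, np.ones(seq.z1.size)])
        (a_ref, b_ref), *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
        assert params.a == pytest.approx(a_ref, rel=1e-8, abs=1e-12)
        assert params.b == pytest.approx(b_ref, rel=1e-8)

    def test_exact_recursion_data_recovered_to_machine_precision(self):
        series = generate_exact(SyntheticSpec(a=-0.05, b=100.0, x1=80.0, n=8))
        params = fit(series)
        assert params.a == pytest.approx(-0.05, abs=1e-10)
        assert params.b == pytest.approx(100.0, abs=1e-8)

    def test_flat_series_rejected(self):
        with pytest.raises(DegenerateModelError):
            fit(np.full(8, 42.0))

    def test_too_short_and_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            fit(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError):
            fit(np.array([1.0, -2.0, 3.0, 4.0]))


class TestPrediction:
    def test_time_response_anchor(self, builtin):
        params = fit(builtin["Medical institutions"])
        assert time_response(params, 0) == pytest.approx(params.x1)

    def test_time_response_closed_form(self):
        params = GM11Params(a=-0.1, b=10.0, x1=5.0, n=4)
        expected = 105 * np.exp(0.1) - 100
        assert time_response(params, 1) == pytest.approx(expected)

    def test_first_fitted_value_is_anchor_for_all_indicators(self, builtin):
        for series in builtin.values():
            pred = predict(fit(series), horizon=3)
            assert pred[0] == series.values[0]
            assert len(pred) == 11

    @pytest.mark.parametrize("name", list(PRINTED_FORECASTS_2025))
    def test_reproduces_published_2025_forecasts(self, builtin, name):
        pred = predict(fit(builtin[name]), horizon=3)
        assert round_half_away(pred[-1]) == PRINTED_FORECASTS_2025[name]

    def test_growing_model_predictions_strictly_increase(self, builtin):
        for series in builtin.values():
            params = fit(series)
            assert params.a < 0
            pred = predict(params, horizon=5)
            assert np.all(np.diff(pred[1:]) > 0)

    def test_fit_on_exact_data_nearly_interpolates(self):
        """Data satisfying the difference equation exactly is reproduced up to
        the small continuous-vs-discrete exponential mismatch (O(a^2) per
        step), even though the recovered (a, b) are exact."""
        series = generate_exact(SyntheticSpec(a=-0.05, b=100.0, x1=80.0, n=8))
        pred = predict(fit(series), horizon=0)
        np.testing.assert_allclose(pred, series.to_array(), rtol=1e-3)
        # the mismatch shrinks quadratically as |a| does
        small = generate_exact(SyntheticSpec(a=-0.005, b=100.0, x1=80.0, n=8))
        pred_small = predict(fit(small), horizon=0)
        rel = np.max(np.abs(pred_small - small.to_array()) / small.to_array())
        assert rel < 1e-5

    def test_negative_horizon_rejected(self, builtin):
        with pytest.raises(ValidationError):
            predict(fit(builtin["Medical beds"]), horizon=-1)


class TestForecastTable:
    def test_years_and_alignment(self, builtin):
        table = forecast_table(builtin["Registered nurses"], horizon=3)
        assert table.years == tuple(range(2015, 2026))
        assert table.horizon == 3
        assert np.isnan(table.actual[8:]).all()
        assert not np.isnan(table.actual[:8]).any()
        assert round_half_away(table.forecast(2025)) == 129_586

    def test_zero_horizon_has_no_extrapolation(self, builtin):
        table = forecast_table(builtin["Registered nurses"], horizon=0)
        assert table.years[-1] == 2022


def test_round_half_away_from_zero():
    assert round_half_away(2.5) == 3
    assert round_half_away(-2.5) == -3
    assert round_half_away(2.4) == 2
    np.testing.assert_array_equal(round_half_away([0.5, 1.5, -0.5]), [1, 2, -1])
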