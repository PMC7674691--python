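"""Scattering-factor arithmetic, bias correction and the ML intake estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

import thyret as th
from thyret.errors import AlignmentError, InvalidDataError, InvalidParameterError
from thyret.intake import Measurement, MeasurementSeries


def _series(times, activities, sf=1.2):
    return MeasurementSeries(
        tuple(Measurement(t_h=t, activity_bq=a, sf_meas=sf) for t, a in zip(times, activities))
    )


def _numeric_mle(series, retention, sfs):
    """Independent oracle: numerically maximize the product likelihood."""
    m = np.atleast_1d(retention.interpolate(series.times_h))
    log_ie = np.log(series.activities_bq / m)
    log_sf = np.log(np.asarray(sfs))

    def nll(log_i):
        return float(np.sum(((log_ie - log_i) / log_sf) ** 2))

    res = minimize_scalar(nll, bounds=(log_ie.min() - 1, log_ie.max() + 1), method="bounded",
                          options={"xatol": 1e-12})
    return math.exp(res.x)


@pytest.fixture(scope="module")
def synthetic_curve():
    t = np.arange(1.0, 200.0, 1.0)
    return th.RetentionCurve(times_h=t, values=0.25 * np.exp(-t / 400.0) * (1 - np.exp(-t / 6.0)))


class TestCombineSF:
    @pytest.mark.parametrize(
        "sf_m, sf_ret, printed",
        [(1.2, 1.55, 1.6), (1.2, 1.45, 1.5)],
    )
    def test_printed_combined_values(self, sf_m, sf_ret, printed):
        assert round(th.combine_sf(sf_m, sf_ret), 1) == printed

    def test_degenerate_component_is_identity(self):
        assert th.combine_sf(1.3, 1.0) == pytest.approx(1.3, rel=1e-12)

    @given(
        st.floats(min_value=1.0, max_value=5.0),
        st.floats(min_value=1.0, max_value=5.0),
        st.floats(min_value=1.0, max_value=5.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_associative_dominating(self, a, b, c):
        assert th.combine_sf(a, b) == pytest.approx(th.combine_sf(b, a), rel=1e-12)
        assert th.combine_sf(a, b) >= max(a, b) * (1 - 1e-12)
        left = th.combine_sf(th.combine_sf(a, b), c)
        right = th.combine_sf(a, th.combine_sf(b, c))
        assert left == pytest.approx(right, rel=1e-9)

    def test_rejects_sub_unity(self):
        with pytest.raises(InvalidParameterError):
            th.combine_sf(0.9, 1.5)


class TestBiasCorrect:
    def test_divides_only_early_points(self):
        series = _series([2.0, 24.0], [110.0, 470.0])
        out = th.bias_correct(series, th.BiasModel(bias=1.35))
        assert out.measurements[0].activity_bq == pytest.approx(110.0 / 1.35)
        assert out.measurements[0].bias_corrected
        assert out.measurements[1].activity_bq == 470.0
        assert not out.measurements[1].bias_corrected

    def test_double_correction_refused(self):
        series = _series([2.0, 24.0], [110.0, 470.0])
        once = th.bias_correct(series)
        with pytest.raises(InvalidDataError):
            th.bias_correct(once)

    def test_unit_bias_is_identity(self):
        series = _series([2.0, 24.0], [110.0, 470.0])
        out = th.bias_correct(series, th.BiasModel(bias=1.0))
        assert out.measurements[0].activity_bq == 110.0


class TestEstimateIntake:
    def test_single_point_ignores_sf(self, synthetic_curve):
        series = _series([24.0], [470.0])
        m24 = synthetic_curve.interpolate(24.0)
        for sf in (1.0, 1.4):
            res = th.estimate_intake(series, synthetic_curve, sf_m_before=1.1, sf_m_after=sf)
            assert res.intake_bq == pytest.approx(470.0 / m24, rel=1e-12)
        res = th.estimate_intake(series, synthetic_curve)
        assert res.dof == 0
        assert math.isnan(res.p_value)

    def test_equal_sfs_give_geometric_mean(self, synthetic_curve):
        series = _series([2.0, 6.0, 30.0, 50.0], [50.0, 120.0, 130.0, 125.0])
        res = th.estimate_intake(series, synthetic_curve, sf_m_before=1.4, sf_m_after=1.4)
        gm = math.exp(np.log(res.implied_intake_bq).mean())
        assert res.intake_bq == pytest.approx(gm, rel=1e-12)
        numeric = _numeric_mle(series, synthetic_curve, res.sf)
        assert res.intake_bq == pytest.approx(numeric, rel=1e-8)

    def test_closed_form_equals_numeric_argmax_on_random_series(self, synthetic_curve):
        rng = np.random.default_rng(99)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            times = np.sort(rng.uniform(2.0, 150.0, size=k))
            times += np.arange(k) * 1e-3  # guard strict ordering
            m = np.atleast_1d(synthetic_curve.interpolate(times))
            intake = rng.uniform(100.0, 1e5)
            activities = intake * m * np.exp(rng.normal(0, 0.3, size=k))
            series = _series(times, activities, sf=float(rng.uniform(1.05, 1.6)))
            sf_b, sf_a = rng.uniform(1.1, 1.8, size=2)
            res = th.estimate_intake(series, synthetic_curve, sf_m_before=sf_b, sf_m_after=sf_a)
            numeric = _numeric_mle(series, synthetic_curve, res.sf)
            assert res.intake_bq == pytest.approx(numeric, rel=1e-8)
            assert res.implied_intake_bq.min() <= res.intake_bq <= res.implied_intake_bq.max()

    def test_jackknife_stays_in_remaining_hull(self, synthetic_curve):
        series = _series([2.0, 6.0, 30.0, 50.0], [60.0, 100.0, 140.0, 110.0])
        for drop in range(4):
            kept = tuple(m for i, m in enumerate(series.measurements) if i != drop)
            sub = MeasurementSeries(kept)
            res = th.estimate_intake(sub, synthetic_curve, sf_m_before=1.5, sf_m_after=1.3)
            assert res.implied_intake_bq.min() <= res.intake_bq <= res.implied_intake_bq.max()

    def test_sf_switch_at_24_hours(self, synthetic_curve):
        series = _series([23.0, 24.0], [100.0, 100.0])
        res = th.estimate_intake(series, synthetic_curve, sf_m_before=1.55, sf_m_after=1.45)
        assert res.sf[0] == pytest.approx(th.combine_sf(1.2, 1.55))
        assert res.sf[1] == pytest.approx(th.combine_sf(1.2, 1.45))

    def test_measurement_outside_grid_rejected(self, synthetic_curve):
        series = _series([0.5], [10.0])
        with pytest.raises(InvalidParameterError):
            th.estimate_intake(series, synthetic_curve)


class TestGoodnessOfFit:
    def test_perfect_data(self, synthetic_curve):
        times = np.array([2.0, 10.0, 40.0])
        m = np.atleast_1d(synthetic_curve.interpolate(times))
        series = _series(times, 1000.0 * m)
        chi2, dof, p = th.goodness_of_fit(series, synthetic_curve, [1.3] * 3, 1000.0)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert dof == 2
        assert p == pytest.approx(1.0)

    def test_fixed_intake_has_full_dof(self, synthetic_curve):
        series = _series([2.0, 10.0], [50.0, 60.0])
        _, dof, _ = th.goodness_of_fit(series, synthetic_curve, [1.3, 1.3], 500.0,
                                       intake_fitted=False)
        assert dof == 2


class TestRaiuAndBias:
    def test_normalized_curve_is_one_at_24h(self, ingestion_reference_curve):
        raiu = th.normalized_raiu(ingestion_reference_curve)
        i24 = int(np.where(raiu.times_h == 24.0)[0][0])
        assert raiu.values[i24] == pytest.approx(1.0)

    def test_scale_invariance(self, ingestion_reference_curve):
        a = th.normalized_raiu(ingestion_reference_curve)
        b = th.normalized_raiu(ingestion_reference_curve.scaled(0.5))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_early_uptake_below_24h_value(self, ingestion_reference_curve):
        raiu = th.normalized_raiu(ingestion_reference_curve)
        for t in (4.0, 5.0):
            i = int(np.where(raiu.times_h == t)[0][0])
            assert raiu.values[i] < 1.0

    def test_identical_curves_unit_bias(self):
        t = np.array([4.0, 5.0, 24.0])
        v = np.array([0.4, 0.5, 1.0])
        result = th.compute_bias(th.RaiuCurve(t, v), th.RaiuCurve(t, v))
        np.testing.assert_allclose(result.ratios, 1.0)
        assert result.mean == pytest.approx(1.0)

    def test_anchor_ratio_is_unity_and_mean_over_early_points(self):
        t = np.array([4.0, 5.0, 24.0])
        measured = th.RaiuCurve(t, np.array([0.56, 0.65, 1.0]))
        calculated = th.RaiuCurve(t, np.array([0.4, 0.5, 1.0]))
        result = th.compute_bias(measured, calculated)
        assert result.ratios[-1] == pytest.approx(1.0)
        assert result.mean == pytest.approx((0.56 / 0.4 + 0.65 / 0.5) / 2)
        assert result.minimum == pytest.approx(1.3)
        assert result.maximum == pytest.approx(1.4)

    def test_mismatched_grids_rejected(self):
        a = th.RaiuCurve(np.array([4.0, 24.0]), np.array([0.5, 1.0]))
        b = th.RaiuCurve(np.array([5.0, 24.0]), np.array([0.5, 1.0]))
        with pytest.raises(AlignmentError):
            th.compute_bias(a, b)

    def test_raiu_requires_unit_anchor(self):
        with pytest.raises(InvalidDataError):
            th.RaiuCurve(np.array([4.0, 24.0]), np.array([0.5, 0.9]))
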