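"""Nonconformity measures, p-values, conformal quantiles and fitted ICPs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from assaycp import (
    ACTIVE,
    NONACTIVE,
    CalibrationError,
    classification_nonconformity,
    conformal_quantile,
    fit_icp_classifier,
    fit_icp_regressor,
    load_icp,
    p_value,
    regression_nonconformity,
    save_icp,
)

from conftest import make_classification_dataset, make_regression_dataset


def brute_force_p(test_alpha, calib):
    return (sum(1 for a in calib if a >= test_alpha) + 1) / (len(calib) + 1)


def brute_force_quantile(calib, confidence):
    s = sorted(calib)
    k = math.ceil(confidence * (len(s) + 1))
    return math.inf if k > len(s) else s[k - 1]


class TestNonconformity:
    def test_classification_sign_convention(self):
        assert classification_nonconformity(2.0, ACTIVE) == -2.0
        assert classification_nonconformity(2.0, NONACTIVE) == 2.0
        assert classification_nonconformity(0.0, ACTIVE) == 0.0
        assert classification_nonconformity(0.0, NONACTIVE) == 0.0

    def test_regression_values(self):
        assert regression_nonconformity(5.0, 4.0, 0.0, 0.01) == pytest.approx(
            0.9900990099009901, abs=1e-6
        )
        assert regression_nonconformity(3.2, 3.2, 1.7) == 0.0
        assert regression_nonconformity(
            6.0, 5.0, math.log(9.99), 0.01
        ) == pytest.approx(0.1, abs=1e-6)

    def test_regression_requires_positive_beta(self):
        with pytest.raises(ValueError):
            regression_nonconformity(1.0, 0.0, 0.0, beta=0.0)


class TestPValue:
    @pytest.mark.parametrize(
        "calib,test,expected",
        [
            ([0.1, 0.2, 0.3], 0.4, 0.25),
            ([0.1, 0.2, 0.3], 0.05, 1.0),
            ([1.0, 2.0, 3.0], 2.0, 0.75),  # ties counted as >=
        ],
    )
    def test_counting_rule(self, calib, test, expected):
        assert p_value(test, calib, interpolate=False) == pytest.approx(expected)

    def test_empty_calibration_rejected(self):
        with pytest.raises(CalibrationError):
            p_value(0.5, [])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            calib = rng.normal(size=n)
            if rng.random() < 0.5:  # force ties half the time
                calib[0] = calib[-1]
            t = rng.normal()
            assert p_value(t, calib, interpolate=False) == brute_force_p(t, calib)

    @given(
        hst.lists(
            hst.floats(min_value=-100, max_value=100), min_size=1, max_size=40
        ),
        hst.floats(min_value=-150, max_value=150),
    )
    def test_interpolated_close_to_counting_and_conservative(self, calib, t):
        calib = list(dict.fromkeys(calib))  # distinct scores
        n = len(calib)
        p_step = p_value(t, calib, interpolate=False)
        p_int = p_value(t, calib, interpolate=True)
        assert p_int >= p_step - 1e-12
        assert p_int <= p_step + 1.0 / (n + 1) + 1e-12

    def test_interpolation_continuous_and_decreasing(self):
        calib = [0.1, 0.4, 0.9, 2.0]
        ts = np.linspace(-1, 3, 400)
        ps = np.array([p_value(t, calib) for t in ts])
        assert np.all(np.diff(ps) <= 1e-12)
        assert ps[0] == 1.0
        assert ps[-1] == pytest.approx(1 / 5)


class TestConformalQuantile:
    def test_order_statistic(self):
        calib = [0.1 * i for i in range(1, 10)]  # 9 values
        a, finite = conformal_quantile(calib, 0.8, interpolate=False)
        assert finite
        assert a == pytest.approx(0.8)

    def test_index_overflow_gives_infinite_width(self):
        a, finite = conformal_quantile([1.0, 2.0, 3.0, 4.0], 0.9, interpolate=False)
        assert not finite
        assert math.isinf(a)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(1, 40))
            calib = rng.exponential(size=n)
            conf = float(rng.uniform(0.05, 0.99))
            a, _ = conformal_quantile(calib, conf, interpolate=False)
            assert a == brute_force_quantile(calib, conf)

    def test_interpolated_below_ceiling(self):
        calib = np.arange(1.0, 20.0)
        for conf in (0.3, 0.5, 0.8):
            a_i, _ = conformal_quantile(calib, conf, interpolate=True)
            a_c, _ = conformal_quantile(calib, conf, interpolate=False)
            assert a_i <= a_c + 1e-12


class TestIcpClassifier:
    def test_mondrian_calibration_and_prediction(self, classification_split):
        proper, calib = classification_split
        icp = fit_icp_classifier(proper, calib)
        assert set(icp.calib_alphas) == {ACTIVE, NONACTIVE}
        assert all(a.size > 0 for a in icp.calib_alphas.values())
        ps = icp.predict_set(calib.X, epsilon=0.2)
        for c in (ACTIVE, NONACTIVE):
            assert np.all((ps.p_values[c] > 0) & (ps.p_values[c] <= 1))
        inc = ps.included(0.2)
        assert inc[ACTIVE].shape == (calib.n,)

    def test_identical_proper_calib_rejected(self, classification_split):
        proper, _ = classification_split
        with pytest.raises(ValueError, match="disjoint"):
            fit_icp_classifier(proper, proper)

    def test_prediction_set_inclusion_rule(self):
        from assaycp import PredictionSet

        ps = PredictionSet(
            {ACTIVE: np.array([0.5, 0.5, 0.1]), NONACTIVE: np.array([0.1, 0.25, 0.15])}
        )
        inc = ps.included(0.2)
        assert list(inc[ACTIVE]) == [True, True, False]
        assert list(inc[NONACTIVE]) == [False, True, False]
        assert list(ps.set_sizes(0.2)) == [1, 2, 0]


class TestIcpRegressor:
    def test_calibration_scores_finite_nonnegative(self, regression_split):
        proper, calib = regression_split
        icp = fit_icp_regressor(proper, calib)
        assert np.all(np.isfinite(icp.calib_alphas))
        assert np.all(icp.calib_alphas >= 0)

    def test_deterministic_given_seed(self, regression_split):
        proper, calib = regression_split
        a = fit_icp_regressor(proper, calib).calib_alphas
        b = fit_icp_regressor(proper, calib).calib_alphas
        np.testing.assert_array_equal(a, b)

    def test_interval_construction_from_order_statistic(self, regression_split):
        proper, calib = regression_split
        icp = fit_icp_regressor(proper, calib)
        icp.calib_alphas = np.arange(0.1, 1.0, 0.1)  # 9 known scores
        iv = icp.predict_interval(calib.X[:3], 0.8)
        y_hat, sigma = icp.point_predictions(calib.X[:3])
        np.testing.assert_allclose(iv.half_width, 0.8 * sigma, atol=1e-12)
        np.testing.assert_allclose(iv.midpoint, y_hat, atol=1e-12)

    def test_half_width_nondecreasing_in_confidence(self, regression_split):
        proper, calib = regression_split
        icp = fit_icp_regressor(proper, calib)
        widths = [
            icp.predict_interval(calib.X, c).half_width
            for c in np.linspace(0.05, 0.95, 19)
        ]
        for lo, hi in zip(widths, widths[1:]):
            assert np.all(hi >= lo - 1e-12)

    def test_overflowing_confidence_flagged_infinite(self, regression_split):
        proper, calib = regression_split
        icp = fit_icp_regressor(proper, calib)
        icp.calib_alphas = icp.calib_alphas[:4]
        iv = icp.predict_interval(calib.X, 0.9)  # ceil(0.9*5)=5 > 4
        assert not np.any(iv.is_finite)
        assert np.all(iv.contains(np.zeros(calib.n)))

    def test_marginal_validity_on_exchangeable_data(self):
        covs = []
        for seed in range(20):
            ds = make_regression_dataset(n=160, seed=seed)
            proper, calib, test = (
                ds.subset(np.arange(80)),
                ds.subset(np.arange(80, 120)),
                ds.subset(np.arange(120, 160)),
            )
            icp = fit_icp_regressor(proper, calib)
            covs.append(np.mean(icp.predict_interval(test.X, 0.8).contains(test.y)))
        assert np.mean(covs) >= 0.8 - 0.03  # Monte Carlo tolerance


class TestPersistence:
    def test_classifier_roundtrip(self, classification_split, tmp_path):
        proper, calib = classification_split
        icp = fit_icp_classifier(proper, calib)
        save_icp(icp, tmp_path / "m.json")
        back = load_icp(tmp_path / "m.json")
        for c in icp.calib_alphas:
            np.testing.assert_array_equal(icp.calib_alphas[c], back.calib_alphas[c])
        np.testing.assert_allclose(
            icp.decision_values(calib.X), back.decision_values(calib.X)
        )

    def test_regressor_roundtrip(self, regression_split, tmp_path):
        proper, calib = regression_split
        icp = fit_icp_regressor(proper, calib)
        save_icp(icp, tmp_path / "m.json")
        back = load_icp(tmp_path / "m.json")
        np.testing.assert_array_equal(icp.calib_alphas, back.calib_alphas)
        a = icp.predict_interval(calib.X, 0.8)
        b = back.predict_interval(calib.X, 0.8)
        np.testing.assert_allclose(a.lower, b.lower)
        np.testing.assert_allclose(a.upper, b.upper)
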