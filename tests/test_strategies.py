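"""Composition rules of the six strategies and median aggregation."""

import numpy as np
import pytest

from assaycp import (
    CalibrationError,
    LabeledDataset,
    PredictionInterval,
    STRATEGIES,
    aggregate_intervals,
    aggregate_p_values,
    calibration_all_new,
    compose,
    fit_strategy,
)

from conftest import make_classification_dataset, make_regression_dataset


@pytest.fixture
def two_assays():
    old = make_regression_dataset(n=100, seed=10, assay="old")
    new = make_regression_dataset(n=50, seed=11, assay="new")
    return old, new


class TestCompose:
    def test_ccp_new_fold_structure(self, two_assays):
        old, new = two_assays
        pairs = compose("CCP_new", old, new, k=10, seed=0)
        assert len(pairs) == 10
        for proper, calib in pairs:
            assert proper.n == 45 and calib.n == 5
            assert set(calib.assay_tag) == {"new"}
            assert set(proper.assay_tag) == {"new"}
        # calibration folds partition A_new
        total = sum(calib.n for _, calib in pairs)
        assert total == new.n

    def test_ccp_at_structure(self):
        old = make_regression_dataset(n=1000, seed=1, assay="old")
        new = make_regression_dataset(n=100, seed=2, assay="new")
        pairs = compose("CCP_AT", old, new, k=10, seed=0)
        assert len(pairs) == 10
        for proper, calib in pairs:
            assert calib.n == 10 and set(calib.assay_tag) == {"new"}
            assert proper.n == 90 + 1000
            tags = list(proper.assay_tag)
            assert tags.count("new") == 90 and tags.count("old") == 1000

    def test_icp_old_new_single_pair(self, two_assays):
        old, new = two_assays
        pairs = compose("ICP_old_new", old, new)
        assert len(pairs) == 1
        proper, calib = pairs[0]
        assert proper.n == old.n and set(proper.assay_tag) == {"old"}
        assert calib.n == new.n and set(calib.assay_tag) == {"new"}

    def test_ccp_at2_calibration_augmented_with_new(self):
        old = make_regression_dataset(n=1000, seed=3, assay="old")
        new = make_regression_dataset(n=100, seed=4, assay="new")
        pairs = compose("CCP_AT2", old, new, k=10, seed=0)
        for proper, calib in pairs:
            assert calib.n == 100 + 100
            tags = list(calib.assay_tag)
            assert tags.count("old") == 100 and tags.count("new") == 100
            assert set(proper.assay_tag) == {"old"} and proper.n == 900

    def test_ccp_pool_mixes_assays(self, two_assays):
        old, new = two_assays
        pairs = compose("CCP_pool", old, new, k=10, seed=0)
        all_calib_tags = np.concatenate([c.assay_tag for _, c in pairs])
        assert set(all_calib_tags) == {"old", "new"}

    def test_exchangeability_bookkeeping(self, two_assays):
        old, new = two_assays
        for name in STRATEGIES:
            pairs = compose(name, old, new, k=5, seed=0)
            all_new = all(set(c.assay_tag) == {"new"} for _, c in pairs)
            assert all_new == calibration_all_new(name)

    def test_proper_and_calib_disjoint_within_each_icp(self, two_assays):
        old, new = two_assays
        for name in ("CCP_new", "CCP_old", "CCP_pool", "CCP_AT2"):
            for proper, calib in compose(name, old, new, k=5, seed=0):
                pc = set(map(float, proper.y)) & set(map(float, calib.y))
                # targets are continuous draws: overlap implies shared rows
                if name != "CCP_AT2":
                    assert not pc

    def test_unknown_strategy_rejected(self, two_assays):
        old, new = two_assays
        with pytest.raises(ValueError, match="CCP_new"):
            compose("CCP_blah", old, new)

    def test_mondrian_minimum_calibration_refusal(self):
        old = make_classification_dataset(n=100, seed=5, assay="old")
        new = make_classification_dataset(n=100, seed=6, assay="new")
        # all-active tiny new assay: some calibration fold lacks a class
        new.y[:] = "A"
        with pytest.raises(CalibrationError, match="class"):
            compose("CCP_new", old, new, k=10, seed=0)


class TestAggregation:
    def test_median_p_values(self):
        out = aggregate_p_values(
            [{"A": np.array([0.1])}, {"A": np.array([0.3])}, {"A": np.array([0.8])}]
        )
        assert out["A"][0] == pytest.approx(0.3)

    def test_even_k_midpoint_and_lower(self):
        dicts = [{"A": np.array([0.2])}, {"A": np.array([0.4])}]
        assert aggregate_p_values(dicts)["A"][0] == pytest.approx(0.3)
        assert aggregate_p_values(dicts, median_rule="lower")["A"][0] == pytest.approx(
            0.2
        )

    def test_k_of_one_is_identity(self):
        out = aggregate_p_values([{"A": np.array([0.42, 0.7])}])
        np.testing.assert_allclose(out["A"], [0.42, 0.7])

    def test_ragged_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_p_values([{"A": np.array([0.1])}, {"B": np.array([0.1])}])

    def test_median_intervals_componentwise(self):
        ivs = [
            PredictionInterval(np.array([6.0]), np.array([2.0]), 0.8),  # [4, 8]
            PredictionInterval(np.array([7.0]), np.array([2.0]), 0.8),  # [5, 9]
            PredictionInterval(np.array([8.0]), np.array([2.0]), 0.8),  # [6, 10]
        ]
        agg = aggregate_intervals(ivs)
        assert agg.lower[0] == pytest.approx(5.0)
        assert agg.upper[0] == pytest.approx(9.0)

    def test_identical_intervals_idempotent(self):
        ivs = [PredictionInterval(np.array([5.0]), np.array([1.0]), 0.8)] * 5
        agg = aggregate_intervals(ivs)
        assert agg.lower[0] == pytest.approx(4.0)
        assert agg.upper[0] == pytest.approx(6.0)

    def test_one_infinite_member_stays_finite(self):
        ivs = [
            PredictionInterval(np.array([5.0]), np.array([w]), 0.8)
            for w in [1.0] * 9 + [np.inf]
        ]
        agg = aggregate_intervals(ivs)
        assert np.isfinite(agg.width[0])

    def test_mixed_confidences_rejected(self):
        ivs = [
            PredictionInterval(np.array([5.0]), np.array([1.0]), 0.8),
            PredictionInterval(np.array([5.0]), np.array([1.0]), 0.9),
        ]
        with pytest.raises(ValueError, match="confidence"):
            aggregate_intervals(ivs)


class TestFitStrategy:
    def test_deterministic_predictions(self, two_assays):
        old, new = two_assays
        test_X = new.X[:10]
        a = fit_strategy("CCP_pool", old, new, k=5, seed=9).predict_interval(test_X, 0.8)
        b = fit_strategy("CCP_pool", old, new, k=5, seed=9).predict_interval(test_X, 0.8)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_mondrian_used_in_all_classification_strategies(self):
        old = make_classification_dataset(n=120, seed=7, assay="old")
        new = make_classification_dataset(n=120, seed=8, assay="new")
        for name in STRATEGIES:
            model = fit_strategy(name, old, new, k=4 if name != "ICP_old_new" else 1, seed=0)
            for icp in model.icps:
                assert set(icp.calib_alphas) == {"A", "N"}

    def test_interval_grid_matches_pointwise_prediction(self, two_assays):
        old, new = two_assays
        model = fit_strategy("CCP_new", None, new, k=5, seed=1)
        grid = [0.5, 0.8]
        by_conf = model.interval_grid(new.X[:8], grid)
        for c in grid:
            direct = model.predict_interval(new.X[:8], c)
            np.testing.assert_allclose(by_conf[c].lower, direct.lower)
            np.testing.assert_allclose(by_conf[c].upper, direct.upper)


class TestShiftValidityInvariants:
    def test_all_strategies_valid_in_no_shift_limit(self):
        """When old and new assays are statistically identical, every
        composition keeps interval coverage at the confidence level."""
        from assaycp import GeneratorConfig, generate_two_assay

        covs = {name: [] for name in STRATEGIES}
        for s in (101, 102, 103, 104, 105):
            cfg = GeneratorConfig.no_shift(seed=s, n_old=400, n_new=400)
            A_old, A_new, _ = generate_two_assay(cfg, "regression")
            train = A_new.subset(np.arange(200))
            test = A_new.subset(np.arange(200, 400))
            for name in STRATEGIES:
                model = fit_strategy(name, A_old, train, k=5, seed=s)
                covs[name].append(
                    np.mean(model.predict_interval(test.X, 0.8).contains(test.y))
                )
        for name, c in covs.items():
            assert np.mean(c) >= 0.8 - 0.05, (name, np.mean(c))

    def test_slope_mismatch_monotonically_degrades_pooling(self):
        """CCP_pool's coverage at confidence 0.8 decreases as the
        inter-assay slope mismatch grows (averaged over seeds)."""
        from assaycp import GeneratorConfig, generate_two_assay

        mean_cov = []
        for slope in (1.0, 0.8, 0.6):
            covs = []
            for s in (201, 202, 203, 204, 205):
                cfg = GeneratorConfig(
                    seed=s, n_old=1000, n_new=400, slope=slope, offset_pic50=0.0
                )
                A_old, A_new, _ = generate_two_assay(cfg, "regression")
                train = A_new.subset(np.arange(150))
                test = A_new.subset(np.arange(150, 400))
                model = fit_strategy("CCP_pool", A_old, train, k=5, seed=s)
                covs.append(
                    np.mean(model.predict_interval(test.X, 0.8).contains(test.y))
                )
            mean_cov.append(np.mean(covs))
        assert mean_cov[0] > mean_cov[1] > mean_cov[2]
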