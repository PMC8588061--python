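"""Glucose accuracy metrics and Clarke error-grid geometry."""

import numpy as np
import pytest

from glucoheat.evaluation import (
    MGDL_PER_MMOLL,
    clarke_zones,
    corr,
    evaluate,
    mad_conventional,
    mad_printed,
    mard,
    rmse,
    sep,
    zone_percentages,
)


def _random_pairs(seed, n=200):
    rng = np.random.default_rng(seed)
    X = rng.uniform(3.0, 12.0, n)
    Y = X * (1 + 0.1 * rng.standard_normal(n))
    return X, np.abs(Y) + 0.1


class TestMard:
    def test_identity_is_zero(self):
        X = np.array([4.0, 6.0, 9.0])
        assert mard(X, X) == 0.0

    def test_hand_arithmetic(self):
        assert mard([4.0, 5.0], [5.0, 4.0]) == pytest.approx(22.5)

    def test_scale_invariance(self):
        X, Y = _random_pairs(0)
        assert mard(3 * X, 3 * Y) == pytest.approx(mard(X, Y), rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            mard([0.0, 5.0], [1.0, 5.0])

    def test_matches_definitional_transcription(self):
        X, Y = _random_pairs(1)
        assert mard(X, Y) == pytest.approx(
            sum(abs(y - x) / x for x, y in zip(X, Y)) / len(X) * 100, rel=1e-12
        )


class TestCorr:
    def test_perfect_positive_and_negative(self):
        X = np.array([4.0, 5.0, 7.0])
        assert corr(X, X) == pytest.approx(1.0)
        assert corr(X, -X + 20) == pytest.approx(-1.0)

    def test_definitional_covariance_formula(self):
        X = np.array([1.0, 2.0, 3.0])
        Y = np.array([1.0, 2.0, 4.0])
        num = np.sum((X - X.mean()) * (Y - Y.mean()))
        den = np.sqrt(np.sum((X - X.mean()) ** 2) * np.sum((Y - Y.mean()) ** 2))
        assert corr(X, Y) == pytest.approx(num / den, rel=1e-12)

    def test_constant_series_undefined(self):
        with pytest.raises(ValueError):
            corr([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])


class TestMad:
    def test_constant_predictions_have_no_spread(self):
        assert mad_printed([4.0, 9.0], [6.0, 6.0]) == 0.0

    def test_two_point_spread(self):
        assert mad_printed([1.0, 1.0], [1.0, 3.0]) == pytest.approx(1.0)

    def test_hand_arithmetic_about_prediction_mean(self):
        assert mad_printed([1.0] * 3, [1.0, 2.0, 6.0]) == pytest.approx(2.0)

    def test_conventional_variant_uses_reference(self):
        assert mad_conventional([4.0, 5.0], [5.0, 4.0]) == pytest.approx(1.0)


class TestRmseSep:
    def test_identity_is_zero(self):
        X = np.array([4.0, 6.0])
        assert rmse(X, X) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([3.0, 4.0], [6.0, 8.0]) == pytest.approx(np.sqrt(25 / 2))

    def test_rmse_dominates_mean_absolute_error(self):
        X, Y = _random_pairs(2)
        assert rmse(X, Y) >= mad_conventional(X, Y)

    def test_sep_ignores_constant_bias(self):
        X = np.array([4.0, 6.0, 8.0])
        assert sep(X, X + 1.5) == pytest.approx(0.0, abs=1e-12)

    def test_sep_definitional_value(self):
        assert sep([5.0, 5.0], [4.0, 6.0]) == pytest.approx(np.sqrt(2.0))

    def test_sep_translation_invariance(self):
        X, Y = _random_pairs(3)
        assert sep(X, Y + 2.0) == pytest.approx(sep(X, Y), rel=1e-12)

    def test_sep_divisor_configurable(self):
        X, Y = _random_pairs(4)
        e = Y - X
        assert sep(X, Y, ddof=0) == pytest.approx(np.std(e), rel=1e-12)

    def test_linear_scaling_of_absolute_metrics(self):
        X, Y = _random_pairs(5)
        for metric in (rmse, mad_conventional, mad_printed, sep):
            assert metric(2 * X, 2 * Y) == pytest.approx(2 * metric(X, Y), rel=1e-12)


def zone_oracle(x, y):
    """Second, independently coded transcription of the Clarke grid (mg/dL).

    Written from the published piecewise inequalities in a different order
    and style than the library implementation.
    """
    within20 = abs(y - x) <= 0.2 * x
    if within20 or (x < 70 and y < 70):
        return "A"
    if (x >= 180 and y <= 70) or (x <= 70 and y >= 180):
        return "E"
    upper_c = 70 <= x <= 290 and y - x >= 110
    lower_c = 130 <= x <= 180 and y <= 1.4 * x - 182
    if upper_c or lower_c:
        return "C"
    right_d = x >= 240 and 70 <= y <= 180
    left_d = (x <= 175 / 3 and 70 <= y <= 180) or (
        175 / 3 <= x <= 70 and y >= 1.2 * x
    )
    if right_d or left_d:
        return "D"
    return "B"


class TestClarke:
    def test_identity_is_all_zone_a(self):
        X = np.linspace(4.1, 10.0, 25)
        zones = clarke_zones(X, X)
        assert set(zones) == {"A"}
        assert zone_percentages(zones)["A"] == 100.0

    def test_twenty_percent_boundary_in_normoglycemia(self):
        ref = 150.0 / MGDL_PER_MMOLL  # 150 mg/dL expressed in mmol/L
        inside = clarke_zones([ref], [ref * 1.199])[0]
        at = clarke_zones([ref], [ref * 1.200])[0]
        outside = clarke_zones([ref], [ref * 1.201])[0]
        assert (inside, at, outside) == ("A", "A", "B")

    def test_one_canonical_point_per_zone(self):
        # mg/dL pairs chosen inside each zone of the published grid
        pairs = {
            "A": (100.0, 110.0),
            "B": (150.0, 200.0),
            "C": (150.0, 280.0),
            "D": (250.0, 120.0),
            "E": (50.0, 250.0),
        }
        refs = [p[0] for p in pairs.values()]
        preds = [p[1] for p in pairs.values()]
        zones = clarke_zones(refs, preds, units="mg/dL")
        assert list(zones) == list(pairs)
        assert all(v == 20.0 for v in zone_percentages(zones).values())

    def test_agrees_with_independent_transcription_on_random_grid(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(20, 400, 500)
        Y = rng.uniform(20, 400, 500)
        zones = clarke_zones(X, Y, units="mg/dL")
        expected = [zone_oracle(x, y) for x, y in zip(X, Y)]
        assert list(zones) == expected

    def test_percentages_sum_to_100_and_partition(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(2.0, 20.0, 300)
        Y = np.abs(X + rng.normal(0, 3.0, 300)) + 0.5
        zones = clarke_zones(X, Y)
        assert sum(zone_percentages(zones).values()) == pytest.approx(100.0, abs=1e-9)
        assert all(z in "ABCDE" for z in zones)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            clarke_zones([5.0, -1.0], [5.0, 5.0])


class TestEvaluateReport:
    def test_report_is_consistent_with_individual_metrics(self):
        X, Y = _random_pairs(9)
        rep = evaluate(X, Y)
        assert rep.n == len(X)
        assert rep.mARD == pytest.approx(mard(X, Y))
        assert rep.CORR == pytest.approx(corr(X, Y))
        assert rep.RMSE == pytest.approx(rmse(X, Y))
        assert rep.SEP == pytest.approx(sep(X, Y))
        assert sum(rep.zone_percentages.values()) == pytest.approx(100.0)
        assert "mARD" in rep.summary()
        assert "clarke_zone_percent" in rep.to_json()
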