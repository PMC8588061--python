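"""Interaction design matrix, MPR4 least squares, BPNN training, hold-out."""

import itertools
import json

import numpy as np
import pytest

from glucoheat.models import (
    BPNN,
    BPNNConfig,
    FEATURE_NAMES,
    FeatureRecord,
    MPR4,
    MPR4_TERMS,
    build_design_matrix,
    holdout_split,
    load_results,
)


def brute_force_design(X):
    """Oracle: enumerate all distinct-predictor products of size 1..4."""
    cols = []
    for k in (1, 2, 3, 4):
        for combo in itertools.combinations(range(4), k):
            cols.append(np.prod(X[:, combo], axis=1))
    return np.column_stack(cols)


@pytest.fixture
def training_data():
    rng = np.random.default_rng(42)
    X = rng.uniform(0.5, 2.0, (120, 4))
    return X


class TestDesignMatrix:
    def test_exactly_fifteen_interaction_columns(self):
        X = np.ones((3, 4))
        assert build_design_matrix(X).shape == (3, 15)
        assert len(MPR4_TERMS) == 15

    def test_matches_brute_force_enumeration(self, training_data):
        D = build_design_matrix(training_data)
        # same column set as the subset enumeration (order may differ)
        oracle = brute_force_design(training_data)
        assert D.shape == oracle.shape
        matched = {
            j: next(
                i for i in range(15) if np.allclose(oracle[:, i], D[:, j])
            )
            for j in range(15)
        }
        assert sorted(matched.values()) == list(range(15))

    def test_all_zero_record_gives_zero_row(self):
        row = build_design_matrix(np.zeros((1, 4)))
        assert np.all(row == 0)

    def test_quadruple_product_column(self):
        row = build_design_matrix(np.array([[1.0, 2.0, 3.0, 4.0]]))
        assert row[0, -1] == 24.0

    def test_nonfinite_feature_named(self):
        X = np.ones((3, 4))
        X[1, 2] = np.nan
        with pytest.raises(ValueError, match="row 1.*HR"):
            build_design_matrix(X)

    def test_accepts_feature_records(self):
        recs = [FeatureRecord(H=1.0, SpO2=2.0, HR=3.0, BF=4.0)]
        assert build_design_matrix(recs)[0, -1] == 24.0


class TestMPR4:
    def test_exact_recovery_of_generating_coefficients(self, training_data):
        rng = np.random.default_rng(1)
        truth = rng.normal(0, 1, 16)
        y = truth[0] + build_design_matrix(training_data) @ truth[1:]
        res = MPR4(training_data, endog=y).fit()
        assert np.allclose(np.r_[res.intercept, res.coefficients], truth, atol=1e-6)
        assert np.max(np.abs(res.predict(training_data) - y)) < 1e-8

    def test_constant_target_degenerates_to_intercept(self, training_data):
        y = np.full(len(training_data), 6.5)
        res = MPR4(training_data, endog=y).fit()
        assert res.intercept == pytest.approx(6.5, abs=1e-8)
        assert np.allclose(res.coefficients, 0.0, atol=1e-8)

    def test_sample_size_rule_refuses_45(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.5, 2.0, (45, 4))
        with pytest.raises(ValueError, match="45"):
            MPR4(X, endog=rng.uniform(4, 10, 45)).fit()

    def test_rank_deficiency_names_collinear_columns(self, training_data):
        X = training_data.copy()
        X[:, 1] = 0.0  # SpO2 identically zero kills every column containing it
        y = np.ones(len(X)) + X[:, 0]
        with pytest.raises(ValueError, match="SpO2"):
            MPR4(X, endog=y).fit()

    def test_prediction_is_rowwise(self, training_data):
        y = training_data @ np.array([1.0, 2.0, 3.0, 4.0]) + 1
        res = MPR4(training_data, endog=y).fit()
        perm = np.random.default_rng(3).permutation(len(training_data))
        assert np.allclose(
            res.predict(training_data[perm]), res.predict(training_data)[perm]
        )

    def test_all_zero_record_predicts_intercept(self, training_data):
        y = training_data.sum(axis=1)
        res = MPR4(training_data, endog=y).fit()
        assert res.predict(np.zeros((1, 4)))[0] == pytest.approx(res.intercept)

    def test_nested_rss_non_increasing(self, training_data):
        # adding interaction columns can only reduce the residual sum of squares
        rng = np.random.default_rng(4)
        y = training_data @ rng.normal(size=4) + rng.normal(0, 0.3, len(training_data))
        D = build_design_matrix(training_data)
        rss = []
        for k in range(1, 16):
            A = np.column_stack([np.ones(len(D)), D[:, :k]])
            r = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            rss.append(r @ r)
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))

    def test_serialization_round_trip(self, training_data, tmp_path):
        y = training_data.sum(axis=1) + 5
        res = MPR4(training_data, endog=y).fit()
        res.save(tmp_path / "m.json")
        loaded = load_results(tmp_path / "m.json")
        assert np.allclose(loaded.predict(training_data), res.predict(training_data))
        assert "mpr4" in (tmp_path / "m.json").read_text()

    def test_summary_names_terms(self, training_data):
        y = training_data.sum(axis=1)
        s = MPR4(training_data, endog=y).fit().summary()
        assert "H*SpO2*HR*BF" in s and "intercept" in s


class TestBPNN:
    def test_architecture_is_4_9_1(self, training_data):
        net = BPNN(training_data, endog=training_data.sum(axis=1))
        assert (net.n_in, net.n_hid) == (4, 9)
        res = net.fit()
        assert res.W1.shape == (9, 4) and res.w2.shape == (9,)

    def test_seeded_fit_is_bit_identical(self, training_data):
        y = training_data.sum(axis=1)
        r1 = BPNN(training_data, endog=y, seed=11).fit()
        r2 = BPNN(training_data, endog=y, seed=11).fit()
        assert np.array_equal(r1.W1, r2.W1)
        assert np.array_equal(r1.b1, r2.b1)
        assert np.array_equal(r1.w2, r2.w2)
        assert r1.b2 == r2.b2

    def test_noiseless_linear_target_learned_below_one_percent(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 2, (200, 4))
        y = 2 * X[:, 0] + X[:, 2] + 3.0
        res = BPNN(X, endog=y, seed=0).fit()
        mard = np.mean(np.abs(res.predict(X) - y) / y) * 100
        assert mard < 1.0

    def test_forward_pass_matches_independent_transcription(self, training_data):
        y = training_data.sum(axis=1)
        res = BPNN(training_data, endog=y, seed=5).fit()
        Xs = (training_data - res.x_mean) / res.x_std
        by_hand = np.tanh(Xs @ res.W1.T + res.b1) @ res.w2 + res.b2
        by_hand = by_hand * res.y_half + res.y_mid
        assert np.allclose(res.predict(training_data), by_hand, atol=0, rtol=0)

    def test_zero_weights_give_constant_output_bias(self, training_data):
        y = training_data.sum(axis=1)
        res = BPNN(training_data, endog=y, seed=0).fit()
        res.W1[:] = 0.0
        res.b1[:] = 0.0
        res.w2[:] = 0.0
        res.b2 = 4.2
        pred = res.predict(training_data)
        expected = 4.2 * res.y_half + res.y_mid
        assert np.allclose(pred, expected)

    def test_training_loss_non_increasing(self, training_data):
        rng = np.random.default_rng(6)
        y = training_data @ rng.normal(size=4) + rng.normal(0, 0.2, len(training_data))
        res = BPNN(training_data, endog=y, seed=6).fit()
        assert np.all(np.diff(res.loss_history) <= 0)

    def test_minimum_sample_size(self):
        X = np.ones((10, 4))
        with pytest.raises(ValueError, match="20"):
            BPNN(X, endog=np.ones(10))

    def test_extrapolation_warns(self, training_data):
        y = training_data.sum(axis=1)
        res = BPNN(training_data, endog=y, seed=0).fit()
        far = np.full((1, 4), 1e4)
        with pytest.warns(UserWarning, match="extrapolation"):
            res.predict(far)

    def test_serialization_round_trip(self, training_data, tmp_path):
        y = training_data.sum(axis=1)
        res = BPNN(training_data, endog=y, seed=1).fit()
        res.save(tmp_path / "net.json")
        loaded = load_results(tmp_path / "net.json")
        assert np.allclose(loaded.predict(training_data), res.predict(training_data))
        d = json.loads((tmp_path / "net.json").read_text())
        assert d["kind"] == "bpnn" and d["seed"] == 1


class TestHoldout:
    def test_partition_property(self):
        tr, te = holdout_split(range(211), seed=0)
        assert len(tr) + len(te) == 211
        assert len(np.intersect1d(tr, te)) == 0
        assert np.array_equal(np.sort(np.r_[tr, te]), np.arange(211))

    def test_default_fraction_gives_118_training_records(self):
        tr, _ = holdout_split(range(211), seed=3)
        assert len(tr) == 118

    def test_same_seed_same_split(self):
        assert np.array_equal(
            holdout_split(range(100), seed=9)[0], holdout_split(range(100), seed=9)[0]
        )

    def test_different_seed_differs(self):
        assert not np.array_equal(
            holdout_split(range(100), seed=1)[0], holdout_split(range(100), seed=2)[0]
        )

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            holdout_split(range(10), train_fraction=1.0)


class TestFeatureRecord:
    def test_field_order_matches_predictor_convention(self):
        rec = FeatureRecord(H=1.0, SpO2=2.0, HR=3.0, BF=4.0, bg_ref=5.0)
        assert np.array_equal(rec.x, [1.0, 2.0, 3.0, 4.0])
        assert FEATURE_NAMES == ("H", "SpO2", "HR", "BF")

    def test_validation(self):
        with pytest.raises(ValueError):
            FeatureRecord(H=np.inf, SpO2=2.0, HR=3.0, BF=4.0)
        with pytest.raises(ValueError):
            FeatureRecord(H=1.0, SpO2=2.0, HR=3.0, BF=4.0, bg_ref=-1.0)
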