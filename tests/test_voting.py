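import numpy as np
import pandas as pd
import pytest

import maldivote as mv
from maldivote.errors import ConfigurationError, DataError
from maldivote.voting import (
    PUBLISHED_SIGNATURE_MZ,
    PUBLISHED_SIGNATURE_PROTEINS,
    CrossValCurve,
    VotingResults,
    WeightedVoting,
    extract_shared_signature,
    loocv_curve,
    _fold_s0,
)
from conftest import gaussian_cohort_table, make_table
from oracles import loocv_errors_brute


def two_by_two_table():
    return make_table(
        np.array([[5.0], [7.0], [1.0], [3.0]]),
        labels=["PDAC", "PDAC", "healthy", "healthy"],
    )


class TestFit:
    def test_hand_example(self):
        res = WeightedVoting(two_by_two_table()).fit()
        row = res.params.iloc[0]
        assert row["mean_case"] == 6.0 and row["mean_control"] == 2.0
        assert row["sd_case"] == pytest.approx(np.sqrt(2))
        assert row["weight"] == pytest.approx(4 / (2 * np.sqrt(2)))
        assert row["boundary"] == pytest.approx(4.0)

    def test_label_swap_negates_weight_keeps_boundary(self):
        t = two_by_two_table()
        res = WeightedVoting(t).fit()
        swapped = make_table(
            t.intensities.to_numpy(),
            labels=["healthy", "healthy", "PDAC", "PDAC"],
        )
        res2 = WeightedVoting(swapped).fit()
        assert res2.params["weight"].iloc[0] == pytest.approx(
            -res.params["weight"].iloc[0]
        )
        assert res2.params["boundary"].iloc[0] == pytest.approx(
            res.params["boundary"].iloc[0]
        )

    def test_constant_shift_moves_boundary_not_weight(self):
        t = two_by_two_table()
        res = WeightedVoting(t).fit()
        shifted = make_table(t.intensities.to_numpy() + 10.0,
                             labels=list(t.labels))
        res2 = WeightedVoting(shifted).fit()
        assert res2.params["weight"].iloc[0] == pytest.approx(
            res.params["weight"].iloc[0]
        )
        assert res2.params["boundary"].iloc[0] == pytest.approx(
            res.params["boundary"].iloc[0] + 10.0
        )

    def test_zero_spread_signal_rejected(self):
        t = make_table(np.array([[1.0], [1.0], [1.0], [1.0]]),
                       labels=["PDAC", "PDAC", "healthy", "healthy"])
        with pytest.raises(DataError, match="2000.0"):
            WeightedVoting(t).fit()


class TestPredict:
    def test_boundary_sample_votes_noncancer(self):
        res = WeightedVoting(two_by_two_table()).fit()
        pred = res.predict(pd.DataFrame({"2000.0": [4.0]}, index=["x"]))
        assert pred.loc["x", "voting_sum"] == pytest.approx(0.0)
        assert pred.loc["x", "predicted"] == "noncancer"

    def test_positive_sample(self):
        res = WeightedVoting(two_by_two_table()).fit()
        pred = res.predict(pd.DataFrame({"2000.0": [7.0]}, index=["x"]))
        assert pred.loc["x", "voting_sum"] == pytest.approx(3 * np.sqrt(2))
        assert pred.loc["x", "predicted"] == "PDAC"

    def test_prediction_strength_from_votes(self):
        # two signals with votes +2 and -1: PS = (2-1)/(2+1)
        params = pd.DataFrame(
            {
                "mz": [3000.0, 4000.0],
                "mean_case": [0, 0], "mean_control": [0, 0],
                "sd_case": [1, 1], "sd_control": [1, 1],
                "weight": [2.0, -1.0],
                "boundary": [0.0, 0.0],
            },
            index=pd.Index(["a", "b"], name="signal_id"),
        )
        res = VotingResults(params=params, n_case=2, n_control=2)
        pred = res.predict(pd.DataFrame({"a": [1.0], "b": [1.0]}, index=["x"]))
        assert pred.loc["x", "voting_sum"] == pytest.approx(1.0)
        assert pred.loc["x", "prediction_strength"] == pytest.approx(1 / 3)
        assert pred.loc["x", "predicted"] == "PDAC"

    def test_missing_signature_signal_errors(self):
        res = WeightedVoting(two_by_two_table()).fit()
        with pytest.raises(DataError):
            res.predict(pd.DataFrame({"9999.9": [1.0]}, index=["x"]))

    def test_prediction_strength_bounded(self):
        rng = np.random.default_rng(2)
        t = gaussian_cohort_table(rng, 10, 10, 12, effects={0: 2.0, 1: 1.0})
        res = WeightedVoting(t).fit()
        ps = res.predict(t)["prediction_strength"]
        assert ((ps >= 0) & (ps <= 1)).all()

    def test_label_swap_negates_voting_sums(self):
        rng = np.random.default_rng(3)
        t = gaussian_cohort_table(rng, 8, 8, 10, effects={0: 2.0})
        flipped = ["healthy" if c == "PDAC" else "PDAC" for c in t.labels]
        t2 = make_table(t.intensities.to_numpy(), labels=flipped)
        v1 = WeightedVoting(t).fit().predict(t)["voting_sum"]
        v2 = WeightedVoting(t2).fit().predict(t)["voting_sum"]
        np.testing.assert_allclose(v1.to_numpy(), -v2.to_numpy())

    def test_affine_invariance_of_calls(self):
        """Common positive scaling plus per-signal shifts leave every
        predicted class unchanged."""
        rng = np.random.default_rng(4)
        t = gaussian_cohort_table(rng, 10, 10, 8, effects={0: 2.0, 3: -1.5})
        shifts = rng.normal(0, 5, size=8)
        X2 = 3.7 * t.intensities.to_numpy() + shifts[None, :]
        t2 = make_table(X2, labels=list(t.labels))
        p1 = WeightedVoting(t).fit().predict(t)["predicted"]
        p2 = WeightedVoting(t2).fit().predict(t2)["predicted"]
        assert (p1 == p2).all()


class TestLoocvCurve:
    def test_k_max_one(self):
        rng = np.random.default_rng(5)
        t = gaussian_cohort_table(rng, 5, 5, 6, effects={0: 3.0})
        curve = loocv_curve(t, candidate_ids=t.signal_ids, k_max=1)
        assert len(curve.ks) == 1 and curve.optimal_k == 1

    def test_invalid_k_max(self):
        rng = np.random.default_rng(5)
        t = gaussian_cohort_table(rng, 5, 5, 6)
        with pytest.raises(ConfigurationError):
            loocv_curve(t, candidate_ids=t.signal_ids, k_max=0)
        with pytest.raises(ConfigurationError):
            loocv_curve(t, candidate_ids=t.signal_ids, k_max=7)

    def test_matches_brute_force_oracle(self):
        """LOOCV error counts equal a from-scratch reimplementation."""
        rng = np.random.default_rng(6)
        t = gaussian_cohort_table(rng, 9, 9, 20,
                                  effects={0: 2.5, 1: -2.0, 2: 1.0})
        k_max = 8
        curve = loocv_curve(t, candidate_ids=t.signal_ids, k_max=k_max)
        mis = loocv_errors_brute(
            t.intensities.to_numpy(),
            (t.labels == "PDAC").to_numpy(),
            t.mz.to_numpy(),
            k_max,
            _fold_s0,
        )
        np.testing.assert_array_equal(curve.misclassifications, mis)

    def test_recovery_optimal_k_small(self):
        """Planted d = 3 drivers among noise: minimum lands at few signals."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = mv.CohortConfig(
                n_cases=30, n_controls=30, n_signals=205, n_differential=5,
                n_strong=5, strong_effect=3.0, seed=400 + seed,
            )
            spectra, sheet, _ = mv.generate_cohort(cfg)
            from maldivote.pipeline import build_feature_table
            from maldivote.preprocessing import BinningConfig

            t = build_feature_table(spectra, sheet, BinningConfig())
            curve = loocv_curve(t, candidate_ids=t.signal_ids, k_max=30)
            hits += 3 <= curve.optimal_k <= 10
        assert hits / n_seeds >= 0.8

    def test_null_labels_give_no_spurious_fit(self):
        """Randomly permuted labels: even the best k misclassifies a
        substantial fraction."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            t = gaussian_cohort_table(rng, 30, 30, 200)
            curve = loocv_curve(t, candidate_ids=t.signal_ids, k_max=30)
            hits += curve.misclassifications.min() >= 0.25 * t.n_samples
        assert hits / n_seeds >= 0.9


class TestSharedSignature:
    def _curve(self, fold_orders, d_frame):
        return CrossValCurve(
            ks=np.array([1, 2]),
            misclassifications=np.array([1, 0]),
            optimal_k=2,
            fold_orders=fold_orders,
            fold_d=d_frame,
            n_samples=len(fold_orders),
        )

    def test_frequency_counting(self):
        d = pd.DataFrame(1.0, index=range(3), columns=["a", "b", "c"])
        curve = self._curve([["a", "b"], ["a", "c"], ["a", "b"]], d)
        assert extract_shared_signature(curve, 2) == ["a", "b"]

    def test_identical_folds_returned_verbatim(self):
        d = pd.DataFrame(1.0, index=range(3), columns=["a", "b"])
        curve = self._curve([["b", "a"]] * 3, d)
        assert set(extract_shared_signature(curve, 2)) == {"a", "b"}

    def test_tie_broken_by_mean_abs_d(self):
        d = pd.DataFrame({"a": [1.0, 1.0], "b": [3.0, 3.0], "c": [2.0, 2.0]})
        curve = self._curve([["a", "b"], ["c", "b"]], d)
        # frequencies: b=2, a=1, c=1; tie a/c -> larger |d| wins (c)
        assert extract_shared_signature(curve, 2) == ["b", "c"]

    def test_k_exceeding_distinct_signals_errors(self):
        d = pd.DataFrame({"a": [1.0]})
        curve = self._curve([["a"]], d)
        with pytest.raises(ConfigurationError):
            extract_shared_signature(curve, 2)


def test_published_signature_constant_is_consistent():
    assert len(PUBLISHED_SIGNATURE_MZ) == 7
    assert list(PUBLISHED_SIGNATURE_MZ) == sorted(PUBLISHED_SIGNATURE_MZ)
    assert set(PUBLISHED_SIGNATURE_PROTEINS) <= set(PUBLISHED_SIGNATURE_MZ)


def test_model_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    t = gaussian_cohort_table(rng, 6, 6, 5, effects={0: 2.0})
    res = WeightedVoting(t).fit()
    path = tmp_path / "model.tsv"
    res.save(path)
    loaded = VotingResults.load(path)
    pd.testing.assert_frame_equal(res.params, loaded.params)
    assert loaded.n_case == 6 and loaded.positive == "PDAC"
    pred1 = res.predict(t)
    pred2 = loaded.predict(t)
    pd.testing.assert_frame_equal(pred1, pred2)
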