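import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import maldivote as mv
from maldivote.errors import ConfigurationError, DataError
from maldivote.screen import (
    SelectionCriteria,
    bonferroni,
    estimate_s0,
    fisher_per_signal,
    kruskal_wallis_per_signal,
    pooled_se,
    sam_fdr,
    sam_statistic,
    select_signals,
)
from conftest import gaussian_cohort_table, make_table
from oracles import fisher_two_sided_enum, kruskal_h_and_p, sam_d_brute


class TestFisherPerSignal:
    def test_separated_groups_median_split(self):
        t = make_table(np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]]),
                       labels=["PDAC"] * 3 + ["healthy"] * 3)
        p = fisher_per_signal(t, rule="median-split")
        # table [[0,3],[3,0]]: enumeration over margins (3,3) gives 0.10
        assert p.iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_constant_signal_gives_p_one(self):
        t = make_table(np.full((6, 1), 4.0), labels=["PDAC"] * 3 + ["healthy"] * 3)
        assert fisher_per_signal(t).iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        t = gaussian_cohort_table(rng, 7, 9, 25, effects={0: 2.0, 1: -1.5})
        p = fisher_per_signal(t)
        X = t.intensities.to_numpy()
        case = (t.labels == "PDAC").to_numpy()
        for j in range(t.n_signals):
            high = X[:, j] > np.median(X[:, j])
            a = int((high & case).sum())
            b = int((~high & case).sum())
            c = int((high & ~case).sum())
            d = int((~high & ~case).sum())
            assert p.iloc[j] == pytest.approx(
                fisher_two_sided_enum(a, b, c, d), rel=1e-9
            )

    def test_presence_rule(self):
        t = make_table(np.array([[1.0], [1.0], [0.0], [0.0]]),
                       labels=["PDAC"] * 2 + ["healthy"] * 2)
        p = fisher_per_signal(t, rule="nonzero-presence")
        assert p.iloc[0] == pytest.approx(fisher_two_sided_enum(2, 0, 0, 2))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        t = gaussian_cohort_table(rng, 6, 6, 10)
        t2 = make_table(np.exp(t.intensities.to_numpy()),
                        labels=list(t.labels))
        pd.testing.assert_series_equal(fisher_per_signal(t), fisher_per_signal(t2))


class TestKruskalWallis:
    def test_hand_example(self):
        t = make_table(np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]),
                       labels=["PDAC"] * 3 + ["healthy"] * 3)
        p = kruskal_wallis_per_signal(t)
        h, p_hand = kruskal_h_and_p([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.857142857)
        assert p.iloc[0] == pytest.approx(p_hand) == pytest.approx(0.0495, abs=5e-4)

    def test_all_tied_gives_p_one(self):
        t = make_table(np.full((6, 1), 2.0), labels=["PDAC"] * 3 + ["healthy"] * 3)
        assert kruskal_wallis_per_signal(t).iloc[0] == 1.0

    def test_matches_scipy_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        X = np.round(rng.normal(0, 1, size=(15, 20)), 1)  # force ties
        t = make_table(X, labels=["PDAC"] * 7 + ["healthy"] * 8)
        p = kruskal_wallis_per_signal(t)
        case = (t.labels == "PDAC").to_numpy()
        for j in range(20):
            expected = stats.kruskal(X[case, j], X[~case, j]).pvalue
            assert p.iloc[j] == pytest.approx(expected, rel=1e-9)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(40):
            t = gaussian_cohort_table(rng, 8, 8, 5)
            ps.extend(kruskal_wallis_per_signal(t).tolist())
        assert np.mean(ps) == pytest.approx(0.5, abs=0.08)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        t = gaussian_cohort_table(rng, 6, 6, 8)
        t2 = make_table(np.exp(t.intensities.to_numpy()), labels=list(t.labels))
        pd.testing.assert_series_equal(
            kruskal_wallis_per_signal(t), kruskal_wallis_per_signal(t2)
        )


class TestSamStatistic:
    def test_equal_means_give_zero(self):
        t = make_table(np.array([[1.0], [3.0], [1.0], [3.0]]),
                       labels=["PDAC", "PDAC", "healthy", "healthy"])
        assert sam_statistic(t, s0=0.5).iloc[0] == pytest.approx(0.0)

    def test_hand_example_and_brute_force(self):
        t = make_table(np.array([[5.0], [7.0], [1.0], [3.0]]),
                       labels=["PDAC", "PDAC", "healthy", "healthy"])
        d = sam_statistic(t, s0=0.0).iloc[0]
        # pooled SE = sqrt((1/2+1/2) * (2+2)/2) = sqrt(2); d = 4/sqrt(2)
        assert d == pytest.approx(4 / np.sqrt(2))
        assert d == pytest.approx(sam_d_brute([5, 7], [1, 3], 0.0))

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(6)
        t = gaussian_cohort_table(rng, 5, 7, 15, effects={2: 1.0})
        d = sam_statistic(t, s0=0.3)
        X = t.intensities.to_numpy()
        case = (t.labels == "PDAC").to_numpy()
        for j in range(15):
            assert d.iloc[j] == pytest.approx(
                sam_d_brute(X[case, j], X[~case, j], 0.3), rel=1e-10
            )

    def test_increasing_s0_shrinks_d(self):
        rng = np.random.default_rng(7)
        t = gaussian_cohort_table(rng, 6, 6, 10, effects={0: 2.0})
        d1 = sam_statistic(t, s0=0.1).abs()
        d2 = sam_statistic(t, s0=0.2).abs()
        nonzero = d1 > 0
        assert (d2[nonzero] < d1[nonzero]).all()

    def test_negative_s0_rejected(self):
        t = gaussian_cohort_table(np.random.default_rng(0), 3, 3, 4)
        with pytest.raises(ConfigurationError):
            sam_statistic(t, s0=-1.0)


class TestEstimateS0:
    def test_result_is_a_candidate_percentile(self):
        rng = np.random.default_rng(10)
        t = gaussian_cohort_table(rng, 10, 10, 60, effects={0: 2.0})
        s0 = estimate_s0(t)
        s = pooled_se(t).to_numpy()
        candidates = np.percentile(s, np.arange(0, 101, 5))
        assert np.isclose(candidates, s0).any()

    def test_constant_se_distribution(self):
        # equal per-signal SE -> any percentile works; function returns one
        X = np.array([[0.0, 0.0], [2.0, 2.0], [1.0, 1.0], [3.0, 3.0]])
        t = make_table(X, labels=["PDAC", "PDAC", "healthy", "healthy"])
        s = pooled_se(t)
        assert s.nunique() == 1
        assert estimate_s0(t) == pytest.approx(s.iloc[0])

    def test_too_few_samples_error(self):
        t = make_table(np.ones((3, 4)), labels=["PDAC", "healthy", "healthy"])
        with pytest.raises(DataError):
            estimate_s0(t)

    def test_selection_robust_to_s0_choice(self):
        """Replacing the tuned s0 by median(s) leaves the selected set
        essentially unchanged (overlap >= 90%)."""
        rng = np.random.default_rng(13)
        effects = {j: 2.5 for j in range(15)}
        t = gaussian_cohort_table(rng, 20, 20, 300, effects=effects)
        crit = SelectionCriteria(n_permutations=200)
        s0_est = estimate_s0(t)
        s0_med = float(np.median(pooled_se(t)))
        sets = []
        for s0 in (s0_est, s0_med):
            d = sam_statistic(t, s0=s0)
            q = sam_fdr(t, d=d, n_permutations=200, seed=1, s0=s0)
            sel = set(q.index[q < crit.sam_fdr_max])
            sets.append(sel)
        a, b = sets
        assert len(a & b) / max(1, len(a | b)) >= 0.9


class TestSamFdr:
    def test_null_calibration(self):
        """On pure noise, essentially no signal reaches q < 0.1%."""
        counts = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            t = gaussian_cohort_table(rng, 20, 20, 300)
            q = sam_fdr(t, n_permutations=200, seed=seed)
            counts.append(int((q < 0.001).sum()))
        expected = 0.001 * 300
        assert np.mean(counts) <= expected + 3 * np.sqrt(expected / len(counts))

    def test_power_on_strong_effects(self):
        """Planted d >= 3 at n = 40+40 reaches q < 0.1% almost always."""
        hits, total = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            effects = {j: 3.0 for j in range(5)}
            t = gaussian_cohort_table(rng, 40, 40, 200, effects=effects)
            q = sam_fdr(t, n_permutations=200, seed=seed)
            hits += int((q.iloc[:5] < 0.001).sum())
            total += 5
        assert hits / total >= 0.95

    def test_invariant_under_signal_relabeling(self):
        rng = np.random.default_rng(14)
        t = gaussian_cohort_table(rng, 8, 8, 30, effects={0: 2.0})
        q1 = sam_fdr(t, n_permutations=150, seed=3)
        # same data, different signal ids
        t2 = make_table(t.intensities.to_numpy(), labels=list(t.labels),
                        mz=3000.0 + 10.0 * np.arange(30))
        q2 = sam_fdr(t2, n_permutations=150, seed=3)
        np.testing.assert_allclose(q1.to_numpy(), q2.to_numpy())

    def test_single_class_rejected(self):
        t = make_table(np.ones((4, 3)), labels=["PDAC"] * 4)
        with pytest.raises(DataError):
            sam_fdr(t, n_permutations=100, seed=0)


class TestBonferroniAndSelection:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(0.00005, 1063, 0.05315), (0.8, 1063, 1.0), (0.123, 1, 0.123)],
    )
    def test_bonferroni_arithmetic(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    @given(p=st.floats(0, 1), m=st.integers(1, 10000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bonferroni_bounds(self, p, m):
        out = bonferroni(p, m)
        assert p <= out <= 1.0

    def test_single_criterion_excluded_under_two_of_three(self):
        frame = pd.DataFrame(
            {
                "p_fisher_bonf": [1.0, 0.001],
                "p_kw_bonf": [0.001, 0.001],
                "sam_q": [0.5, 0.0],
            },
            index=["only_kw", "all_three"],
        )
        crit = SelectionCriteria(min_criteria_met=2)
        assert select_signals(frame, crit) == ["all_three"]
        for m in (1, 2, 3):
            assert "all_three" in select_signals(
                frame, SelectionCriteria(min_criteria_met=m)
            )

    def test_selection_monotone_in_min_criteria(self):
        rng = np.random.default_rng(21)
        t = gaussian_cohort_table(rng, 15, 15, 80,
                                  effects={j: 2.0 for j in range(10)})
        results = {}
        for m in (1, 2, 3):
            crit = SelectionCriteria(min_criteria_met=m, n_permutations=150)
            res = mv.DifferentialScreen(t, crit).fit(seed=2)
            results[m] = set(res.selected_ids)
        assert results[3] <= results[2] <= results[1]

    def test_bonferroni_familywise_error_under_null(self):
        """Permuted labels: any corrected p < alpha is rare (FWER <= alpha)."""
        rng = np.random.default_rng(22)
        t = gaussian_cohort_table(rng, 15, 15, 150)
        hits = 0
        n_perm = 30
        base = t.labels.to_numpy()
        for i in range(n_perm):
            labels = pd.Series(rng.permutation(base), index=t.sample_ids)
            p = kruskal_wallis_per_signal(t, labels)
            hits += int((bonferroni(p.to_numpy(), t.n_signals) < 0.05).any())
        assert hits / n_perm <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_perm)


def test_screen_recovers_planted_set_at_spec_effect_floor():
    """Explicit planted effects |d| >= 1.5: symmetric difference <= 15%."""
    rng = np.random.default_rng(31)
    n_diff = 134
    d = rng.uniform(1.5, 2.5, size=n_diff) * rng.choice([-1, 1], size=n_diff)
    cfg = mv.CohortConfig(seed=31, effect_sizes=d, factor_separation=2.5)
    spectra, sheet, truth = mv.generate_cohort(cfg)
    from maldivote.pipeline import build_feature_table
    from maldivote.preprocessing import BinningConfig

    table = build_feature_table(spectra, sheet, BinningConfig())
    res = mv.DifferentialScreen(table).fit(seed=31)
    planted = {
        table.mz.index[(table.mz - truth.signal_mz[s]).abs().argmin()]
        for s in truth.differential_signal_ids
    }
    sym = len(set(res.selected_ids) ^ planted)
    assert sym <= 0.15 * n_diff


def test_criteria_validation():
    with pytest.raises(ConfigurationError):
        SelectionCriteria(alpha=0.0)
    with pytest.raises(ConfigurationError):
        SelectionCriteria(min_criteria_met=4)
    with pytest.raises(ConfigurationError):
        SelectionCriteria(n_permutations=50)
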