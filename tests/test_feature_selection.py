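import math

import numpy as np
import pytest

from confsel.core_data import ConformationDataset
from confsel.feature_selection import (RqaConfig, anova_f_scores,
                                       binned_mutual_information,
                                       consensus_select, diagonal_entropy,
                                       mutual_information_scores,
                                       project_features, recurrence_diagonals,
                                       recurrence_matrix, rqa_entropy_scores,
                                       spearman_scores)
from conftest import make_dataset
from helpers_oracles import (brute_anova_f, brute_diagonal_census,
                             brute_entropy, brute_mi_from_bins,
                             brute_quantile_bins, brute_recurrence_matrix,
                             brute_spearman)


def two_col(x, y):
    x = np.asarray(x, dtype=float)
    return ConformationDataset("t", np.column_stack([x, x]), ["a", "b"], y)


class TestAnova:
    def test_worked_example(self):
        # groups {1,2,3} vs {2,3,4}: MSB = 1.5, MSW = 1 -> F = 1.5
        ds = two_col([1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1])
        assert anova_f_scores(ds).scores["a"] == pytest.approx(1.5, abs=1e-12)

    def test_degenerate_columns(self):
        X = np.column_stack([
            [5.0] * 6,                 # constant in both classes -> 0
            [1, 1, 1, 2, 2, 2],        # perfectly separated -> +inf
        ])
        ds = ConformationDataset("t", X, ["same", "sep"], [0, 0, 0, 1, 1, 1])
        scores = anova_f_scores(ds).scores
        assert scores["same"] == 0.0
        assert scores["sep"] == math.inf
        assert anova_f_scores(ds).selected[0] == "sep"

    def test_matches_bruteforce_on_random_instances(self):
        for seed in range(10):
            ds = make_dataset(n=24, d=4, seed=seed)
            scores = anova_f_scores(ds).scores
            for j, name in enumerate(ds.feature_names):
                expect = brute_anova_f(ds.features[:, j], ds.labels)
                assert scores[name] == pytest.approx(expect, abs=1e-9)


class TestMutualInformation:
    def test_identity_feature_gives_ln2(self):
        ds = two_col([0, 1] * 50, np.array([0, 1] * 50))
        assert mutual_information_scores(ds).scores["a"] == pytest.approx(
            math.log(2), abs=1e-12)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(20):
            x = rng.normal(size=2000)
            y = rng.permutation(np.repeat([0, 1], 1000))
            vals.append(binned_mutual_information(x, y, bins=10))
        assert np.mean(vals) < 0.01

    def test_double_sum_on_exact_joint(self):
        # joint p(u,v) = [[0.4, 0.1], [0.1, 0.4]] as 1000 exact samples
        u = np.repeat([0, 0, 1, 1], [400, 100, 100, 400])
        v = np.repeat([0, 1, 0, 1], [400, 100, 100, 400])
        expect = sum(
            p * math.log(p / (pu * pv))
            for p, pu, pv in [(0.4, 0.5, 0.5), (0.1, 0.5, 0.5),
                              (0.1, 0.5, 0.5), (0.4, 0.5, 0.5)]
        )
        got = binned_mutual_information(u.astype(float), v, bins=10)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_constant_feature_scores_zero(self):
        ds = two_col([3.0] * 20, np.array([0, 1] * 10))
        assert mutual_information_scores(ds).scores["a"] == 0.0

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=25)
            y = rng.integers(0, 2, 25)
            u = brute_quantile_bins(x, 10)
            expect = brute_mi_from_bins(u, list(y))
            assert binned_mutual_information(x, y, 10) == pytest.approx(
                expect, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=400)
        y = rng.integers(0, 2, 400)
        a = binned_mutual_information(x, y)
        b = binned_mutual_information(np.exp(x), y)
        assert a == pytest.approx(b, abs=1e-12)


class TestRecurrence:
    def test_monotone_series_has_no_recurrences(self):
        cfg = RqaConfig(radius=0.01)
        assert recurrence_diagonals(np.arange(20, dtype=float), cfg) == {}

    def test_periodic_series_matches_enumeration(self):
        series = np.array([1, 2, 1, 2, 1, 2], dtype=float)
        cfg = RqaConfig(radius=0.5)
        got = recurrence_diagonals(series, cfg)
        r = brute_recurrence_matrix(series, radius=0.5)
        assert got == brute_diagonal_census(r)
        assert got  # generous radius must produce diagonal lines

    @pytest.mark.parametrize("seed", range(8))
    def test_random_series_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.normal(size=10 + seed * 3)
        for radius in (0.2, 0.8):
            cfg = RqaConfig(radius=radius)
            got = recurrence_diagonals(series, cfg)
            r = brute_recurrence_matrix(series, radius=radius)
            assert got == brute_diagonal_census(r)

    def test_constant_series_treated_as_all_recurrent(self):
        counts = recurrence_diagonals(np.full(6, 4.2), RqaConfig())
        # every off-main diagonal is one full line: two each of lengths 2..5
        assert counts == {2: 2, 3: 2, 4: 2, 5: 2}

    def test_recurrence_matrix_symmetric(self):
        rng = np.random.default_rng(3)
        r = recurrence_matrix(rng.normal(size=30))
        assert np.array_equal(r, r.T)


class TestRqaEntropy:
    def test_degenerate_distributions(self):
        assert diagonal_entropy({}) == 0.0
        assert diagonal_entropy({3: 7}) == 0.0
        assert diagonal_entropy({2: 4, 5: 4}) == pytest.approx(math.log(2))

    def test_scores_match_bruteforce_census(self):
        ds = make_dataset(n=30, d=3, seed=7)
        cfg = RqaConfig()
        scores = rqa_entropy_scores(ds, cfg).scores
        for j, name in enumerate(ds.feature_names):
            r = brute_recurrence_matrix(ds.features[:, j], radius=cfg.radius)
            expect = brute_entropy(brute_diagonal_census(r))
            assert scores[name] == pytest.approx(expect, abs=1e-9)

    def test_sensitive_to_row_order(self):
        # frame order is the signal: a smooth series loses its structure
        # when shuffled
        t = np.linspace(0, 8 * np.pi, 300)
        smooth = np.sin(t) + 0.05 * np.random.default_rng(1).normal(size=300)
        rng = np.random.default_rng(2)
        shuffled = rng.permutation(smooth)
        e1 = diagonal_entropy(recurrence_diagonals(smooth, RqaConfig()))
        e2 = diagonal_entropy(recurrence_diagonals(shuffled, RqaConfig()))
        assert e1 != pytest.approx(e2, abs=1e-6)


class TestSpearman:
    def test_identity_and_antitone(self):
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        assert spearman_scores(two_col(y, y)).scores["a"] == pytest.approx(1.0)
        assert spearman_scores(two_col(1 - y, y)).scores["a"] == pytest.approx(1.0)

    def test_monotone_nonlinear_feature(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([1.0, 2.0, 3.0, 10.0, 100.0, 1000.0])
        assert spearman_scores(two_col(x, y)).scores["a"] == pytest.approx(
            brute_spearman(x, y))

    def test_constant_feature_warns_and_scores_zero(self):
        ds = two_col([2.0] * 10, np.array([0, 1] * 5))
        with pytest.warns(UserWarning, match="constant"):
            scores = spearman_scores(ds).scores
        assert scores["a"] == 0.0

    def test_matches_bruteforce_on_random_instances(self):
        for seed in range(10):
            ds = make_dataset(n=27, d=4, seed=100 + seed)
            scores = spearman_scores(ds).scores
            for j, name in enumerate(ds.feature_names):
                expect = abs(brute_spearman(ds.features[:, j], ds.labels))
                assert scores[name] == pytest.approx(expect, abs=1e-9)


class TestInvariants:
    def test_label_scorers_invariant_to_row_permutation(self):
        ds = make_dataset(n=120, d=5, seed=8, effect=1.0, informative=(0,))
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n)
        shuffled = ConformationDataset(
            "p", ds.features[perm], ds.feature_names, ds.labels[perm])
        for scorer in (anova_f_scores, mutual_information_scores,
                       spearman_scores):
            a = scorer(ds).scores
            b = scorer(shuffled).scores
            for name in ds.feature_names:
                assert a[name] == pytest.approx(b[name], abs=1e-9)

    def test_score_ranges(self):
        ds = make_dataset(n=100, d=4, seed=9, effect=1.5, informative=(1,))
        assert all(v >= 0 for v in anova_f_scores(ds).scores.values())
        assert all(v >= 0 for v in mutual_information_scores(ds).scores.values())
        assert all(0 <= v <= 1 for v in spearman_scores(ds).scores.values())
        assert all(v >= 0 for v in rqa_entropy_scores(ds).scores.values())

    def test_scale_equivariance(self):
        ds = make_dataset(n=80, d=3, seed=10, effect=1.0, informative=(0,))
        scaled = ConformationDataset(
            "s", ds.features * 1000.0, ds.feature_names, ds.labels)
        for scorer in (anova_f_scores, spearman_scores, rqa_entropy_scores):
            a, b = scorer(ds).scores, scorer(scaled).scores
            for name in ds.feature_names:
                assert a[name] == pytest.approx(b[name], rel=1e-9)

    def test_tie_break_by_column_order(self):
        X = np.column_stack([[5.0] * 8, [5.0] * 8, [5.0] * 8])
        ds = ConformationDataset("t", X, ["z", "m", "a"], [0, 1] * 4)
        ranking = anova_f_scores(ds, top_x=2)
        assert ranking.selected == ("z", "m")


class TestConsensus:
    def _rankings(self, selected_lists):
        from confsel.feature_selection import FeatureRanking
        names = ["a", "b", "c", "d"]
        return [
            FeatureRanking(method=m, scores={n: 0.0 for n in names},
                           top_x=2, selected=tuple(sel))
            for m, sel in zip(["anova", "mi", "rqa", "spearman"],
                              selected_lists)
        ]

    def test_vote_counts_and_thresholds(self):
        rankings = self._rankings(
            [("a", "b"), ("a", "b"), ("a", "c"), ("a", "b")])
        c4 = consensus_select(rankings, threshold=4)
        assert c4.votes == {"a": 4, "b": 3, "c": 1, "d": 0}
        assert c4.selected == ("a",)
        c3 = consensus_select(rankings, threshold=3)
        assert c3.selected == ("a", "b")

    def test_empty_consensus_returned_not_hidden(self):
        rankings = self._rankings([("a",), ("b",), ("c",), ("d",)])
        assert consensus_select(rankings, 4).selected == ()

    def test_mismatched_feature_sets_rejected(self):
        from confsel.feature_selection import FeatureRanking
        a = FeatureRanking("anova", {"x": 1.0}, 1, ("x",))
        b = FeatureRanking("mi", {"y": 1.0}, 1, ("y",))
        with pytest.raises(ValueError, match="different feature set"):
            consensus_select([a, b, a, a])


class TestProject:
    def test_identity_and_single_column(self, tiny_ds):
        same = project_features(tiny_ds, tiny_ds.feature_names)
        np.testing.assert_array_equal(same.features, tiny_ds.features)
        one = project_features(tiny_ds, ["f1"])
        assert one.d == 1
        np.testing.assert_array_equal(one.features[:, 0],
                                      tiny_ds.features[:, 1])

    def test_unknown_name_listed(self, tiny_ds):
        with pytest.raises(KeyError, match="nope"):
            project_features(tiny_ds, ["f0", "nope"])
        with pytest.raises(ValueError, match="empty"):
            project_features(tiny_ds, [])
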