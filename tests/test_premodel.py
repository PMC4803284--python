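"""Pre-modeling statistics: factor tests, profiles, scaling, clustering, gains."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import harmex as hx
from harmex import premodel as pm
from harmex.chords import RatingDataset, Trial


def kruskal_oracle(groups):
    """Textbook tie-corrected Kruskal-Wallis H."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = rankdata(all_vals)
    start = 0
    H = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return H / tie


def friedman_oracle(grid):
    """Textbook tie-corrected Friedman chi-square for blocks x treatments."""
    n, k = grid.shape
    ranks = np.apply_along_axis(rankdata, 1, grid)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * (R**2).sum() - 3 * n * (k + 1)
    ties = 0.0
    for row in grid:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    return chi2 / correction


def table_from_grid(values):
    """Build a (key1, key2) -> mean table over the complete 12 x 12 design."""
    idx = pd.MultiIndex.from_tuples([(a, b) for a in range(12) for b in range(12)])
    return pd.Series(np.asarray(values, dtype=float).ravel(), index=idx, name="mean_dor")


class TestAverageDors:
    def test_mean_over_participants(self):
        ds = RatingDataset([Trial("p1", (0, 7), 8), Trial("p2", (0, 7), 6)])
        table = pm.average_dors(ds, 2)
        assert table[(0, 7)] == pytest.approx(7.0)

    def test_single_participant_identity(self):
        ds = RatingDataset([Trial("p1", (0, 7), 8), Trial("p1", (2, 5), 3)])
        table = pm.average_dors(ds, 2)
        assert table[(0, 7)] == 8 and table[(2, 5)] == 3

    def test_complete_design_sizes(self, experiment_dataset):
        assert len(pm.average_dors(experiment_dataset, 2)) == 144
        assert len(pm.average_dors(experiment_dataset, 3)) == 144
        assert len(pm.average_dors(experiment_dataset, 4)) == 64

    def test_three_chord_keys_are_interval_pairs(self, experiment_dataset):
        keys = set(pm.average_dors(experiment_dataset, 3).index)
        assert keys == {(a, b) for a in range(12) for b in range(12)}


class TestKruskalWallis:
    def test_matches_textbook_oracle_on_random_tables(self, rng):
        for _ in range(20):
            table = table_from_grid(rng.uniform(1, 9, size=144))
            for factor in ("interval", "first_pitch", "second_pitch"):
                res = pm.kruskal_wallis_by_factor(table, factor)
                groups = [[] for _ in range(12)]
                for (a, b), v in table.items():
                    key = {(0): a, 1: b, 2: (b - a) % 12}[
                        {"first_pitch": 0, "second_pitch": 1, "interval": 2}[factor]
                    ]
                    groups[key].append(v)
                assert res.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-9)
                assert res.df == 11

    def test_equal_group_mean_ranks_give_zero(self):
        # every interval group holds one copy of each value 1..12
        grid = np.empty((12, 12))
        for a in range(12):
            for b in range(12):
                grid[a, b] = a + 1
        res = pm.kruskal_wallis_by_factor(table_from_grid(grid), "interval")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_incomplete_design_rejected(self):
        idx = pd.MultiIndex.from_tuples([(0, 1), (0, 2)])
        with pytest.raises(ValueError, match="missing"):
            pm.kruskal_wallis_by_factor(pd.Series([5.0, 6.0], index=idx), "interval")


class TestFriedman:
    def test_matches_textbook_oracle_on_random_grids(self, rng):
        for _ in range(20):
            grid = rng.uniform(1, 9, size=(12, 12))
            res = pm.friedman_by_interval(table_from_grid(grid), "interval_from_second")
            assert res.statistic == pytest.approx(friedman_oracle(grid), abs=1e-9)
            assert res.df == 11

    def test_first_interval_arrangement_reindexes_by_total_interval(self, rng):
        grid = rng.uniform(1, 9, size=(12, 12))
        res = pm.friedman_by_interval(table_from_grid(grid), "interval_from_first")
        regrid = np.empty((12, 12))
        for i1 in range(12):
            for i2 in range(12):
                regrid[i2, (i1 + i2) % 12] = grid[i1, i2]
        assert res.statistic == pytest.approx(friedman_oracle(regrid), abs=1e-9)

    def test_all_ties_degenerate(self):
        with pytest.raises(ValueError, match="tie"):
            pm.friedman_by_interval(table_from_grid(np.ones((12, 12))), "interval_from_second")


class TestProfileVectors:
    def test_constant_ratings_give_constant_vectors(self):
        trials = []
        for cond in (2, 3, 4):
            for seq in hx.generate_stimulus_set(cond, seed=0):
                trials.append(Trial("p", seq, 5.0))
        vectors = pm.interval_profile_vectors(RatingDataset(trials))
        assert [v.label for v in vectors] == list(pm.PROFILE_LABELS)
        for v in vectors:
            assert v.values == (5.0, 5.0, 5.0, 5.0)

    def test_rating_planted_from_interval_recovered(self):
        """Ratings set to 1 + interval/2 reproduce the direct group averages."""
        trials = []
        for cond in (2, 3, 4):
            for seq in hx.generate_stimulus_set(cond, seed=1):
                iv = hx.interval(seq[-2], seq[-1])
                trials.append(Trial("p", seq, 1.0 + iv / 2.0))
        ds = RatingDataset(trials)
        vectors = {v.label: v for v in pm.interval_profile_vectors(ds)}
        # for the adjacent positions the interval to the final chord IS the rating key
        for label in ("C1-C2", "C2-C3", "C3-C4"):
            assert vectors[label].values == tuple(1.0 + iv / 2.0 for iv in (2, 5, 7, 10))


class TestNonmetricMds:
    def test_equilateral_triangle_embeds_exactly(self):
        D = np.ones((3, 3)) - np.eye(3)
        _, stress = pm.nonmetric_mds(D, dims=2, n_init=8)
        assert stress < 1e-6

    def test_planar_configuration_recovered(self, rng):
        P = rng.normal(size=(6, 2))
        D = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
        _, stress = pm.nonmetric_mds(D, dims=2, eps=1e-15)
        assert stress < 1e-6

    def test_stress_non_increasing_in_dims(self, rng):
        P = rng.normal(size=(6, 3))
        D = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
        _, s1 = pm.nonmetric_mds(D, dims=1)
        _, s2 = pm.nonmetric_mds(D, dims=2)
        assert s2 <= s1 + 1e-9

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            pm.nonmetric_mds(D)


class TestCompleteLinkClustering:
    def test_two_separated_pairs_merge_within_first(self):
        # points on a line: {0, 1} and {10, 11}
        x = np.array([0.0, 1.0, 10.0, 11.0])
        D = np.abs(x[:, None] - x[None, :])
        dend = pm.complete_link_clustering(D, labels=("a", "b", "c", "d"))
        heights = dend.heights
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(1.0)
        assert heights[2] == pytest.approx(11.0)  # complete link: max distance

    def test_single_pair(self):
        D = np.array([[0.0, 2.5], [2.5, 0.0]])
        dend = pm.complete_link_clustering(D, labels=("a", "b"))
        assert dend.heights.tolist() == [2.5]

    def test_merge_heights_monotone(self, rng):
        P = rng.normal(size=(6, 4))
        D = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
        dend = pm.complete_link_clustering(D)
        assert np.all(np.diff(dend.heights) >= -1e-12)


class TestContextGain:
    @staticmethod
    def _matched_dataset():
        """3-chord ratings copied from the matched 2-chord interval means."""
        rng = np.random.default_rng(0)
        trials = []
        by_interval = {iv: 2.0 + iv * 0.5 for iv in range(12)}
        for a in range(12):
            for b in range(12):
                trials.append(Trial("p", (a, b), min(by_interval[(b - a) % 12], 9.0)))
        for seq in hx.generate_stimulus_set(3, seed=2):
            iv = hx.interval(seq[1], seq[2])
            trials.append(Trial("p", seq, min(by_interval[iv], 9.0)))
        return RatingDataset(trials)

    def test_matched_construction_gives_zero_gain(self):
        gain, test, posthoc = pm.context_gain_analysis(self._matched_dataset())
        assert np.allclose(gain.to_numpy(), 0.0)
        assert test.statistic == 0.0 and test.p == 1.0
        assert not posthoc["significant"].any()

    def test_bonferroni_threshold_over_66_pairs(self):
        _, _, posthoc = pm.context_gain_analysis(self._matched_dataset())
        assert posthoc.attrs["n_pairs"] == 66
        assert posthoc.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 66)
        assert posthoc.attrs["bonferroni_threshold"] < 0.00076

    def test_planted_gain_flagged_by_posthoc(self):
        """A strong planted advantage of total-intervals {0, 7} over {1, 8}
        appears in the pairwise mean-rank comparisons."""
        rng = np.random.default_rng(3)
        trials = []
        for a in range(12):
            for b in range(12):
                trials.append(Trial("p", (a, b), 5.0))
        for seq in hx.generate_stimulus_set(3, seed=4):
            total = hx.interval(seq[0], seq[2])
            base = 5.0 + (3.0 if total in (0, 7) else -3.0 if total in (1, 8) else 0.0)
            trials.append(Trial("p", seq, base + rng.normal(0, 0.05)))
        gain, test, posthoc = pm.context_gain_analysis(RatingDataset(trials))
        assert test.p < 0.001
        flagged = posthoc[posthoc["significant"]]
        pairs = set(map(tuple, flagged[["treatment_a", "treatment_b"]].to_numpy()))
        for good in (0, 7):
            for bad in (1, 8):
                assert tuple(sorted((good, bad))) in pairs
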