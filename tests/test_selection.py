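"""ICC robustness filter, collinearity pruning, and the five rankers."""

import warnings

import numpy as np
import pytest

import dlradiomics as dlr
from dlradiomics.features import FeatureMatrix
from dlradiomics.selection import (
    RANKERS,
    MultiSegFeatureSet,
    SelectionConfig,
    filter_robust,
    icc_case3a,
    inffs_adjacency,
    prune_collinear,
    rank_features,
)


def icc_oracle(m: np.ndarray) -> float:
    """Brute-force two-way ANOVA mean squares, computed cell by cell."""
    n, k = m.shape
    grand = m.mean()
    msr = sum((m[i].mean() - grand) ** 2 for i in range(n)) * k / (n - 1)
    msc = sum((m[:, j].mean() - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestIcc:
    def test_perfect_agreement(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 3))
        assert icc_case3a(m) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,k", [(4, 3), (6, 5), (8, 7), (10, 9)])
    def test_matches_anova_oracle(self, n, k, rng):
        m = rng.normal(size=(n, 1)) * 2 + rng.normal(size=(n, k)) * 0.5
        assert icc_case3a(m) == pytest.approx(icc_oracle(m), abs=1e-10)

    def test_matches_pingouin_absolute_agreement_single(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.normal(size=(8, 1)) * 3 + rng.normal(size=(8, 4))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 4),
            "rater": np.tile(np.arange(4), 8),
            "score": m.ravel(),
        })
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc_a1 = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_case3a(m) == pytest.approx(icc_a1, abs=1e-8)

    def test_constant_rater_offset_below_one(self, rng):
        base = rng.normal(size=(4, 1)) * 2
        m = base + np.array([[0.0, 0.5, 1.0]])  # systematic rater shifts
        icc = icc_case3a(m)
        assert icc < 1.0
        assert icc == pytest.approx(icc_oracle(m), abs=1e-10)

    def test_all_equal_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(icc_case3a(np.full((4, 3), 2.0)))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            icc_case3a(np.zeros((1, 3)))


class TestFilterRobust:
    def test_reproduced_kept_noise_dropped(self, rng):
        subjects = rng.normal(size=(10, 1))
        ms = MultiSegFeatureSet()
        ms.add("stable", np.tile(subjects, (1, 9)) + rng.normal(size=(10, 9)) * 0.01)
        ms.add("fresh_noise", rng.normal(size=(10, 9)))
        kept = filter_robust(ms)
        assert "stable" in kept
        assert "fresh_noise" not in kept

    def test_threshold_is_strict(self, rng):
        m = rng.normal(size=(6, 1)) + rng.normal(size=(6, 4)) * 0.5
        icc = icc_case3a(m)
        ms = MultiSegFeatureSet()
        ms.add("f", m)
        cfg = SelectionConfig(icc_threshold=icc)  # exactly at the feature's ICC
        assert filter_robust(ms, cfg) == []


class TestPruneCollinear:
    def test_hand_example_drops_higher_index_on_tie(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        c = [5.0, 1.0, 4.0, 2.0, 3.0]
        fm = FeatureMatrix(np.column_stack([a, a, c]), ["A", "B", "C"],
                           [f"s{i}" for i in range(5)])
        assert prune_collinear(fm) == ["A", "C"]

    def test_postcondition_no_offending_pair(self, rng):
        base = rng.normal(size=(60, 4))
        # correlated block: noisy copies of the same parents
        extra = base[:, [0, 0, 1, 2]] + rng.normal(size=(60, 4)) * 0.1
        vals = np.column_stack([base, extra])
        fm = FeatureMatrix(vals, [f"f{j}" for j in range(8)],
                           [f"s{i}" for i in range(60)])
        kept = prune_collinear(fm)
        from scipy.stats import spearmanr

        sub = fm.subset(kept).values
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert abs(spearmanr(sub[:, i], sub[:, j]).statistic) <= 0.8

    def test_independent_noise_all_retained(self, rng):
        fm = FeatureMatrix(rng.normal(size=(100, 10)),
                           [f"f{j}" for j in range(10)],
                           [f"s{i}" for i in range(100)])
        assert prune_collinear(fm) == fm.feature_names

    def test_single_feature_unchanged(self):
        fm = FeatureMatrix(np.arange(5.0)[:, None], ["only"], [f"s{i}" for i in range(5)])
        assert prune_collinear(fm) == ["only"]

    def test_sample_order_insensitive(self, rng):
        vals = rng.normal(size=(40, 6))
        vals[:, 1] = vals[:, 0] + rng.normal(size=40) * 0.05
        names = [f"f{j}" for j in range(6)]
        fm1 = FeatureMatrix(vals, names, [f"s{i}" for i in range(40)])
        perm = rng.permutation(40)
        fm2 = FeatureMatrix(vals[perm], names, [f"s{i}" for i in range(40)])
        assert prune_collinear(fm1) == prune_collinear(fm2)


class TestRankers:
    def _cohort(self, rng, n=30, p=8):
        x = rng.normal(size=(n, p))
        y = (rng.random(n) < 0.5).astype(int)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        return x, y

    def test_wlcx_ranks_separated_feature_first(self, rng):
        y = np.repeat([0, 1], 8)
        x = rng.normal(size=(16, 6))
        x[:, 3] = np.arange(16.0)  # perfectly separated: rank-sum p minimal
        fm = FeatureMatrix(x, [f"f{j}" for j in range(6)], [f"s{i}" for i in range(16)])
        res = rank_features(fm, y, SelectionConfig(ranker="WLCX"))
        assert res.feature_names[0] == "f3"

    def test_identical_features_fall_back_to_index_order(self):
        x = np.tile(np.arange(8.0)[:, None], (1, 4))
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        fm = FeatureMatrix(x + np.zeros((8, 4)), ["f0", "f1", "f2", "f3"],
                           [f"s{i}" for i in range(8)])
        # identical columns forbidden by unique-name rule only on names; values can tie
        for ranker in RANKERS:
            res = rank_features(fm, y, SelectionConfig(ranker=ranker))
            assert res.feature_names == ["f0", "f1", "f2", "f3"]

    @pytest.mark.parametrize("ranker", RANKERS)
    def test_planted_feature_in_top10(self, ranker, cohort_informative):
        fmz, y, _ = cohort_informative
        res = rank_features(fmz, y, SelectionConfig(ranker=ranker))
        assert "feat_000" in res.top(10)

    @pytest.mark.parametrize("ranker", RANKERS)
    def test_deterministic(self, ranker, cohort_informative):
        fmz, y, _ = cohort_informative
        small = fmz.subset(fmz.feature_names[:12])
        r1 = rank_features(small, y, SelectionConfig(ranker=ranker))
        r2 = rank_features(small, y, SelectionConfig(ranker=ranker))
        assert r1.feature_names == r2.feature_names
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_wlcx_invariant_to_monotone_transform(self, cohort_informative):
        fmz, y, _ = cohort_informative
        small = fmz.subset(fmz.feature_names[:10])
        warped = FeatureMatrix(np.exp(small.values / 2), small.feature_names,
                               small.sample_ids)
        r1 = rank_features(small, y, SelectionConfig(ranker="WLCX"))
        r2 = rank_features(warped, y, SelectionConfig(ranker="WLCX"))
        assert r1.feature_names == r2.feature_names

    def test_one_class_labels_rejected(self, rng):
        x, _ = self._cohort(rng)
        fm = FeatureMatrix(x, [f"f{j}" for j in range(x.shape[1])],
                           [f"s{i}" for i in range(x.shape[0])])
        with pytest.raises(ValueError):
            rank_features(fm, np.zeros(x.shape[0]), SelectionConfig(ranker="WLCX"))


def test_inffs_matches_truncated_series_oracle(rng):
    x = rng.normal(size=(40, 12))
    y = (rng.random(40) < 0.5).astype(int)
    a = inffs_adjacency(x, y, alpha=0.5)
    spectral = np.max(np.abs(np.linalg.eigvals(a)))
    r = 0.9 / spectral
    s_closed = np.linalg.inv(np.eye(12) - r * a) - np.eye(12)
    s_series = np.zeros((12, 12))
    term = np.eye(12)
    for _ in range(200):
        term = term @ (r * a)
        s_series += term
    np.testing.assert_allclose(s_closed, s_series, atol=1e-8)
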