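"""0.632+ bootstrap machinery, forward selection, grid, t-test, sweeps."""

import itertools
import warnings

import numpy as np
import pytest

import dlradiomics as dlr
from dlradiomics.evaluation import (
    BootstrapConfig,
    auc,
    auc632plus,
    bootstrap_replicates,
    corrected_resampled_ttest,
    evaluate_grid,
    forward_select,
    overfitting_rate,
    undersample_sweep,
    volume_correlation_check,
    weight_632plus,
)
from dlradiomics.features import FeatureMatrix
from dlradiomics.models import ClassifierSpec

FAST_LDA = ClassifierSpec("LDA", params={"solver": "svd"})


class TestAuc:
    def test_fully_concordant(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_enumerated_example(self):
        assert auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 31))
            scores = rng.normal(size=n).round(1)  # coarse -> ties occur
            y = (rng.random(n) < 0.5).astype(int)
            y[:2] = [0, 1]
            pairs = [
                1.0 if si > sj else (0.5 if si == sj else 0.0)
                for (si, yi), (sj, yj) in itertools.product(zip(scores, y), repeat=2)
                if yi == 1 and yj == 0
            ]
            assert auc(scores, y) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestBootstrap:
    def test_inbag_size_and_oob_complement(self):
        reps = bootstrap_replicates(30, BootstrapConfig(50, seed=4))
        for rep in reps:
            assert rep.in_bag.size == 30
            assert set(rep.oob) == set(range(30)) - set(rep.in_bag)

    def test_single_sample(self):
        reps = bootstrap_replicates(1, BootstrapConfig(3, seed=0))
        for rep in reps:
            assert list(rep.in_bag) == [0]
            assert rep.oob.size == 0

    def test_reproducible_from_seed(self):
        r1 = bootstrap_replicates(20, BootstrapConfig(10, seed=7))
        r2 = bootstrap_replicates(20, BootstrapConfig(10, seed=7))
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.in_bag, b.in_bag)


class TestFormulas:
    def test_weight_at_zero_overfitting(self):
        assert weight_632plus(0.0) == pytest.approx(0.632, abs=1e-15)

    def test_weight_range(self):
        for r in np.linspace(0, 1, 21):
            assert 0.632 <= weight_632plus(r) <= 1.0 + 1e-12

    def test_collapsed_replicate_value(self):
        # apparent 1.0, OOB 0.4: clamped AUC' = 0.5, R = 1, a = 1 -> value 0.5
        r = overfitting_rate(1.0, 0.4)
        a = weight_632plus(r)
        assert r == 1.0 and a == pytest.approx(1.0)
        assert (1 - a) * 1.0 + a * 0.5 == pytest.approx(0.5)

    def test_hand_evaluated_replicate(self):
        # apparent 0.9, OOB 0.7 -> R = 0.5, a = 0.632/0.816, value ~ 0.745
        r = overfitting_rate(0.9, 0.7)
        a = weight_632plus(r)
        value = (1 - a) * 0.9 + a * 0.7
        assert value == pytest.approx(0.7450980392156862, abs=1e-12)

    def test_no_overfitting_when_oob_exceeds_apparent(self):
        assert overfitting_rate(0.7, 0.8) == 0.0


class TestAuc632Plus:
    def test_perfectly_separable_estimate_is_one(self):
        x = np.concatenate([np.linspace(-3, -1, 20), np.linspace(1, 3, 20)])[:, None]
        y = np.repeat([0, 1], 20)
        res = auc632plus(x, y, FAST_LDA, cfg=BootstrapConfig(30, seed=1))
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(1.0)

    def test_all_positive_classifier_sens_spec(self):
        # scores above threshold everywhere: sensitivity 1, specificity 0
        from dlradiomics.evaluation import _sens_spec

        sens, spec = _sens_spec(np.full(10, 0.9), np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0]), 0.5)
        assert sens == 1.0 and spec == 0.0

    def test_estimate_in_unit_interval_and_weights_valid(self, rng):
        x = rng.normal(size=(40, 3))
        y = np.tile([0, 1], 20)
        res = auc632plus(x, y, FAST_LDA, cfg=BootstrapConfig(40, seed=2),
                         keep_replicates=True)
        assert 0.0 <= res.auc <= 1.0
        for rep in res.replicates:
            if rep.skipped:
                continue
            assert 0.632 <= rep.weight <= 1.0 + 1e-12
            assert rep.auc_clamped >= 0.5
            assert 0.0 <= rep.overfit_rate <= 1.0

    def test_degenerate_replicates_skipped_and_counted(self):
        # n=8 with 2 positives: many in-bags or OOB sets miss the positive class
        x = np.arange(8.0)[:, None]
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        res = auc632plus(x, y, FAST_LDA, cfg=BootstrapConfig(100, seed=3))
        assert res.n_skipped > 0
        assert res.n_bootstrap + res.n_skipped == 100

    def test_seed_stability(self, rng):
        x = rng.normal(size=(60, 2))
        y = (x[:, 0] + rng.normal(size=60) * 2 > 0).astype(int)
        a = auc632plus(x, y, FAST_LDA, cfg=BootstrapConfig(150, seed=10)).auc
        b = auc632plus(x, y, FAST_LDA, cfg=BootstrapConfig(150, seed=99)).auc
        assert a == pytest.approx(b, abs=0.03)


class TestForwardSelect:
    def test_informative_feature_selected(self, rng):
        y = np.repeat([0, 1], 50)
        x = rng.normal(size=(100, 10))
        x[:, 4] += 2.0 * y
        res = forward_select(x, y, FAST_LDA, [f"f{j}" for j in range(10)],
                             cfg=BootstrapConfig(40, seed=5))
        assert "f4" in res.features

    def test_duplicate_candidates_give_singleton(self, rng):
        y = np.repeat([0, 1], 30)
        col = rng.normal(size=60) + y
        x = np.tile(col[:, None], (1, 4))
        res = forward_select(x, y, FAST_LDA, ["f0", "f1", "f2", "f3"],
                             cfg=BootstrapConfig(40, seed=6))
        assert len(res.features) == 1

    def test_deterministic_given_master_seed(self, rng):
        y = np.repeat([0, 1], 30)
        x = rng.normal(size=(60, 6))
        x[:, 0] += y
        r1 = forward_select(x, y, FAST_LDA, [f"f{j}" for j in range(6)],
                            cfg=BootstrapConfig(30, seed=8))
        r2 = forward_select(x, y, FAST_LDA, [f"f{j}" for j in range(6)],
                            cfg=BootstrapConfig(30, seed=8))
        assert r1.features == r2.features
        assert r1.auc == r2.auc

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            forward_select(rng.normal(size=(10, 2)), np.tile([0, 1], 5),
                           FAST_LDA, [], cfg=BootstrapConfig(5, seed=0))


class TestGrid:
    def test_small_grid_shape_and_mean(self, rng):
        y = np.repeat([0, 1], 30)
        vals = rng.normal(size=(60, 6))
        vals[:, 0] += 1.5 * y
        fm = FeatureMatrix(vals, [f"f{j}" for j in range(6)],
                           [f"s{i}" for i in range(60)])
        tops = {"WLCX": ["f0", "f1"], "CHSQ": ["f0", "f2"]}
        specs = [FAST_LDA, ClassifierSpec("NB")]
        grid = evaluate_grid(fm, y, tops, specs, BootstrapConfig(25, seed=3))
        assert grid.auc_grid.shape == (2, 2)
        assert grid.mean_auc == pytest.approx(np.nanmean(grid.auc_grid))
        assert np.isfinite(grid.auc_grid).all()


class TestCorrectedTTest:
    def test_all_zero_diffs(self):
        res = corrected_resampled_ttest(np.zeros(10), 61, 35)
        assert res.t == 0.0
        assert res.p_one_tailed == pytest.approx(0.5)

    def test_hand_example(self):
        # K=4, diffs {0.1, 0.2, 0.0, 0.1}: mean 0.1, s^2 = 1/150
        from scipy.stats import t as tdist

        res = corrected_resampled_ttest([0.1, 0.2, 0.0, 0.1], 61, 35)
        expected_t = 0.1 / np.sqrt((0.25 + 35 / 61) * (1 / 150))
        assert res.t == pytest.approx(expected_t, abs=1e-12)
        assert res.t == pytest.approx(1.35, abs=0.02)
        assert res.df == 3
        assert res.p_one_tailed == pytest.approx(float(tdist.sf(expected_t, 3)), abs=1e-12)

    def test_scale_invariance(self, rng):
        d = rng.normal(size=20) * 0.05 + 0.02
        t1 = corrected_resampled_ttest(d, 61, 35).t
        t2 = corrected_resampled_ttest(3.7 * d, 61, 35).t
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_constant_nonzero_diffs_degenerate(self):
        res = corrected_resampled_ttest(np.full(5, 0.1), 61, 35)
        assert res.degenerate
        assert res.p_one_tailed == 0.0


class TestSweep:
    def test_balanced_labels_identity(self, rng):
        vals = rng.normal(size=(40, 3))
        rates = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(2, 3, 20)])
        vals[:, 0] += (rates > 1.5) * 1.0
        fm = FeatureMatrix(vals, ["f0", "f1", "f2"], [f"s{i}" for i in range(40)])
        cfg = BootstrapConfig(30, seed=9)
        sweep = undersample_sweep(rates, [1.5], fm, FAST_LDA, cfg=cfg,
                                  n_undersample=5, seed=1)
        direct = auc632plus(None, (rates > 1.5).astype(int), FAST_LDA,
                            features=["f0", "f1", "f2"], cfg=cfg, feature_matrix=fm)
        assert sweep[1.5] == pytest.approx(direct.auc)

    def test_empty_class_threshold_skipped(self, rng):
        vals = rng.normal(size=(20, 2))
        fm = FeatureMatrix(vals, ["f0", "f1"], [f"s{i}" for i in range(20)])
        rates = rng.uniform(0, 1, 20)
        with pytest.warns(UserWarning, match="skipped"):
            sweep = undersample_sweep(rates, [5.0], fm, FAST_LDA,
                                      cfg=BootstrapConfig(10, seed=0),
                                      n_undersample=3, seed=2)
        assert sweep == {}


class TestVolumeCorrelation:
    def test_identity_and_reversal(self, rng):
        vols = rng.uniform(5, 50, 30)
        ranks = vols.argsort().argsort().astype(float)
        fm = FeatureMatrix(np.column_stack([vols, ranks.max() - ranks]),
                           ["same", "reversed"], [f"s{i}" for i in range(30)])
        rho = volume_correlation_check(fm, vols)
        assert rho["same"] == pytest.approx(1.0)
        assert rho["reversed"] == pytest.approx(-1.0)

    def test_independent_noise_weak(self, rng):
        vols = rng.uniform(5, 50, 96)
        fm = FeatureMatrix(rng.normal(size=(96, 3)), ["a", "b", "c"],
                           [f"s{i}" for i in range(96)])
        rho = volume_correlation_check(fm, vols)
        assert max(abs(v) for v in rho.values()) < 0.3

    def test_constant_feature_undefined(self, rng):
        fm = FeatureMatrix(np.ones((10, 1)), ["const"], [f"s{i}" for i in range(10)])
        rho = volume_correlation_check(fm, rng.uniform(1, 2, 10))
        assert np.isnan(rho["const"])
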