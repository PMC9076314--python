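"""Classification, trial-wise CV, confusion metrics, ANOVA comparison,
robustness sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import oracles
from myofeat import (
    SynthConfig,
    classify,
    compare_bonferroni,
    cv_from_features,
    generate_dataset,
    metrics_from_confusion,
    trialwise_cv,
)
from myofeat.evaluate import (
    DEFAULT_SNR_GRID,
    DEFAULT_WINDOW_GRID,
    extract_dataset,
    sweep_snr,
    sweep_window,
)
from myofeat.features import FeatureMatrix


def _fm(X, y, trials=None):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    return FeatureMatrix(
        values=X,
        columns=[f"f{i}" for i in range(X.shape[1])],
        labels=np.asarray(y),
        trial_index=np.asarray(trials if trials is not None else np.ones(n, int)),
        window_index=np.arange(n),
    )


class TestClassify:
    @pytest.mark.parametrize("model", ["lda", "svm", "knn"])
    def test_separated_gaussians_perfectly_classified(self, rng, model):
        train = _fm(np.r_[rng.normal(0, 0.1, (30, 1)), rng.normal(8, 0.1, (30, 1))],
                    ["a"] * 30 + ["b"] * 30)
        test = _fm(np.array([[0.05], [7.9], [-0.1], [8.2]]), ["a", "b", "a", "b"])
        pred = classify(train, test, model=model)
        assert list(pred) == ["a", "b", "a", "b"]

    def test_knn_self_classification_with_triplicate_exemplars(self):
        X = np.repeat(np.array([[0.0], [5.0], [10.0]]), 3, axis=0)
        y = np.repeat(["a", "b", "c"], 3)
        fm = _fm(X, y)
        assert list(classify(fm, fm, model="knn")) == list(y)

    def test_label_permutation_symmetry(self, rng):
        train = _fm(np.r_[rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))],
                    ["a"] * 20 + ["b"] * 20)
        renamed = _fm(train.values,
                      np.where(train.labels == "a", "z", "a"))
        test = _fm(rng.normal(0, 0.5, (10, 2)), ["a"] * 10)
        p1 = classify(train, test, model="knn")
        p2 = classify(renamed, test, model="knn")
        assert all((a == "a") == (b == "z") for a, b in zip(p1, p2))

    def test_column_mismatch_rejected(self, rng):
        train = _fm(rng.normal(size=(10, 2)), ["a"] * 5 + ["b"] * 5)
        test = _fm(rng.normal(size=(4, 3)), ["a"] * 4)
        with pytest.raises(ValueError):
            classify(train, test)


class TestMetrics:
    def test_hand_computed_two_class_case(self):
        per, _ = metrics_from_confusion(np.array([[8, 2], [1, 9]]), ["c1", "c2"])
        m = per["c1"]
        assert m.sensitivity == pytest.approx(80.0)
        assert m.specificity == pytest.approx(90.0)
        assert m.precision == pytest.approx(800.0 / 9)
        assert m.accuracy == pytest.approx(85.0)
        assert m.f1 == pytest.approx(1600.0 / 19)

    def test_diagonal_confusion_all_100(self):
        per, macro = metrics_from_confusion(np.diag([5, 7, 3]))
        assert all(v == 100.0 for v in macro.as_dict().values())

    def test_uniform_confusion_macro_sensitivity_10_percent(self):
        _, macro = metrics_from_confusion(np.full((10, 10), 4))
        assert macro.sensitivity == pytest.approx(10.0)

    def test_zero_denominator_reports_zero_with_warning(self):
        # class 2 never predicted: precision denominator 0
        C = np.array([[5, 0], [3, 0]])
        with pytest.warns(UserWarning, match="zero denominator"):
            per, _ = metrics_from_confusion(C, ["a", "b"])
        assert per["b"].precision == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_oracle_on_random_confusions(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        C = rng.integers(0, 30, size=(k, k))
        C[0, 0] += 1  # nonempty
        per, macro = metrics_from_confusion(C)
        rows = C.tolist()
        for m in range(k):
            expected = oracles.metrics_oracle(rows, m)
            got = per[m].as_dict()
            for key in expected:
                assert got[key] == pytest.approx(expected[key], abs=1e-9)
                assert 0.0 <= got[key] <= 100.0
        # F1 is the harmonic mean of the class's own precision/sensitivity
        for m in range(k):
            p, s = per[m].precision, per[m].sensitivity
            if p + s > 0:
                assert per[m].f1 == pytest.approx(2 * p * s / (p + s), abs=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.array([[1, -1], [0, 2]]))


class TestTrialwiseCv:
    def test_fold_sizes_on_default_conditions(self, proposed_features):
        """6 trials x 10 movements x 20 windows: each fold trains on 1000
        windows and tests on 200."""
        report = cv_from_features(proposed_features, "lda")
        assert len(report.fold_confusions) == 6
        for C in report.fold_confusions:
            assert C.sum() == 200
        assert report.pooled_confusion.sum() == 1200

    def test_fold_disjointness(self, proposed_features):
        """No trial contributes windows to both train and test of a fold."""
        fm = proposed_features
        trials = sorted(set(fm.trial_index.tolist()))
        for t in trials:
            test_mask = fm.trial_index == t
            assert not set(fm.trial_index[test_mask]) & set(fm.trial_index[~test_mask])

    def test_noiseless_distinct_amplitudes_reach_100(self):
        amps = {"A": (0.1, 0.1), "B": (0.4, 0.3), "C": (1.0, 0.8)}
        cfg = SynthConfig(movements=tuple(amps), amplitudes=amps, noise_rms=0.0,
                          n_trials=3, duration_s=2.0, seed=5)
        report = trialwise_cv(generate_dataset(cfg), "PROPOSED", "lda")
        assert report.macro_mean.f1 == pytest.approx(100.0)

    def test_unequal_trial_counts_rejected(self, rng):
        fm = _fm(rng.normal(size=(30, 3)),
                 ["a"] * 20 + ["b"] * 10,
                 trials=[1] * 10 + [2] * 10 + [1] * 10)
        with pytest.raises(ValueError, match="unequal trial"):
            cv_from_features(fm)

    def test_pipeline_deterministic(self, small_dataset):
        r1 = trialwise_cv(small_dataset, "FS2", "lda")
        r2 = trialwise_cv(small_dataset, "FS2", "lda")
        assert r1.to_dict() == r2.to_dict()

    def test_metric_aggregation_bounds(self, proposed_features):
        report = cv_from_features(proposed_features, "knn")
        for ms in (report.macro_mean, *report.per_movement.values()):
            for v in ms.as_dict().values():
                assert 0.0 <= v <= 100.0


class TestCompareBonferroni:
    def test_identical_groups_cap_at_one(self):
        a = [1.0, 2.0, 3.0]
        assert compare_bonferroni(a, a, n_comparisons=10) == 1.0

    def test_two_group_anova_equals_squared_t(self, rng):
        a = rng.normal(0, 1, 18)
        b = rng.normal(0.5, 1, 18)
        f, p_f = stats.f_oneway(a, b)
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-9)
        assert compare_bonferroni(a, b, 1) == pytest.approx(p_f, rel=1e-9)

    def test_power_on_well_separated_groups(self):
        """N(0,1) vs N(5,1), n = 18: corrected p < 0.001 in >= 99/100
        seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p = compare_bonferroni(rng.normal(0, 1, 18), rng.normal(5, 1, 18),
                                   n_comparisons=10)
            hits += p < 0.001
        assert hits >= 99

    def test_degenerate_zero_variance(self):
        assert compare_bonferroni([1.0, 1.0], [2.0, 2.0]) == 0.0
        assert compare_bonferroni([1.0, 1.0], [1.0, 1.0]) == 1.0


class TestSweeps:
    def test_window_sweep_grid_and_variants(self, small_dataset):
        result = sweep_window(small_dataset, "FS2", "lda", grid=(100, 200, 350))
        assert result.axis == [100.0, 200.0, 350.0]
        for p in result.points:
            assert p.base.spec_name == "FS2"
            assert "LMAV" in p.augmented.spec_name or p.augmented.spec_name != "FS2"

    def test_default_grids(self):
        assert list(DEFAULT_WINDOW_GRID) == list(range(50, 351, 50))
        assert list(DEFAULT_SNR_GRID) == list(range(0, 21))

    def test_snr_sweep_deterministic_and_on_grid(self, small_dataset):
        r1 = sweep_snr(small_dataset, "FS2", "lda", seed=1, grid=(0, 10))
        r2 = sweep_snr(small_dataset, "FS2", "lda", seed=1, grid=(0, 10))
        assert r1.axis == [0.0, 10.0]
        assert r1.to_dict() == r2.to_dict()

    def test_fold_sd_shrinks_with_window_size(self, default_dataset):
        """Longer windows average more signal, so fold-to-fold scatter of
        the F1 score trends down across {50, 150, 250, 350} ms."""
        result = sweep_window(default_dataset, "PROPOSED11", "lda",
                              grid=(50, 150, 250, 350))
        sds = [p.base.macro_sd.f1 for p in result.points]
        assert sds[-1] <= sds[0] + 0.5
        assert max(sds[1:]) <= sds[0] + 1.0


def test_extract_dataset_shapes(small_dataset):
    fm = extract_dataset(small_dataset, "FS2", window_ms=200.0)
    # 1.4 s at 2 kHz -> 7 windows of 400 samples per trial, 12 trials
    assert fm.values.shape == (7 * 12, 12)
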