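import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantstress3d.evaluation import (
    HEXAGON_AREA,
    ConfusionCounts,
    auc,
    basic_metrics,
    compare_methods,
    f_score_from_precision_recall,
    kfold_cv,
    kfold_indices,
    mean_bundle,
    moisture_ratio,
    pam,
    plot_pam,
)


class TestBasicMetrics:
    def test_perfect_classifier(self):
        b = basic_metrics(ConfusionCounts(tp=10, tn=5, fp=0, fn=0))
        assert b.recall == b.precision == b.f_score == 1.0
        assert b.accuracy == b.specificity == b.jaccard == 1.0
        assert b.undefined == set()

    def test_f1_from_printed_precision_recall(self):
        # published pair for the 999-superpixel configuration
        assert round(f_score_from_precision_recall(0.9344, 0.9661), 4) == 0.9500

    def test_counts_from_labels(self):
        b = ConfusionCounts.from_labels([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (b.tp, b.tn, b.fp, b.fn) == (2, 1, 1, 1)

    def test_jaccard_f1_identity_over_count_grid(self):
        # JI == F1 / (2 - F1) on every count combination
        for tp in range(1, 5):
            for fp in range(0, 4):
                for fn in range(0, 4):
                    b = basic_metrics(ConfusionCounts(tp, 3, fp, fn))
                    assert b.jaccard == pytest.approx(b.f_score / (2 - b.f_score))

    def test_f1_is_harmonic_mean(self):
        b = basic_metrics(ConfusionCounts(tp=7, tn=2, fp=3, fn=5))
        assert b.f_score == pytest.approx(
            f_score_from_precision_recall(b.precision, b.recall)
        )

    def test_zero_denominators_flagged(self):
        b = basic_metrics(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
        assert b.recall is None and b.precision is None
        assert {"recall", "precision"} <= b.undefined
        assert b.accuracy == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_chance_level_large_n(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_mannwhitney_with_ties(self):
        scores = np.array([0.1, 0.4, 0.4, 0.8, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        oracle = u / (3 * 3)
        assert auc(scores, labels) == pytest.approx(oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


def shoelace(xy):
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestPAM:
    def test_unit_hexagon(self):
        pa, score = pam([1.0] * 6)
        assert pa == pytest.approx(HEXAGON_AREA)
        assert score == pytest.approx(1.0)

    def test_normalizer_truncates_to_published_constant(self):
        assert math.floor(HEXAGON_AREA * 1e5) / 1e5 == 2.59807

    def test_zero_radii(self):
        pa, score = pam([0.0] * 6)
        assert pa == 0.0 and score == 0.0

    def test_shoelace_oracle_on_random_radii(self):
        rng = np.random.default_rng(1)
        angles = np.deg2rad(90.0 - 60.0 * np.arange(6))
        for _ in range(200):
            radii = rng.random(6)
            xy = np.column_stack(
                [radii * np.cos(angles), radii * np.sin(angles)]
            )
            pa, _ = pam(radii)
            assert pa == pytest.approx(shoelace(xy))

    @settings(max_examples=50, deadline=None)
    @given(
        radii=st.lists(st.floats(0, 1), min_size=6, max_size=6),
        bump=st.integers(0, 5),
        delta=st.floats(0, 0.5),
    )
    def test_monotone_in_each_radius(self, radii, bump, delta):
        _, before = pam(radii)
        bumped = list(radii)
        bumped[bump] = min(1.0, bumped[bump] + delta)
        _, after = pam(bumped)
        assert after >= before - 1e-12

    def test_out_of_range_radius_rejected(self):
        with pytest.raises(ValueError):
            pam([1.1, 1, 1, 1, 1, 1])

    def test_bundle_with_missing_metric_rejected(self):
        b = basic_metrics(ConfusionCounts(5, 5, 1, 1))  # no AUC yet
        with pytest.raises(ValueError, match="auc"):
            pam(b)

    def test_plot_export(self, tmp_path):
        out = tmp_path / "pam.svg"
        plot_pam([0.9, 0.8, 0.7, 0.9, 0.85, 0.95], path=out)
        assert out.stat().st_size > 0


class TestKFold:
    def test_partition_sizes(self):
        folds = kfold_indices(10, k=5, seed=0)
        assert [len(f) for f in folds] == [2] * 5

    def test_partition_property(self):
        for n, k, seed in [(10, 5, 0), (13, 5, 1), (7, 3, 2)]:
            folds = kfold_indices(n, k, seed)
            joined = np.sort(np.concatenate(folds))
            assert np.array_equal(joined, np.arange(n))

    def test_determinism(self):
        a = kfold_indices(20, 5, seed=3)
        b = kfold_indices(20, 5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(10, k=1)

    def test_cv_runs_threshold_classifier(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, (50, 1))
        y = (x[:, 0] > 0.5).astype(int)

        def train(_X, _y, _seed):
            return 0.5

        def predict(model, X):
            return (X[:, 0] > model).astype(int), X[:, 0]

        bundles, mean = kfold_cv(x, y, train, predict, k=5, seed=0)
        assert len(bundles) == 5
        assert mean.accuracy == 1.0
        assert mean.auc == 1.0


class TestCompareMethods:
    A = {"recall": 0.9661, "precision": 0.9344}
    B = {"recall": 0.7788, "precision": 0.7606}

    def test_published_absolute_deltas(self):
        out = compare_methods(self.A, self.B)
        assert out["recall"]["delta"] == 0.1873
        assert out["precision"]["delta"] == 0.1738

    def test_published_relative_improvement(self):
        out = compare_methods(self.A, self.B)
        assert out["recall"]["relative_pct"] == 24.05

    def test_depth_sensor_recall_delta(self):
        out = compare_methods({"recall": 0.9661}, {"recall": 0.9412})
        assert out["recall"]["delta"] == 0.0249

    def test_identity(self):
        out = compare_methods(self.A, self.A)
        assert all(v["delta"] == 0 and v["relative_pct"] == 0 for v in out.values())

    def test_zero_baseline_flagged(self):
        out = compare_methods({"recall": 0.5}, {"recall": 0.0}, metrics=["recall"])
        assert out["recall"]["relative_pct"] is None


class TestMoistureRatio:
    def test_initial_time_is_one(self):
        assert moisture_ratio(Mt=300, Mo=300, Me=0) == 1.0

    def test_equilibrium_is_zero(self):
        assert moisture_ratio(Mt=12, Mo=300, Me=12) == 0.0

    def test_midpoint(self):
        assert moisture_ratio(Mt=150, Mo=290, Me=10) == 0.5

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            moisture_ratio(1, 5, 5)


def test_mean_bundle_skips_undefined():
    a = basic_metrics(ConfusionCounts(5, 5, 0, 0))
    b = basic_metrics(ConfusionCounts(0, 4, 0, 0))  # recall undefined
    m = mean_bundle([a, b])
    assert m.recall == 1.0  # averaged over the one defined value
    assert m.accuracy == 1.0


def test_metrics_to_csv(tmp_path):
    from plantstress3d.evaluation import metrics_to_csv

    b = basic_metrics(ConfusionCounts(5, 5, 0, 0))
    path = tmp_path / "metrics.csv"
    metrics_to_csv(b, path)
    header, values = path.read_text().splitlines()
    assert header.split(",")[0] == "recall"
    assert values.split(",")[0] == "1.000000"
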