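"""Metrics, stratified nested CV, leakage/stratification invariants, band pairing."""

import numpy as np
import pytest
from scipy.stats import binom

from drsviab.classify import (
    ClassifierSpec,
    EvaluationReport,
    HyperparameterGrid,
    band_comparison_experiment,
    compute_metrics,
    fit_predict_classifier,
    make_stratified_folds,
    stratified_nested_cv,
)
from drsviab.dataset import LabeledDataset
from drsviab.simulate import NoiseModel, build_state_library, simulate_spectrum
from drsviab.spectra import FrequencyGrid, PermittivitySpectrum, default_grid


def two_condition_dataset(n_per_class=60, n_points=20, seed=0):
    """Control vs 6 h ischemia spectra under the stated measurement noise:
    the class means differ by far more than the noise sd."""
    lib = build_state_library()
    grid = default_grid(n_points=n_points)
    rng = np.random.default_rng(seed)
    spectra, labels, groups = [], [], []
    for label, cond in (("viable", "Control"), ("nonviable", "I-6h")):
        for i in range(n_per_class):
            spectra.append(simulate_spectrum(lib[cond], grid, NoiseModel(), rng))
            labels.append(label)
            groups.append((f"s{i % 8}", 1 if label == "viable" else 2))
    return LabeledDataset(spectra, labels, groups)


def banded_signal_dataset(n_per_class=50, seed=0):
    """Synthetic two-class data whose class difference is confined, by
    construction, to the 6-14 GHz half of the band."""
    grid = default_grid(n_points=24)
    rng = np.random.default_rng(seed)
    bump = np.where(grid.points >= 6e9, 2.0, 0.0)
    spectra, labels, groups = [], [], []
    for label, shift in (("viable", 0.0), ("nonviable", 1.0)):
        for i in range(n_per_class):
            er = 50.0 + shift * bump + rng.normal(0, 0.5, len(grid))
            ei = 5.0 + np.abs(rng.normal(0, 0.2, len(grid)))
            spectra.append(PermittivitySpectrum(grid, er, ei))
            labels.append(label)
            groups.append((f"s{i}", 1))
    return LabeledDataset(spectra, labels, groups)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1])
        m = compute_metrics(y, y)
        for k in ("accuracy", "f1", "sensitivity", "specificity"):
            assert m[k] == 100.0

    def test_confusion_matrix_arithmetic(self):
        # TP=9, FN=1, TN=8, FP=2
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 9 + [0] + [0] * 8 + [1] * 2)
        m = compute_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["f1"] == pytest.approx(100 * 18 / 21, abs=0.05)  # 85.7 %

    def test_all_positive_predictor(self):
        y_true = np.array([1, 1, 0, 0])
        m = compute_metrics(y_true, np.ones(4, dtype=int))
        assert m["sensitivity"] == 100.0
        assert m["specificity"] == 0.0
        assert m["undefined"] == []

    def test_all_negative_predictor(self):
        # a missed positive keeps the F1 denominator nonzero: F1 = 0, defined
        y_true = np.array([1, 0, 0, 0])
        y_pred = np.array([0, 0, 0, 0])
        m = compute_metrics(y_true, y_pred)
        assert m["f1"] == 0.0
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 100.0
        assert m["undefined"] == []

    def test_accuracy_exact_identity(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 50)
        y_true[:5] = 0
        y_true[5:10] = 1
        y_pred = rng.integers(0, 2, 50)
        m = compute_metrics(y_true, y_pred)
        c = m["confusion"]
        assert m["accuracy"] == 100.0 * (c["tp"] + c["tn"]) / 50

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics(np.ones(4, dtype=int), np.ones(4, dtype=int))


class TestFolds:
    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(0)
        y = (rng.random(103) < 0.3).astype(int)
        folds = make_stratified_folds(y, 5, seed=1)
        pos_share = y.mean()
        for _, test_idx in folds:
            ideal = pos_share * len(test_idx)
            assert abs(y[test_idx].sum() - ideal) <= 1

    def test_folds_partition_the_data(self):
        y = np.array([0, 1] * 20)
        folds = make_stratified_folds(y, 5, seed=0)
        all_test = np.sort(np.concatenate([t for _, t in folds]))
        np.testing.assert_array_equal(all_test, np.arange(40))

    def test_too_few_class_members_rejected(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError):
            make_stratified_folds(y, 5, seed=0)


class TestNestedCV:
    def test_separable_classes_linear_baseline(self):
        data = two_condition_dataset(n_per_class=60, seed=1)
        report = stratified_nested_cv(
            data, ClassifierSpec("linear_baseline"), seed=0
        )
        assert report.rows[0]["accuracy_mean"] >= 95.0

    def test_no_leakage_between_outer_test_and_inner_loops(self):
        data = two_condition_dataset(n_per_class=30, seed=2)
        _, _, details = stratified_nested_cv(
            data, ClassifierSpec("linear_baseline"), seed=3, return_details=True
        )
        for d in details:
            test_set = set(d["test_idx"].tolist())
            rest = d["rest_idx"]
            assert test_set.isdisjoint(rest.tolist())
            for idx_itr, idx_ival in d["inner_folds"]:
                # inner indices address the rest-array; map back to records
                assert test_set.isdisjoint(rest[idx_itr].tolist())
                assert test_set.isdisjoint(rest[idx_ival].tolist())

    def test_permuted_labels_give_chance_accuracy(self):
        """With labels shuffled, pooled outer accuracy must sit inside the
        central 99 % binomial band around the majority-class share."""
        data = two_condition_dataset(n_per_class=60, seed=4)
        rng = np.random.default_rng(99)
        labels = list(data.labels)
        rng.shuffle(labels)
        shuffled = LabeledDataset(data.spectra, labels, data.group_keys)
        _, fold_metrics, _ = stratified_nested_cv(
            shuffled, ClassifierSpec("linear_baseline"), seed=5, return_details=True
        )
        n_total = len(shuffled)
        n_correct = sum(
            fm["confusion"]["tp"] + fm["confusion"]["tn"] for fm in fold_metrics
        )
        lo = binom.ppf(0.005, n_total, 0.5)
        hi = binom.ppf(0.995, n_total, 0.5)
        assert lo <= n_correct <= hi

    def test_same_seed_identical_report(self):
        data = two_condition_dataset(n_per_class=30, seed=6)
        spec = ClassifierSpec("linear_baseline")
        r1 = stratified_nested_cv(data, spec, seed=7)
        r2 = stratified_nested_cv(data, spec, seed=7)
        assert r1.rows == r2.rows

    def test_sequence_family_runs_in_nested_cv(self):
        data = two_condition_dataset(n_per_class=20, n_points=12, seed=8)
        spec = ClassifierSpec(
            "conv1d",
            grid_points=(
                (("learning_rate", 1e-3), ("units", 4), ("batch_size", 16)),
                (("learning_rate", 1e-2), ("units", 4), ("batch_size", 16)),
            ),
            max_epochs=4,
        )
        report = stratified_nested_cv(data, spec, k_outer=2, k_inner=2, seed=0)
        row = report.rows[0]
        assert row["n_folds"] == 2
        assert 0 <= row["accuracy_mean"] <= 100

    def test_group_aware_mode_keeps_groups_intact(self):
        data = two_condition_dataset(n_per_class=40, seed=9)
        _, _, details = stratified_nested_cv(
            data,
            ClassifierSpec("linear_baseline"),
            seed=0,
            group_aware=True,
            return_details=True,
        )
        keys = np.array([f"{s}|{c}" for s, c in data.group_keys])
        for d in details:
            assert set(keys[d["test_idx"]]).isdisjoint(keys[d["rest_idx"]])


class TestFitPredict:
    def test_probabilities_normalised(self):
        data = two_condition_dataset(n_per_class=15, n_points=12, seed=10)
        train, test = data.subset(range(20)), data.subset(range(20, 30))
        _, probs = fit_predict_classifier(
            ClassifierSpec("linear_baseline"), train, test, {"C": 1.0}, seed=0
        )
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_linear_boundary_close_to_generating_threshold(self):
        """1-D threshold structure: the learned boundary lies within one
        grid step of the generating threshold."""
        grid = FrequencyGrid(np.array([1e9, 2e9]))
        xs = np.linspace(40.0, 60.0, 81)
        thresh = 50.0
        spectra = [
            PermittivitySpectrum(grid, np.array([x, 1.0]), np.array([1.0, 1.0]))
            for x in xs
        ]
        labels = ["nonviable" if x >= thresh else "viable" for x in xs]
        data = LabeledDataset(spectra, labels, [("s", 1)] * len(xs))
        y_hat, _ = fit_predict_classifier(
            ClassifierSpec("linear_baseline"), data, data, {"C": 100.0}, seed=0
        )
        flips = xs[np.flatnonzero(np.diff(y_hat)) + 1]
        step = xs[1] - xs[0]
        assert len(flips) == 1
        assert abs(flips[0] - thresh) <= step


class TestBandComparison:
    def test_identical_band_gives_zero_delta(self):
        data = two_condition_dataset(n_per_class=25, seed=11)
        report = band_comparison_experiment(
            data,
            [ClassifierSpec("linear_baseline")],
            seed=0,
            bands={"whole": (200e6, 14e9), "selected": (200e6, 14e9)},
            k_outer=3,
            k_inner=3,
        )
        rows = {r["band"]: r for r in report.rows}
        assert rows["selected"]["accuracy_delta_vs_whole"] == pytest.approx(0.0)

    def test_signal_confined_to_selected_band(self):
        data = banded_signal_dataset(seed=12)
        report = band_comparison_experiment(
            data,
            [ClassifierSpec("linear_baseline")],
            seed=1,
            k_outer=3,
            k_inner=3,
        )
        rows = {r["band"]: r for r in report.rows}
        assert (
            rows["selected"]["accuracy_mean"] >= rows["whole"]["accuracy_mean"] - 1.0
        )

    def test_fold_assignments_paired_across_bands(self):
        data = two_condition_dataset(n_per_class=25, seed=13)
        spec = ClassifierSpec("linear_baseline")
        folds = {}
        for name, band in (("whole", (200e6, 14e9)), ("selected", (6e9, 14e9))):
            sub = data.restrict_band(*band)
            _, _, details = stratified_nested_cv(
                sub, spec, k_outer=3, k_inner=3, seed=2, return_details=True
            )
            folds[name] = [tuple(d["test_idx"].tolist()) for d in details]
        assert folds["whole"] == folds["selected"]


class TestGrid:
    def test_default_grid_is_the_published_search_space(self):
        g = HyperparameterGrid()
        assert g.learning_rate == (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
        assert g.ridge_lambda == (1e-6, 1e-5, 1e-4, 1e-3)
        assert g.batch_size == (8, 16, 32, 64)
        assert g.units == (8, 16, 32, 64)
        assert g.dropout == (0.1, 0.2, 0.3)
        assert len(g.points()) == 5 * 4 * 4 * 4 * 3

    def test_subsample_is_seeded_and_bounded(self):
        g = HyperparameterGrid()
        s1 = g.subsample(10, seed=3)
        s2 = g.subsample(10, seed=3)
        assert s1 == s2 and len(s1) == 10

    def test_report_csv_layout(self, tmp_path):
        rep = EvaluationReport()
        rep.add("linear_baseline", "whole", [
            {"accuracy": 90.0, "f1": 91.0, "sensitivity": 92.0, "specificity": 88.0},
            {"accuracy": 92.0, "f1": 93.0, "sensitivity": 94.0, "specificity": 90.0},
        ])
        path = tmp_path / "r.csv"
        rep.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns)[:4] == ["family", "band", "accuracy_mean", "accuracy_sd"]
        assert df.loc[0, "accuracy_mean"] == pytest.approx(91.0)
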