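"""Viable/non-viable classification with nested stratified cross-validation.

Spectra are classified as viable (< 4 h ischemic exposure) or non-viable.
Hyperparameters are selected in an inner stratified 5-fold loop by validation
accuracy; performance is reported only on outer held-out folds, so no test
record ever influences model selection.  Accuracy, F1, sensitivity and
specificity are reported as mean +/- sd over the outer folds, with the
non-viable class as the positive (detected) class.

Sequence families (LSTM variants and the 1-D CNN) consume each spectrum as a
frequency-ordered sequence of (eps', eps'') steps, standardised per frequency
with training-fold statistics only.  Flat baselines (linear, margin/SVM,
tree ensemble) see the same standardised features concatenated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .dataset import LabeledDataset
from .nets import FAMILIES as NN_FAMILIES
from .nets import SequenceClassifier, TrainConfig
from .spectra import DEFAULT_F_MAX, DEFAULT_F_MIN

__all__ = [
    "HyperparameterGrid",
    "ClassifierSpec",
    "EvaluationReport",
    "compute_metrics",
    "fit_predict_classifier",
    "stratified_nested_cv",
    "band_comparison_experiment",
    "make_stratified_folds",
    "WHOLE_BAND",
    "SELECTED_BAND",
]

WHOLE_BAND = (DEFAULT_F_MIN, DEFAULT_F_MAX)
SELECTED_BAND = (6e9, DEFAULT_F_MAX)

ALL_FAMILIES = NN_FAMILIES + (
    "margin_baseline",
    "tree_ensemble_baseline",
    "linear_baseline",
)


@dataclass(frozen=True)
class HyperparameterGrid:
    """Hyperparameter search space for the sequence networks."""

    learning_rate: tuple[float, ...] = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
    ridge_lambda: tuple[float, ...] = (1e-6, 1e-5, 1e-4, 1e-3)
    batch_size: tuple[int, ...] = (8, 16, 32, 64)
    units: tuple[int, ...] = (8, 16, 32, 64)
    dropout: tuple[float, ...] = (0.1, 0.2, 0.3)

    def points(self) -> list[dict]:
        keys = ("learning_rate", "ridge_lambda", "batch_size", "units", "dropout")
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(getattr(self, k) for k in keys))
        ]

    def subsample(self, n: int, seed: int = 0) -> list[dict]:
        """Seeded subsample of the full grid (for desk-scale searches)."""
        pts = self.points()
        if n >= len(pts):
            return pts
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(pts), size=n, replace=False))
        return [pts[i] for i in idx]


#: Small fixed grids for the flat baselines.
BASELINE_GRIDS = {
    "linear_baseline": [{"C": c} for c in (0.01, 1.0, 100.0)],
    "margin_baseline": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "tree_ensemble_baseline": [
        {"n_estimators": n, "max_depth": d} for n in (100,) for d in (None, 10)
    ],
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus its hyperparameter search space.

    Sequence families use 3 stacked sequence layers + dense softmax; the
    conv family uses 2 convolutional layers + max pooling + dense.
    ``grid_points`` (if given) overrides the full grid -- nested search over
    the complete default grid is far beyond desk scale for the networks.
    """

    family: str
    grid: HyperparameterGrid = field(default_factory=HyperparameterGrid)
    grid_points: tuple | None = None
    n_layers: int = 3
    kernel: int = 5
    max_epochs: int = 100
    patience: int = 10

    def __post_init__(self):
        if self.family not in ALL_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    def search_points(self) -> list[dict]:
        if self.grid_points is not None:
            return [dict(p) for p in self.grid_points]
        if self.family in NN_FAMILIES:
            return self.grid.points()
        return [dict(p) for p in BASELINE_GRIDS[self.family]]


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(y_true, y_pred, positive: int = 1) -> dict:
    """Accuracy, F1, sensitivity and specificity in percent.

    The positive class defaults to 1 = non-viable (the clinically sought
    detection).  Metrics with an empty denominator are returned as NaN and
    named in the ``undefined`` list rather than silently zeroed.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true must contain both classes")
    pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    out = {
        "accuracy": 100.0 * (tp + tn) / len(y_true),
        "f1": ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        "undefined": undefined,
    }
    return out


# ---------------------------------------------------------------------------
# feature preparation


class _Standardizer:
    """Per-frequency, per-channel standardisation with train statistics."""

    def fit(self, X):
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd_ = sd
        return self

    def transform(self, X):
        return (X - self.mean_) / self.sd_


def _flatten(X):
    return X.reshape(X.shape[0], -1)


def fit_predict_classifier(
    spec: ClassifierSpec,
    train: LabeledDataset,
    test: LabeledDataset,
    hp: dict,
    seed: int = 0,
    val: LabeledDataset | None = None,
):
    """Fit one classifier at one grid point; predict labels + probabilities.

    Returns ``(y_pred, probs)`` with ``probs`` of shape (n_test, 2) summing
    to 1 per record.  Deterministic given the seed.
    """
    X_tr, y_tr = train.to_arrays()
    X_te, _ = test.to_arrays()
    std = _Standardizer().fit(X_tr)
    X_tr, X_te = std.transform(X_tr), std.transform(X_te)
    X_val = y_val = None
    if val is not None and len(val):
        X_val, y_val = val.to_arrays()
        X_val = std.transform(X_val)

    if spec.family in NN_FAMILIES:
        clf = SequenceClassifier(
            spec.family,
            units=int(hp.get("units", 16)),
            dropout=float(hp.get("dropout", 0.1)),
            seed=seed,
            kernel=spec.kernel,
            n_layers=spec.n_layers,
        )
        cfg = TrainConfig(
            learning_rate=float(hp.get("learning_rate", 1e-3)),
            ridge_lambda=float(hp.get("ridge_lambda", 1e-4)),
            batch_size=int(hp.get("batch_size", 32)),
            max_epochs=spec.max_epochs,
            patience=spec.patience,
        )
        clf.fit(X_tr, y_tr, X_val, y_val, config=cfg)
        probs = clf.predict_proba(X_te)
    else:
        Xf_tr, Xf_te = _flatten(X_tr), _flatten(X_te)
        if spec.family == "linear_baseline":
            model = LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)
        elif spec.family == "margin_baseline":
            model = SVC(C=hp.get("C", 1.0), probability=True, random_state=seed)
        else:
            model = RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 100),
                max_depth=hp.get("max_depth"),
                random_state=seed,
            )
        model.fit(Xf_tr, y_tr)
        probs = model.predict_proba(Xf_te)
        if probs.shape[1] == 1:  # single-class training fold
            probs = np.hstack([1 - probs, probs])
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# nested CV


def make_stratified_folds(
    y, k: int, seed: int, groups=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified (optionally group-aware) fold index pairs."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for a stratified split")
    if np.bincount(y).min() < k:
        raise ValueError(f"need at least {k} members of each class")
    if groups is not None:
        cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(y)), y, groups))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


@dataclass
class EvaluationReport:
    """Per-(family, band) metrics: mean and sd over outer folds, percent."""

    rows: list[dict] = field(default_factory=list)

    def add(self, family, band, fold_metrics, extra=None):
        row = {"family": family, "band": band}
        for m in ("accuracy", "f1", "sensitivity", "specificity"):
            vals = np.array([fm[m] for fm in fold_metrics], dtype=float)
            row[f"{m}_mean"] = float(np.nanmean(vals))
            row[f"{m}_sd"] = float(np.nanstd(vals))
        row["n_folds"] = len(fold_metrics)
        if extra:
            row.update(extra)
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path):
        cols = [
            "family",
            "band",
            "accuracy_mean",
            "accuracy_sd",
            "f1_mean",
            "f1_sd",
            "sensitivity_mean",
            "sensitivity_sd",
            "specificity_mean",
            "specificity_sd",
        ]
        df = self.to_frame()
        df[[c for c in cols if c in df.columns]].to_csv(path, index=False)


def stratified_nested_cv(
    data: LabeledDataset,
    spec: ClassifierSpec,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
    group_aware: bool = False,
    band_label: str = "whole",
    return_details: bool = False,
):
    """Nested stratified k-fold cross-validation of one classifier family.

    For each outer fold the hyperparameter grid is searched only on inner
    folds of the remaining data; the winner (highest mean inner-validation
    accuracy, ties to the first grid point) is refit on all non-test data
    and evaluated once on the held-out fold.  ``group_aware=True`` splits by
    (subject, case) instead, preventing repeated-measurement leakage at the
    cost of departing from label-only stratification.
    """
    y = data.y
    groups = (
        np.array([f"{s}|{c}" for s, c in data.group_keys]) if group_aware else None
    )
    outer = make_stratified_folds(y, k_outer, seed, groups)
    fold_metrics = []
    details = []
    for fold_i, (idx_rest, idx_test) in enumerate(outer):
        rest, test = data.subset(idx_rest), data.subset(idx_test)
        y_rest = y[idx_rest]
        inner = make_stratified_folds(
            y_rest,
            k_inner,
            seed + 1000 + fold_i,
            groups[idx_rest] if groups is not None else None,
        )
        grid_pts = spec.search_points()
        if len(grid_pts) == 1:
            best_hp = grid_pts[0]
            inner_acc = [np.nan]
        else:
            inner_acc = []
            for hp in grid_pts:
                accs = []
                for idx_itr, idx_ival in inner:
                    tr, va = rest.subset(idx_itr), rest.subset(idx_ival)
                    y_hat, _ = fit_predict_classifier(
                        spec, tr, va, hp, seed=seed + fold_i, val=va
                    )
                    accs.append(float(np.mean(y_hat == y_rest[idx_ival])))
                inner_acc.append(float(np.mean(accs)))
            best_hp = grid_pts[int(np.argmax(inner_acc))]
        y_hat, _ = fit_predict_classifier(
            spec, rest, test, best_hp, seed=seed + fold_i
        )
        fold_metrics.append(compute_metrics(y[idx_test], y_hat))
        details.append(
            {
                "fold": fold_i,
                "test_idx": np.asarray(idx_test),
                "rest_idx": np.asarray(idx_rest),
                "inner_folds": inner,
                "best_hp": best_hp,
                "inner_accuracy": inner_acc,
            }
        )
    report = EvaluationReport()
    report.add(spec.family, band_label, fold_metrics)
    if return_details:
        return report, fold_metrics, details
    return report


def band_comparison_experiment(
    data: LabeledDataset,
    specs: list[ClassifierSpec],
    seed: int = 0,
    bands: dict[str, tuple[float, float]] | None = None,
    k_outer: int = 5,
    k_inner: int = 5,
    group_aware: bool = False,
) -> EvaluationReport:
    """Paired whole-band vs selected-band evaluation.

    Fold assignments depend only on the labels and the seed, so they are
    identical across bands (a paired design); the report carries the mean
    accuracy delta (band minus whole) per family.
    """
    bands = bands or {"whole": WHOLE_BAND, "selected": SELECTED_BAND}
    report = EvaluationReport()
    for spec in specs:
        per_band = {}
        for name, (f_lo, f_hi) in bands.items():
            sub = data.restrict_band(f_lo, f_hi)
            r = stratified_nested_cv(
                sub,
                spec,
                k_outer=k_outer,
                k_inner=k_inner,
                seed=seed,
                group_aware=group_aware,
                band_label=name,
            )
            per_band[name] = r.rows[0]
        ref = per_band.get("whole")
        for name, row in per_band.items():
            extra = {}
            if ref is not None:
                extra["accuracy_delta_vs_whole"] = (
                    row["accuracy_mean"] - ref["accuracy_mean"]
                )
            row = dict(row)
            row.update(extra)
            report.rows.append(row)
    return report
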