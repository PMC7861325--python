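"""Classifier evaluation: leave-one-subject-out CV, balanced undersampling,
and the selector x classifier grid.

The protocol: for every held-out subject, the remaining subjects' rows
are balanced by randomly undersampling the majority class, standardized
with training-fold statistics, and used to train the classifier, which
then predicts every row of the held-out subject.  Because undersampling
discards rows at random, the whole procedure is repeated for five
iterations and the confusion counts are pooled over all subjects and
iterations (a metric-averaging mode is available).  Metrics: sensitivity
(impaired = positive class), specificity, balanced accuracy = the
geometric mean sqrt(sensitivity x specificity), and bias = sensitivity -
specificity.

Feature selection can run nested (re-selected inside each training fold;
leakage-free, the default) or globally on the full dataset before the
outer loop (select once on the full dataset, as the emulated study most plausibly did).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifiers import CLASSIFIER_IDS, make_classifier
from .feature_stats import compute_index_stats
from .selection import FeatureSubset, SelectionConfig, select

SELECTOR_IDS: tuple[str, ...] = ("all", "t_filter", "fisher_filter", "sfs", "ga")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn,
            self.tn + other.tn, self.fp + other.fp,
        )


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    bias: float


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return math.sqrt(sensitivity * specificity)


def metrics_from_confusion(c: ConfusionCounts) -> Metrics:
    """Sensitivity/specificity/balanced accuracy/bias from pooled counts."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must appear in the test pool")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return Metrics(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=balanced_accuracy(sens, spec),
        bias=sens - spec,
    )


def undersample_balance(
    data: pd.DataFrame, seed: int, label_col: str = "label"
) -> pd.DataFrame:
    """Balance classes by randomly undersampling the majority class.

    Minority rows are kept untouched; majority rows are sampled without
    replacement down to the minority count.  Deterministic per seed.
    """
    counts = data[label_col].value_counts()
    if len(counts) < 2:
        raise ValueError("training set must contain both classes")
    minority = counts.idxmin()
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls, sub in data.groupby(label_col, sort=True):
        if cls == minority or len(sub) == n_min:
            parts.append(sub)
        else:
            idx = rng.choice(len(sub), size=n_min, replace=False)
            parts.append(sub.iloc[np.sort(idx)])
    return pd.concat(parts).sort_index()


@dataclass(frozen=True)
class EvalConfig:
    n_iterations: int = 5
    seed: int = 0
    standardize: bool = True
    aggregation: str = "pooled"  # pooled counts | "averaged" metrics
    selection_scope: str = "nested"  # nested | global (single full-dataset selection)
    objective_mode: str = "cv"  # cv (grouped k-fold) | loso (same protocol as the report)
    inner_cv_folds: int = 3  # grouped CV folds for the "cv" wrapper objective
    objective_iterations: int = 1  # undersampling iterations inside the "loso" objective
    classifier_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.aggregation not in {"pooled", "averaged"}:
            raise ValueError("aggregation must be 'pooled' or 'averaged'")
        if self.selection_scope not in {"nested", "global"}:
            raise ValueError("selection_scope must be 'nested' or 'global'")
        if self.objective_mode not in {"cv", "loso"}:
            raise ValueError("objective_mode must be 'cv' or 'loso'")


def _derive_seed(*parts: int) -> int:
    """Deterministic 31-bit seed from structured parts."""
    return int(np.random.SeedSequence(entropy=list(parts)).generate_state(1)[0] % (2**31))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _fit_predict(
    spec_id: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int,
    config: EvalConfig,
) -> np.ndarray:
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(X_test))):
        raise ValueError("non-finite feature values")
    if config.standardize:
        X_train, X_test = _standardize(X_train, X_test)
    overrides = config.classifier_overrides.get(spec_id, {})
    clf = make_classifier(spec_id, seed=seed, X=X_train, **overrides)
    if len(np.unique(y_train)) == 1:
        # degenerate fold: constant predictor
        return np.full(X_test.shape[0], y_train[0])
    clf.fit(X_train, y_train)
    return np.asarray(clf.predict(X_test))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def loso_evaluate(
    spec_id: str,
    data: pd.DataFrame,
    features: tuple[str, ...] | FeatureSubset,
    config: EvalConfig = EvalConfig(),
    label_col: str = "label",
    subject_col: str = "subject_id",
) -> tuple[Metrics, list[dict]]:
    """Leave-one-subject-out evaluation of one classifier on one subset.

    Returns (metrics, per-fold detail records).  With ``pooled``
    aggregation the metrics come from confusion counts summed over every
    (iteration, held-out subject) fold; with ``averaged`` they are the
    mean of per-iteration pooled metrics.
    """
    if isinstance(features, FeatureSubset):
        features = features.features
    features = list(features)
    subjects = sorted(data[subject_col].unique())
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects for leave-one-subject-out")
    detail: list[dict] = []
    total = ConfusionCounts()
    per_iter_metrics: list[Metrics] = []
    for it in range(config.n_iterations):
        it_counts = ConfusionCounts()
        for subj in subjects:
            test = data[data[subject_col] == subj]
            train = data[data[subject_col] != subj]
            if len(test) == 0:
                warnings.warn(f"subject {subj} has no rows; skipped")
                continue
            sub_seed = _derive_seed(config.seed, it, int(subj))
            train_bal = undersample_balance(train, seed=sub_seed, label_col=label_col)
            y_pred = _fit_predict(
                spec_id,
                train_bal[features].to_numpy(dtype=float),
                train_bal[label_col].to_numpy(),
                test[features].to_numpy(dtype=float),
                seed=sub_seed,
                config=config,
            )
            c = _confusion(test[label_col].to_numpy(), y_pred)
            it_counts = it_counts + c
            detail.append(
                {"iteration": it, "subject": subj, "tp": c.tp, "fn": c.fn,
                 "tn": c.tn, "fp": c.fp}
            )
        total = total + it_counts
        if config.aggregation == "averaged":
            per_iter_metrics.append(metrics_from_confusion(it_counts))
    if config.aggregation == "averaged":
        sens = float(np.mean([m.sensitivity for m in per_iter_metrics]))
        spec = float(np.mean([m.specificity for m in per_iter_metrics]))
        metrics = Metrics(sens, spec, balanced_accuracy(sens, spec), sens - spec)
    else:
        metrics = metrics_from_confusion(total)
    return metrics, detail


def make_subset_objective(
    spec_id: str,
    data: pd.DataFrame,
    config: EvalConfig,
    label_col: str = "label",
    subject_col: str = "subject_id",
    feature_names: list[str] | None = None,
):
    """Wrapper objective: subset -> balanced accuracy on ``data``.

    ``objective_mode="cv"``: grouped cross-validation over subjects
    (round-robin into ``inner_cv_folds`` folds), undersampling and
    standardization inside each training fold, counts pooled over folds.
    ``objective_mode="loso"``: the leave-one-subject-out protocol of the
    final report (same folds and undersampling-seed scheme, over
    ``objective_iterations`` undersampling draws), so the wrapper
    maximizes the quantity being reported.  In both
    modes splits depend only on the evaluation seed, so different subsets
    are compared on identical data.
    """
    subjects = sorted(data[subject_col].unique())
    splits = []
    if config.objective_mode == "loso":
        for it in range(config.objective_iterations):
            for subj in subjects:
                test = data[data[subject_col] == subj]
                train = data[data[subject_col] != subj]
                if test.empty or train[label_col].nunique() < 2:
                    continue
                seed = _derive_seed(config.seed, it, int(subj))
                train_bal = undersample_balance(train, seed=seed, label_col=label_col)
                splits.append((train_bal, test, seed))
    else:
        k = min(config.inner_cv_folds, len(subjects))
        folds: list[list] = [subjects[i::k] for i in range(k)]
        for f, held in enumerate(folds):
            test = data[data[subject_col].isin(held)]
            train = data[~data[subject_col].isin(held)]
            if test.empty or train[label_col].nunique() < 2:
                continue
            seed = _derive_seed(config.seed, 7001, f)
            train_bal = undersample_balance(train, seed=seed, label_col=label_col)
            splits.append((train_bal, test, seed))

    if feature_names is None:
        feature_names = [
            c for c in data.columns
            if c not in {label_col, subject_col} and data[c].dtype.kind in "fi"
        ]
    col_index = {name: j for j, name in enumerate(feature_names)}
    # pre-extracted numpy views: the wrapper slices columns per candidate subset
    np_splits = [
        (
            train_bal[feature_names].to_numpy(dtype=float),
            train_bal[label_col].to_numpy(),
            test[feature_names].to_numpy(dtype=float),
            test[label_col].to_numpy(),
            seed,
        )
        for train_bal, test, seed in splits
    ]

    def objective(subset: tuple[str, ...]) -> float:
        if not subset:
            return 0.0
        cols = [col_index[f] for f in subset]
        total = ConfusionCounts()
        for Xtr, ytr, Xte, yte, seed in np_splits:
            y_pred = _fit_predict(
                spec_id, Xtr[:, cols], ytr, Xte[:, cols], seed=seed, config=config
            )
            total = total + _confusion(yte, y_pred)
        if total.tp + total.fn == 0 or total.tn + total.fp == 0:
            return 0.0
        return metrics_from_confusion(total).balanced_accuracy

    return objective


def _select_for(
    selector: str,
    spec_id: str,
    data: pd.DataFrame,
    feature_names: list[str],
    sel_config: SelectionConfig,
    eval_config: EvalConfig,
    label_col: str,
    subject_col: str,
) -> FeatureSubset:
    sel = replace(sel_config, method=selector)
    if selector == "all":
        return select(sel, feature_names)
    if selector in {"t_filter", "fisher_filter"}:
        stats = compute_index_stats(data, feature_names, label_col=label_col)
        return select(sel, feature_names, stats=stats)
    objective = make_subset_objective(
        spec_id, data, eval_config, label_col=label_col, subject_col=subject_col
    )
    return select(sel, feature_names, objective=objective)


@dataclass
class GridResult:
    """Selector x classifier grid: metric matrices plus per-cell detail."""

    balanced_accuracy: pd.DataFrame  # classifiers x selectors
    sensitivity: pd.DataFrame
    specificity: pd.DataFrame
    bias: pd.DataFrame
    subsets: dict  # (classifier, selector) -> FeatureSubset | dict of per-fold subsets
    failures: list = field(default_factory=list)


def run_grid(
    data: pd.DataFrame,
    feature_names: list[str],
    eval_config: EvalConfig = EvalConfig(),
    sel_config: SelectionConfig = SelectionConfig(),
    classifiers: tuple[str, ...] = CLASSIFIER_IDS,
    selectors: tuple[str, ...] = SELECTOR_IDS,
    label_col: str = "label",
    subject_col: str = "subject_id",
) -> GridResult:
    """Evaluate every (classifier, selector) cell.

    ``selection_scope="global"`` selects one subset per cell on the full
    dataset, then runs LOSO with it.  ``"nested"`` re-selects inside each
    outer training fold; the held-out subject never influences its own
    feature set.  A failed cell is recorded and left missing.
    """
    mats = {
        name: pd.DataFrame(np.nan, index=list(classifiers), columns=list(selectors))
        for name in ("balanced_accuracy", "sensitivity", "specificity", "bias")
    }
    subsets: dict = {}
    failures: list = []
    subjects = sorted(data[subject_col].unique())
    for spec_id in classifiers:
        for selector in selectors:
            try:
                if eval_config.selection_scope == "global" or selector == "all":
                    subset = _select_for(
                        selector, spec_id, data, feature_names,
                        sel_config, eval_config, label_col, subject_col,
                    )
                    metrics, _ = loso_evaluate(
                        spec_id, data, subset, eval_config, label_col, subject_col
                    )
                    subsets[(spec_id, selector)] = subset
                else:
                    metrics, fold_subsets = _nested_cell(
                        spec_id, selector, data, feature_names,
                        sel_config, eval_config, label_col, subject_col, subjects,
                    )
                    subsets[(spec_id, selector)] = fold_subsets
            except Exception as exc:  # record and continue with the grid
                failures.append((spec_id, selector, repr(exc)))
                continue
            mats["balanced_accuracy"].loc[spec_id, selector] = metrics.balanced_accuracy
            mats["sensitivity"].loc[spec_id, selector] = metrics.sensitivity
            mats["specificity"].loc[spec_id, selector] = metrics.specificity
            mats["bias"].loc[spec_id, selector] = metrics.bias
    return GridResult(
        balanced_accuracy=mats["balanced_accuracy"],
        sensitivity=mats["sensitivity"],
        specificity=mats["specificity"],
        bias=mats["bias"],
        subsets=subsets,
        failures=failures,
    )


def _nested_cell(
    spec_id: str,
    selector: str,
    data: pd.DataFrame,
    feature_names: list[str],
    sel_config: SelectionConfig,
    eval_config: EvalConfig,
    label_col: str,
    subject_col: str,
    subjects: list,
) -> tuple[Metrics, dict]:
    """One grid cell with per-outer-fold feature selection.

    The subset for a held-out subject is selected on the other subjects'
    rows only (selection once per fold, reused across the undersampling
    iterations); counts pooled as in ``loso_evaluate``.
    """
    fold_subsets: dict = {}
    total = ConfusionCounts()
    per_iter: list[ConfusionCounts] = [ConfusionCounts() for _ in range(eval_config.n_iterations)]
    for subj in subjects:
        test = data[data[subject_col] == subj]
        train = data[data[subject_col] != subj]
        if test.empty:
            warnings.warn(f"subject {subj} has no rows; skipped")
            continue
        subset = _select_for(
            selector, spec_id, train, feature_names,
            sel_config, eval_config, label_col, subject_col,
        )
        fold_subsets[subj] = subset
        feats = list(subset.features)
        for it in range(eval_config.n_iterations):
            sub_seed = _derive_seed(eval_config.seed, it, int(subj))
            train_bal = undersample_balance(train, seed=sub_seed, label_col=label_col)
            y_pred = _fit_predict(
                spec_id,
                train_bal[feats].to_numpy(dtype=float),
                train_bal[label_col].to_numpy(),
                test[feats].to_numpy(dtype=float),
                seed=sub_seed,
                config=eval_config,
            )
            c = _confusion(test[label_col].to_numpy(), y_pred)
            per_iter[it] = per_iter[it] + c
            total = total + c
    if eval_config.aggregation == "averaged":
        ms = [metrics_from_confusion(c) for c in per_iter]
        sens = float(np.mean([m.sensitivity for m in ms]))
        spec = float(np.mean([m.specificity for m in ms]))
        return Metrics(sens, spec, balanced_accuracy(sens, spec), sens - spec), fold_subsets
    return metrics_from_confusion(total), fold_subsets
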