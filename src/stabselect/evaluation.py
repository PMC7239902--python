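"""Nested cross-validation, independent testing and permutation significance.

Model development runs 10 stratified outer folds.  Inside each fold the
z-scoring parameters, the feature subset and the SVM-RBF hyperparameters
(C in {2^1..2^7}, gamma in {2^-7..2^-1}, tuned by inner 10-fold CV) are all
re-fit on the fold's training part only, and the untouched validation part
is scored; the development accuracy is the mean over the ten folds.  The
ten fitted fold models are kept and each one — its normalisation, its
feature subset and its classifier — predicts the held-out test sample; the
reported testing metrics are means over the ten models, with the autistic
class as the positive class.

Statistical significance uses a label-permutation test: development and
test labels are permuted jointly, the entire development pipeline
(selection included) is re-run, and the empirical p is
(#{permuted >= observed} + 1) / (n_permutations + 1), so 100 permutations
floor the attainable p at 1/101 < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .matrix import FeatureMatrix, GROUP_AUTISTIC
from .preprocessing import NormalizationParams, apply_zscore, fit_zscore
from .selection import wrapped_t_select
from .stability import kuncheva_index


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM-RBF hyperparameter grids and inner CV folds."""

    c_grid: tuple[float, ...] = tuple(2.0 ** j for j in range(1, 8))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** i for i in range(-7, 0))
    inner_folds: int = 10

    def __post_init__(self):
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if min(self.c_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValueError("C and gamma must be positive")


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class FoldModel:
    """Everything one outer fold fitted: normalisation, features, classifier."""

    norm: NormalizationParams
    features: tuple[str, ...]
    feature_idx: tuple[int, ...]
    svm: SVC
    C: float
    gamma: float
    inner_accuracy: float
    fold_accuracy: float
    train_idx: tuple[int, ...] = ()


@dataclass
class DevelopmentResult:
    """Nested-CV output: per-fold accuracies, models and selection stability."""

    fold_accuracies: list[float]
    fold_models: list[FoldModel]
    feature_sets: list[tuple[str, ...]]
    ki: float
    seed: int

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class TestResult:
    accuracy: float
    sensitivity: float
    specificity: float
    per_model: list[dict]


@dataclass
class EvaluationResult:
    development: DevelopmentResult
    test: TestResult | None = None
    repeats: list[dict] = field(default_factory=list)
    p_value: float | None = None


def grid_search_svm(X: np.ndarray, y: np.ndarray,
                    config: ClassifierConfig = DEFAULT_CONFIG,
                    seed: int = 0) -> tuple[SVC, float, float, float]:
    """Exhaustive (C, gamma) search by inner stratified CV accuracy.

    Ties favour the smallest C and then the largest gamma (the smoother
    model).  Returns the model refit on all rows plus the winning pair and
    its inner CV accuracy.
    """
    class_min = int(min(np.sum(y == c) for c in np.unique(y)))
    n_splits = min(config.inner_folds, class_min)
    if n_splits < 2:
        raise ValueError("class sizes too small for inner cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best = None  # (acc, C, gamma)
    for C in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid, reverse=True):
            correct = 0
            total = 0
            for tr, va in folds:
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(X[tr], y[tr])
                correct += int((clf.predict(X[va]) == y[va]).sum())
                total += len(va)
            acc = correct / total
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    acc, C, gamma = best
    model = SVC(kernel="rbf", C=C, gamma=gamma)
    model.fit(X, y)
    return model, C, gamma, acc


def nested_cv(dev: FeatureMatrix, selector, config: ClassifierConfig = DEFAULT_CONFIG,
              seed: int = 0, outer_folds: int = 10) -> DevelopmentResult:
    """Leakage-free model development over stratified outer folds.

    ``selector(X, y, ids, rng) -> feature ids`` sees only the z-scored
    training part of each fold.
    """
    X, y = dev.to_arrays()
    ids = dev.feature_ids
    ss = np.random.SeedSequence(seed)
    outer_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    fold_streams = ss.spawn(outer_folds)

    class_min = int(min(np.sum(y == c) for c in np.unique(y)))
    n_splits = min(outer_folds, class_min)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=outer_seed)

    fold_models, fold_accs, feature_sets = [], [], []
    for f, (tr, va) in enumerate(skf.split(X, y)):
        stream = fold_streams[f]
        params = fit_zscore(X[tr], feature_ids=ids)
        Xtr = apply_zscore(params, X[tr])
        Xva = apply_zscore(params, X[va])
        selected = tuple(selector(Xtr, y[tr], ids, stream))
        idx = tuple(ids.index(fid) for fid in selected)
        inner_seed = int(np.random.default_rng(stream).integers(2 ** 31))
        model, C, gamma, inner_acc = grid_search_svm(
            Xtr[:, idx], y[tr], config, seed=inner_seed)
        acc = float((model.predict(Xva[:, idx]) == y[va]).mean())
        fold_models.append(FoldModel(params, selected, idx, model, C, gamma,
                                     inner_acc, acc, tuple(int(i) for i in tr)))
        fold_accs.append(acc)
        feature_sets.append(selected)

    ki = kuncheva_index([set(s) for s in feature_sets], n_features=len(ids))
    return DevelopmentResult(fold_accs, fold_models, feature_sets, ki, seed)


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return {
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
    }


def independent_test(fold_models, testset: FeatureMatrix) -> TestResult:
    """Score every fold model on the held-out sample and average the metrics.

    Each model applies its own development-fitted normalisation and feature
    subset; the positive class for sensitivity/specificity is autistic.
    """
    X, y = testset.to_arrays()
    ids = testset.feature_ids
    per_model = []
    for model in fold_models:
        if tuple(ids) != model.norm.feature_ids:
            raise ValueError("test matrix features do not match the fold model")
        Xz = apply_zscore(model.norm, X)
        pred = model.svm.predict(Xz[:, list(model.feature_idx)])
        metrics = _confusion_metrics(y, pred)
        metrics["C"] = model.C
        metrics["gamma"] = model.gamma
        per_model.append(metrics)
    return TestResult(
        accuracy=float(np.mean([m["accuracy"] for m in per_model])),
        sensitivity=float(np.mean([m["sensitivity"] for m in per_model])),
        specificity=float(np.mean([m["specificity"] for m in per_model])),
        per_model=per_model,
    )


def evaluate_wrapped(dev: FeatureMatrix, test: FeatureMatrix | None = None,
                     k: int = 10, delta: float = 1e-4,
                     stable_runs: int = 100,
                     config: ClassifierConfig = DEFAULT_CONFIG,
                     seed: int = 0, max_iterations: int = 100_000):
    """Development and testing with the wrapped t-test selector.

    The wrapped run's frozen folds double as the outer CV partition: after
    the selector stabilises on one feature set, each fold grid-searches the
    classifier on that set and is scored on its held-out part, and the ten
    fold models predict the independent sample.

    Returns ``(EvaluationResult, WrappedState)``.
    """
    X, y = dev.to_arrays()
    ids = dev.feature_ids
    final, state = wrapped_t_select(dev, k=k, delta=delta,
                                    stable_runs=stable_runs, seed=seed,
                                    max_iterations=max_iterations)
    idx = tuple(ids.index(fid) for fid in final)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    fold_models, fold_accs, feature_sets = [], [], []
    for tr, va in state.fold_indices:
        params = fit_zscore(X[tr], feature_ids=ids)
        Xtr = apply_zscore(params, X[tr])
        Xva = apply_zscore(params, X[va])
        model, C, gamma, inner_acc = grid_search_svm(
            Xtr[:, idx], y[tr], config, seed=int(rng.integers(2 ** 31)))
        acc = float((model.predict(Xva[:, idx]) == y[va]).mean())
        fold_models.append(FoldModel(params, final, idx, model, C, gamma,
                                     inner_acc, acc, tuple(int(i) for i in tr)))
        fold_accs.append(acc)
        feature_sets.append(final)
    development = DevelopmentResult(fold_accs, fold_models, feature_sets,
                                    kuncheva_index([set(s) for s in feature_sets],
                                                   n_features=len(ids)),
                                    seed)
    result = EvaluationResult(development)
    if test is not None:
        result.test = independent_test(fold_models, test)
    return result, state


def repeat_runs(dev: FeatureMatrix, test: FeatureMatrix | None, selector,
                config: ClassifierConfig = DEFAULT_CONFIG,
                n_repeats: int = 50, seed: int = 0) -> EvaluationResult:
    """Repeat development (fresh outer partitions) to get metric distributions."""
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_repeats)]
    repeats = []
    last = None
    for rs in repeat_seeds:
        development = nested_cv(dev, selector, config, seed=rs)
        record = {"seed": rs, "dev_accuracy": development.accuracy,
                  "ki": development.ki}
        test_result = None
        if test is not None:
            test_result = independent_test(development.fold_models, test)
            record.update(test_accuracy=test_result.accuracy,
                          sensitivity=test_result.sensitivity,
                          specificity=test_result.specificity)
        repeats.append(record)
        last = EvaluationResult(development, test_result)
    last.repeats = repeats
    return last


def summarize_repeats(repeats: list[dict]) -> dict:
    """Median and IQR of each recorded metric over the repeat runs."""
    frame = pd.DataFrame(repeats).drop(columns=["seed"], errors="ignore")
    out = {}
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[col] = {"median": float(med), "iqr": (float(q1), float(q3)),
                    "mean": float(vals.mean())}
    return out


def empirical_p(observed: float, permuted) -> float:
    """(#{permuted >= observed} + 1) / (n + 1) — the permutation p-value."""
    permuted = np.asarray(list(permuted), dtype=float)
    if permuted.size < 1:
        raise ValueError("need at least one permutation")
    return float((np.sum(permuted >= observed) + 1) / (permuted.size + 1))


def permutation_significance(dev: FeatureMatrix, test: FeatureMatrix,
                             selector, observed: float,
                             config: ClassifierConfig = DEFAULT_CONFIG,
                             n_permutations: int = 100,
                             seed: int = 0) -> tuple[float, list[float]]:
    """Empirical p for the observed testing accuracy.

    Development and test labels are permuted jointly and the whole pipeline
    — selection, tuning, testing — reruns per permutation with a fresh
    outer partition.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    all_labels = np.concatenate([dev.labels.to_numpy(), test.labels.to_numpy()])
    n_dev = dev.n_samples
    permuted_accs = []
    for b in range(n_permutations):
        perm = rng.permutation(all_labels)
        dev_b = dev.with_labels(perm[:n_dev])
        test_b = test.with_labels(perm[n_dev:])
        run_seed = int(rng.integers(2 ** 31))
        development = nested_cv(dev_b, selector, config, seed=run_seed)
        permuted_accs.append(independent_test(development.fold_models, test_b).accuracy)
    return empirical_p(observed, permuted_accs), permuted_accs
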