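"""Ensemble machine-learning biomarker discovery.

Three models are trained per classification task and platform: random-forest
recursive feature elimination (``rf_rfe``), bagged-tree RFE (``bagged_rfe``) —
the two wrapper methods — and a tuned random forest ranked by impurity
importance (``rf_embedded``).  The workflow per task:

1. stratified 75/25 train/test split;
2. minority classes upsampled with replacement to the majority size (training
   partition only — the test set stays untouched by selection and balancing);
3. each wrapper runs RFE over a subset-size grid with stratified k-fold CV,
   picking the size with the best mean held-out accuracy (ties to the smaller
   size) and aggregating per-fold rankings by mean rank; the embedded model
   tunes its features-per-split parameter by CV and ranks all predictors;
4. each model is finalized on its top-15 predictors: refit on the balanced
   training set, scored on the untouched test set (accuracy, per-class
   sensitivity, and an exact one-sided binomial p-value of the accuracy against
   the no-information rate);
5. models with accuracy < 0.80 or p >= 0.05 are excluded; the predictors found
   in every surviving model's top 15 are the consensus biomarkers, ordered by
   their mean rank across models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.stats import binomtest
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.tree import DecisionTreeClassifier

from .datamodel import EmissionMatrix, SpeciesAnnotation, ValidationError
from .dapc import labels_for_samples

__all__ = ["MLTask", "ModelResult", "BiomarkerReport", "stratified_split",
           "upsample_minority", "rfe_wrapper", "embedded_rf", "finalize_model",
           "consensus_biomarkers", "run_task", "DEFAULT_SUBSET_GRID"]

DEFAULT_SUBSET_GRID = (5, 10, 15, 20, 30, 50)  # "all features" appended at run time
ACCURACY_BAR = 0.80
ALPHA = 0.05
EstimatorKind = Literal["random_forest", "bagged_trees"]


@dataclass(frozen=True)
class MLTask:
    label: str                       # phylum | trophic_mode | lifestyle | substrate | host_type
    platform: str
    seed: int = 0
    test_fraction: float = 0.25
    cv_folds: int = 10


@dataclass(frozen=True)
class ModelResult:
    model_id: str                    # rf_rfe | bagged_rfe | rf_embedded
    optimal_subset_size: Optional[int]
    ranked_predictors: tuple[str, ...]
    top15: tuple[str, ...]
    accuracy: float
    sensitivity: dict[str, Optional[float]]
    accuracy_p_value: float

    @property
    def passed(self) -> bool:
        return self.accuracy >= ACCURACY_BAR and self.accuracy_p_value < ALPHA

    def rank_of(self, predictor: str) -> int:
        return self.ranked_predictors.index(predictor) + 1


@dataclass(frozen=True)
class BiomarkerReport:
    task: MLTask
    models: tuple[ModelResult, ...]
    consensus: tuple[str, ...]       # ordered by mean rank
    mean_ranks: dict[str, float]
    mean_accuracy: Optional[float]
    mean_sensitivity: dict[str, Optional[float]]
    mean_p_value: Optional[float]
    n_passing: int
    note: str = ""


# ---------------------------------------------------------------------------
# Splitting and balancing
# ---------------------------------------------------------------------------


def stratified_split(n_samples: int, labels: Sequence[str], test_fraction: float = 0.25,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test split, >= 1 test sample per class."""
    y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    singles = classes[counts < 2].tolist()
    if singles:
        raise ValidationError(f"classes with a single sample cannot be split: {singles}")
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                      random_state=seed)
    train, test = next(splitter.split(np.zeros((n_samples, 1)), y))
    return np.sort(train), np.sort(test)


def upsample_minority(labels: Sequence[str], seed: int = 0) -> np.ndarray:
    """Indices (into ``labels``) resampling every class up to the majority size.

    Original rows are always kept; the extra rows are drawn with replacement, so
    upsampled rows are exact copies.  Classes already at the majority size pass
    through unchanged.
    """
    y = np.asarray(list(labels))
    rng = np.random.default_rng(seed)
    majority = max(np.bincount(np.unique(y, return_inverse=True)[1]))
    out: list[np.ndarray] = []
    for cls in dict.fromkeys(y.tolist()):  # first-appearance class order
        idx = np.nonzero(y == cls)[0]
        extra = rng.choice(idx, size=majority - idx.size, replace=True)
        out.append(np.concatenate([idx, extra]))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def _make_estimator(kind: EstimatorKind, seed: int, max_features=None):
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, random_state=seed, n_jobs=1,
            max_features=max_features if max_features is not None else "sqrt")
    if kind == "bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=50, random_state=seed, n_jobs=1)
    raise ValidationError(f"unknown estimator kind {kind!r}")


def _importances(model) -> np.ndarray:
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_)
    # bagging: average importances over member trees
    return np.mean([t.feature_importances_ for t in model.estimators_], axis=0)


def _cv_splitter(y: np.ndarray, cv_folds: int, seed: int) -> StratifiedKFold:
    min_class = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    folds = min(cv_folds, int(min_class))
    if folds < cv_folds:
        warnings.warn(f"reducing CV folds {cv_folds} -> {folds} (smallest class)",
                      stacklevel=3)
    return StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)


# ---------------------------------------------------------------------------
# Wrapper (RFE) and embedded selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionResult:
    optimal_subset_size: Optional[int]
    ranked_predictors: tuple[str, ...]
    cv_accuracy: dict[int, float]


def rfe_wrapper(X: np.ndarray, y: Sequence[str], feature_names: Sequence[str],
                estimator: EstimatorKind = "random_forest",
                subset_grid: Sequence[int] = DEFAULT_SUBSET_GRID,
                cv_folds: int = 10, seed: int = 0) -> SelectionResult:
    """caret-style recursive feature elimination with cross-validated size choice.

    Per CV fold the estimator is fit on all features, features are ranked by
    importance, the set is cut down to each grid size in turn (refitting and
    re-ranking at every step — recursive elimination), and held-out accuracy is
    recorded per size.  The optimal size maximizes mean CV accuracy (ties to the
    smaller size).  The final ranking is the mean over folds of each feature's
    elimination rank (1 = kept longest / most important), ties broken by first
    appearance in the feature list.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y))
    names = list(feature_names)
    p = X.shape[1]
    grid = sorted({min(s, p) for s in subset_grid if s >= 1} | {p})
    if max(subset_grid) > p:
        warnings.warn(f"subset grid clamped to {p} features", stacklevel=2)
    sizes_desc = sorted(grid, reverse=True)

    skf = _cv_splitter(y, cv_folds, seed)
    acc_per_size: dict[int, list[float]] = {s: [] for s in grid}
    rank_sum = np.zeros(p)
    n_folds = 0
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        n_folds += 1
        current = np.arange(p)
        fold_rank = np.empty(p, dtype=float)
        imp_order: np.ndarray | None = None
        for size in sizes_desc:
            if size < current.size:
                # eliminate down to `size`, recording ranks of the dropped tail
                keep = imp_order[:size]
                dropped = imp_order[size:]
                for r, j in enumerate(dropped):
                    fold_rank[current[j]] = size + 1 + r
                current = current[keep]
            est = _make_estimator(estimator, seed + 101 * fold)
            est.fit(X[np.ix_(tr, current)], y[tr])
            acc_per_size[size].append(
                float(np.mean(est.predict(X[np.ix_(te, current)]) == y[te])))
            imp = _importances(est)
            imp_order = np.argsort(-imp, kind="stable")
        for r, j in enumerate(imp_order):
            fold_rank[current[j]] = r + 1
        rank_sum += fold_rank

    mean_acc = {s: float(np.mean(v)) for s, v in acc_per_size.items()}
    optimal = min(grid, key=lambda s: (-mean_acc[s], s))
    mean_rank = rank_sum / n_folds
    order = np.lexsort((np.arange(p), mean_rank))  # ties -> first appearance
    ranked = tuple(names[j] for j in order)
    return SelectionResult(optimal_subset_size=optimal, ranked_predictors=ranked,
                           cv_accuracy=mean_acc)


def embedded_rf(X: np.ndarray, y: Sequence[str], feature_names: Sequence[str],
                tune_grid_length: int = 5, cv_folds: int = 10,
                seed: int = 0) -> SelectionResult:
    """Tuned random forest ranked by impurity importance (embedded method).

    The features-per-split parameter is tuned over ``tune_grid_length`` values
    spanning sqrt(p)..p by CV accuracy (ties to the smaller value); the tuned
    forest, refit on the full training set, ranks every predictor.  Duplicate
    columns split importance between themselves; the ranking stays a total
    order via the first-appearance tie-break.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y))
    p = X.shape[1]
    lo = max(1, int(round(np.sqrt(p))))
    grid = sorted({int(v) for v in np.linspace(lo, p, tune_grid_length).round()})
    skf = _cv_splitter(y, cv_folds, seed)
    splits = list(skf.split(X, y))
    mean_acc: dict[int, float] = {}
    for mf in grid:
        accs = []
        for fold, (tr, te) in enumerate(splits):
            est = _make_estimator("random_forest", seed + 101 * fold, max_features=mf)
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[te]) == y[te])))
        mean_acc[mf] = float(np.mean(accs))
    best = min(grid, key=lambda v: (-mean_acc[v], v))
    final = _make_estimator("random_forest", seed, max_features=best)
    final.fit(X, y)
    order = np.argsort(-_importances(final), kind="stable")
    ranked = tuple(feature_names[j] for j in order)
    return SelectionResult(optimal_subset_size=None, ranked_predictors=ranked,
                           cv_accuracy=mean_acc)


# ---------------------------------------------------------------------------
# Final models and consensus
# ---------------------------------------------------------------------------


def finalize_model(X_train: np.ndarray, y_train: Sequence[str],
                   X_test: np.ndarray, y_test: Sequence[str],
                   predictors: Sequence[str], feature_names: Sequence[str],
                   estimator: EstimatorKind = "random_forest", seed: int = 0,
                   ) -> tuple[float, dict[str, Optional[float]], float]:
    """Refit on the selected predictors and score the untouched test set.

    Returns ``(accuracy, per-class sensitivity, accuracy p-value)``.  The
    p-value is a one-sided exact binomial test of the observed number of correct
    test predictions against the no-information rate (the largest class
    prevalence in the test set).  Classes absent from the test set get
    sensitivity ``None``.
    """
    pos = {f: j for j, f in enumerate(feature_names)}
    missing = [f for f in predictors if f not in pos]
    if missing:
        raise ValidationError(f"predictors not in feature table: {missing}")
    cols = [pos[f] for f in predictors]
    y_train = np.asarray(list(y_train))
    y_test = np.asarray(list(y_test))
    est = _make_estimator(estimator, seed)
    est.fit(np.asarray(X_train, dtype=float)[:, cols], y_train)
    pred = est.predict(np.asarray(X_test, dtype=float)[:, cols])
    correct = int((pred == y_test).sum())
    n = len(y_test)
    accuracy = correct / n
    classes, counts = np.unique(y_test, return_counts=True)
    nir = counts.max() / n
    p_value = float(binomtest(correct, n, nir, alternative="greater").pvalue)
    sensitivity: dict[str, Optional[float]] = {}
    for cls in sorted(set(y_train) | set(y_test)):
        mask = y_test == cls
        sensitivity[cls] = float((pred[mask] == cls).mean()) if mask.any() else None
    return accuracy, sensitivity, p_value


def consensus_biomarkers(task: MLTask, models: Sequence[ModelResult]) -> BiomarkerReport:
    """Intersect the top-15 sets of the passing models, ordered by mean rank.

    Models with accuracy < 0.80 or p >= 0.05 are excluded first.  Aggregated
    metrics are plain arithmetic means over the surviving models.
    """
    if not models:
        raise ValidationError("consensus needs at least one model result")
    passing = [m for m in models if m.passed]
    note = ""
    if len(passing) < 3:
        note = (f"only {len(passing)} of {len(models)} models passed the "
                f"accuracy >= {ACCURACY_BAR} and p < {ALPHA} bar")
    if not passing:
        return BiomarkerReport(task=task, models=tuple(models), consensus=(),
                               mean_ranks={}, mean_accuracy=None,
                               mean_sensitivity={}, mean_p_value=None,
                               n_passing=0, note=note or "no passing model")
    shared = set(passing[0].top15)
    for m in passing[1:]:
        shared &= set(m.top15)
    mean_ranks = {f: float(np.mean([m.rank_of(f) for m in passing])) for f in shared}
    consensus = tuple(sorted(shared, key=lambda f: (mean_ranks[f], f)))
    all_classes = sorted({c for m in passing for c in m.sensitivity})
    mean_sens: dict[str, Optional[float]] = {}
    for cls in all_classes:
        vals = [m.sensitivity.get(cls) for m in passing]
        known = [v for v in vals if v is not None]
        mean_sens[cls] = float(np.mean(known)) if known else None
    return BiomarkerReport(
        task=task, models=tuple(models), consensus=consensus, mean_ranks=mean_ranks,
        mean_accuracy=float(np.mean([m.accuracy for m in passing])),
        mean_sensitivity=mean_sens,
        mean_p_value=float(np.mean([m.accuracy_p_value for m in passing])),
        n_passing=len(passing), note=note)


# ---------------------------------------------------------------------------
# Task runner
# ---------------------------------------------------------------------------


def run_task(matrix: EmissionMatrix, annotations: dict[str, SpeciesAnnotation],
             task: MLTask, subset_grid: Sequence[int] = DEFAULT_SUBSET_GRID,
             ) -> BiomarkerReport:
    """Run the full three-model procedure for one task on one platform table."""
    all_labels = labels_for_samples(matrix, annotations, task.label)
    rows = [i for i, v in enumerate(all_labels) if v is not None]
    y = np.asarray([all_labels[i] for i in rows])
    X = matrix.values[rows]
    names = list(matrix.compound_ids)

    train, test = stratified_split(len(rows), y, task.test_fraction, task.seed)
    up = upsample_minority(y[train], seed=task.seed + 1)
    Xtr, ytr = X[train][up], y[train][up]
    Xte, yte = X[test], y[test]

    model_specs = (("rf_rfe", "random_forest", True),
                   ("bagged_rfe", "bagged_trees", True),
                   ("rf_embedded", "random_forest", False))
    results: list[ModelResult] = []
    for i, (model_id, est_kind, is_wrapper) in enumerate(model_specs):
        mseed = task.seed + 7919 * (i + 1)
        if is_wrapper:
            sel = rfe_wrapper(Xtr, ytr, names, estimator=est_kind,
                              subset_grid=subset_grid, cv_folds=task.cv_folds,
                              seed=mseed)
        else:
            sel = embedded_rf(Xtr, ytr, names, cv_folds=task.cv_folds, seed=mseed)
        top15 = sel.ranked_predictors[:min(15, len(names))]
        acc, sens, pval = finalize_model(Xtr, ytr, Xte, yte, top15, names,
                                         estimator=est_kind, seed=mseed)
        results.append(ModelResult(
            model_id=model_id, optimal_subset_size=sel.optimal_subset_size,
            ranked_predictors=sel.ranked_predictors, top15=top15,
            accuracy=acc, sensitivity=sens, accuracy_p_value=pval))
    return consensus_biomarkers(task, results)


def zscore_profiles(matrix: EmissionMatrix, predictors: Sequence[str]) -> "np.ndarray":
    """Species-mean profiles of selected biomarkers, z-scored per compound
    (zero mean, unit sd) for visualization-style reporting."""
    means = matrix.species_means()[list(predictors)].to_numpy()
    sd = means.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (means - means.mean(axis=0)) / sd


def unique_biomarker_counts(reports: Sequence[BiomarkerReport]) -> dict[str, dict[str, int]]:
    """Consensus-set sizes per task, with and without cross-task deduplication."""
    raw = {f"{r.task.label}:{r.task.platform}": len(r.consensus) for r in reports}
    seen: set[str] = set()
    dedup: dict[str, int] = {}
    for r in reports:
        fresh = [c for c in r.consensus if c not in seen]
        seen.update(fresh)
        dedup[f"{r.task.label}:{r.task.platform}"] = len(fresh)
    return {"per_task": raw, "cross_task_deduplicated": dedup}
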