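"""Model training and evaluation for synergy prediction.

Exposes statsmodels-style modelling objects: :class:`SynergyRegression`
and :class:`SynergyClassification` are built from a feature matrix, a
target vector and a :class:`DataSplit`; ``fit()`` performs an exhaustive
grid search maximizing mean 5-fold cross-validated Pearson r (regression)
or positive-class F1 (classification) on the training folds only, refits
at the best grid point and returns a Results object carrying the chosen
hyperparameters, the CV table, test-set predictions, an
:class:`EvaluationReport` and a ``summary()`` table.

Model families: elastic net, ridge, RBF kernel ridge, random forest and
extremely randomized trees for regression; logistic regression, SVM and
the two forests for classification. Hyperparameter grids span
exponentially increasing regularization values (1e-4..1 or 1e-4..100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, LogisticRegression, Ridge
from sklearn.metrics import f1_score as _sk_f1
from sklearn.svm import SVC

__all__ = [
    "DataSplit",
    "ModelSpec",
    "TrainedModel",
    "EvaluationReport",
    "split_data",
    "grid_search_train",
    "pearson_r",
    "subset_eval_by_prediction",
    "classify_by_threshold",
    "f1_score",
    "rank_best_combination",
    "SynergyRegression",
    "SynergyClassification",
]

REGRESSION_FAMILIES = ("elastic_net", "ridge", "kernel_ridge_rbf",
                       "random_forest", "extra_trees")
CLASSIFICATION_FAMILIES = ("logistic", "svm", "random_forest", "extra_trees")

#: Default hyperparameter grids per family (exponential regularization
#: ladders from 1e-4 up to 1 or 100; forest grids over size/feature
#: fraction/leaf size).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "elastic_net": {"alpha": list(np.logspace(-4, 0, 5)),
                    "l1_ratio": [0.1, 0.5, 0.9]},
    "ridge": {"alpha": list(np.logspace(-4, 2, 7))},
    "kernel_ridge_rbf": {"alpha": list(np.logspace(-4, 0, 5)),
                         "gamma": list(np.logspace(-4, 1, 6))},
    "random_forest": {"n_estimators": [100, 500],
                      "max_features": ["sqrt", 0.3, 1.0],
                      "min_samples_leaf": [1, 5]},
    "extra_trees": {"n_estimators": [100, 500],
                    "max_features": ["sqrt", 0.3, 1.0],
                    "min_samples_leaf": [1, 5]},
    "logistic": {"C": list(np.logspace(-4, 2, 7))},
    "svm": {"C": list(np.logspace(-4, 2, 7))},
}


@dataclass(frozen=True)
class DataSplit:
    """An 80:20 train/test split with 5 CV folds inside the training set."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: tuple[np.ndarray, ...]
    seed: int

    def __post_init__(self) -> None:
        train = set(self.train_idx.tolist())
        test = set(self.test_idx.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")
        fold_union: set[int] = set()
        for f in self.folds:
            fset = set(f.tolist())
            if fold_union & fset:
                raise ValueError("CV folds overlap")
            fold_union |= fset
        if fold_union != train:
            raise ValueError("CV folds must partition the training set")


def split_data(n_samples: int, seed: int, test_fraction: float = 0.2,
               n_folds: int = 5) -> DataSplit:
    """Uniform random split; reproducible for a fixed seed."""
    if n_samples < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    n_test = int(round(n_samples * test_fraction))
    test_idx = np.sort(order[:n_test])
    train_idx = np.sort(order[n_test:])
    shuffled_train = rng.permutation(train_idx)
    folds = tuple(np.sort(f) for f in np.array_split(shuffled_train, n_folds))
    return DataSplit(train_idx=train_idx, test_idx=test_idx, folds=folds, seed=seed)


@dataclass(frozen=True)
class ModelSpec:
    """A model family, its task and its hyperparameter grid."""

    family: str
    task: str = "regression"  # or "classification"
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        allowed = REGRESSION_FAMILIES if self.task == "regression" else CLASSIFICATION_FAMILIES
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.family not in allowed:
            raise ValueError(f"family {self.family!r} not available for {self.task}")

    @property
    def effective_grid(self) -> dict[str, list]:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]

    def grid_points(self) -> list[dict]:
        grid = self.effective_grid
        keys = list(grid)
        return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]

    def make_estimator(self, params: dict):
        fam, seed = self.family, self.seed
        if self.task == "regression":
            if fam == "elastic_net":
                return ElasticNet(max_iter=10000, **params)
            if fam == "ridge":
                return Ridge(**params)
            if fam == "kernel_ridge_rbf":
                return KernelRidge(kernel="rbf", **params)
            if fam == "random_forest":
                return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
            return ExtraTreesRegressor(random_state=seed, n_jobs=1, **params)
        if fam == "logistic":
            return LogisticRegression(max_iter=5000, **params)
        if fam == "svm":
            return SVC(**params)
        if fam == "random_forest":
            return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)


@dataclass
class TrainedModel:
    """Grid-search outcome: chosen point, its CV score, the refitted estimator."""

    spec: ModelSpec
    params: dict
    cv_score: float
    estimator: object
    cv_table: pd.DataFrame

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


# ---------------------------------------------------------------------------
# metrics

def pearson_r(y_true, y_pred) -> float:
    """Product-moment correlation; errors on constant or short input."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 3:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("pearson_r is undefined for constant input")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def subset_eval_by_prediction(y_true, y_pred, cutoff: float) -> tuple[float, int]:
    """Pearson r restricted to confidently predicted samples.

    Keeps samples with |y_pred| > cutoff (cutoff 0 keeps everything) and
    returns (r, subset size); errors when fewer than 3 samples remain.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mask = np.ones(len(y_pred), bool) if cutoff == 0 else np.abs(y_pred) > cutoff
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} samples have |prediction| > {cutoff}")
    return pearson_r(y_true[mask], y_pred[mask]), n


def classify_by_threshold(scores, thr: float) -> np.ndarray:
    """Drop-zone labelling: +1 above +thr, -1 below -thr, 0 = dropped."""
    if thr < 0:
        raise ValueError("threshold must be non-negative")
    scores = np.asarray(scores, dtype=float)
    labels = np.zeros(len(scores), dtype=np.int8)
    labels[scores > thr] = 1
    labels[scores < -thr] = -1
    return labels


def f1_score(labels_true, labels_pred) -> float:
    """Positive-class F1 = 2*precision*recall / (precision + recall)."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if not np.any(labels_true == 1):
        raise ValueError("f1_score needs at least one true positive-class member")
    if not np.any(labels_pred == 1):
        warnings.warn("no predicted positives; F1 defined as 0", stacklevel=2)
        return 0.0
    return float(_sk_f1(labels_true, labels_pred, pos_label=1, zero_division=0))


def rank_best_combination(pairs, y_true, y_pred) -> tuple[tuple[str, str], int, int]:
    """Predicted rank of the observed-best combination for one cell line.

    Candidates are ranked by predicted score descending; prediction ties
    are broken pessimistically (the observed-best pair takes the worst
    rank among its ties). Returns (best observed pair, 1-based rank, n).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_true)
    if n < 2 or len(y_pred) != n or len(pairs) != n:
        raise ValueError("need >= 2 aligned candidate combinations")
    best = int(np.argmax(y_true))
    rank = int(np.sum(y_pred >= y_pred[best]))
    return tuple(pairs[best]), rank, n


# ---------------------------------------------------------------------------
# grid search

def _cv_metric(task: str):
    return pearson_r if task == "regression" else f1_score


def grid_search_train(spec: ModelSpec, split: DataSplit, X: np.ndarray,
                      y: np.ndarray) -> TrainedModel:
    """Exhaustive grid search over ``spec``'s grid on the CV folds.

    Each grid point is scored by the mean over folds of the task metric
    (Pearson r / F1) computed on the held-out fold; ties keep the first
    point in grid order. The winner is refitted on the full training set.
    Test rows never enter any fold fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X rows must align with y")
    if spec.task == "regression" and np.std(y[split.train_idx].astype(float)) == 0:
        raise ValueError("constant target: nothing to fit")
    metric = _cv_metric(spec.task)

    rows = []
    best_score, best_params = -np.inf, None
    for params in spec.grid_points():
        fold_scores = []
        for fold in split.folds:
            fit_idx = np.setdiff1d(split.train_idx, fold)
            if spec.task == "classification" and len(np.unique(y[fit_idx])) < 2:
                continue  # degenerate fold (single class); skip
            est = spec.make_estimator(params)
            est.fit(X[fit_idx], y[fit_idx])
            try:
                fold_scores.append(metric(y[fold], est.predict(X[fold])))
            except ValueError:
                continue  # metric undefined on this held-out fold
        if not fold_scores:
            warnings.warn(f"no scorable CV fold for grid point {params}",
                          stacklevel=2)
            continue
        score = float(np.mean(fold_scores))
        rows.append({**params, "cv_score": score})
        if score > best_score:
            best_score, best_params = score, params
    if best_params is None:
        raise ValueError("no grid point could be scored on the CV folds")
    estimator = spec.make_estimator(best_params)
    estimator.fit(X[split.train_idx], y[split.train_idx])
    return TrainedModel(spec=spec, params=best_params, cv_score=best_score,
                        estimator=estimator, cv_table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# evaluation report

@dataclass
class EvaluationReport:
    """Test-set evaluation: overall/per-cell-line/subset Pearson r,
    thresholded F1, and per-cell-line rank of the observed-best pair."""

    pearson_overall: float | None = None
    pearson_by_cell_line: dict[str, float] = field(default_factory=dict)
    pearson_by_pred_magnitude: dict[float, tuple[float, int]] = field(default_factory=dict)
    f1_by_threshold: dict[float, float] = field(default_factory=dict)
    ranking: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pearson_overall": self.pearson_overall,
            "pearson_by_cell_line": self.pearson_by_cell_line,
            "pearson_by_pred_magnitude": {
                str(k): {"r": v[0], "n": v[1]}
                for k, v in self.pearson_by_pred_magnitude.items()
            },
            "f1_by_threshold": {str(k): v for k, v in self.f1_by_threshold.items()},
            "ranking": self.ranking,
        }


def evaluate_regression(meta: pd.DataFrame, y_true, y_pred,
                        magnitude_cutoffs=(10.0, 15.0, 20.0)) -> EvaluationReport:
    """Full regression report on aligned test-set rows.

    ``meta`` carries cell_line/drug_a/drug_b per row. Per-cell-line r is
    reported only for cell lines with >= 3 test samples; ranking only
    where a cell line has >= 2 candidate combinations.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rep = EvaluationReport(pearson_overall=pearson_r(y_true, y_pred))
    for cutoff in magnitude_cutoffs:
        try:
            rep.pearson_by_pred_magnitude[cutoff] = subset_eval_by_prediction(
                y_true, y_pred, cutoff)
        except ValueError:
            pass
    meta = meta.reset_index(drop=True)
    for cell, idx in meta.groupby("cell_line").groups.items():
        idx = np.asarray(idx)
        if len(idx) >= 3:
            try:
                rep.pearson_by_cell_line[cell] = pearson_r(y_true[idx], y_pred[idx])
            except ValueError:
                pass
        if len(idx) >= 2:
            pairs = list(zip(meta.loc[idx, "drug_a"], meta.loc[idx, "drug_b"]))
            pair, rank, n = rank_best_combination(pairs, y_true[idx], y_pred[idx])
            rep.ranking[cell] = {"best_pair": list(pair), "predicted_rank": rank, "n": n}
    return rep


# ---------------------------------------------------------------------------
# Model / Results objects

class SynergyRegression:
    """Synergy-score regression model over a featurized sample table.

    Parameters
    ----------
    X : (n, p) feature matrix aligned with ``meta`` and ``y``.
    y : measured synergy scores.
    meta : DataFrame with cell_line / drug_a / drug_b per row.
    split : the train/test + CV fold layout.
    family : model family name.
    grid : optional grid override (defaults to the family grid).
    """

    def __init__(self, X, y, meta: pd.DataFrame, split: DataSplit,
                 family: str = "extra_trees", grid: dict | None = None,
                 seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.meta = meta.reset_index(drop=True)
        self.split = split
        self.spec = ModelSpec(family=family, task="regression", grid=grid, seed=seed)

    def fit(self) -> "SynergyRegressionResults":
        trained = grid_search_train(self.spec, self.split, self.X, self.y)
        return SynergyRegressionResults(self, trained)


class SynergyRegressionResults:
    """Fitted synergy regression: predictions, evaluation and summary."""

    def __init__(self, model: SynergyRegression, trained: TrainedModel):
        self.model = model
        self.trained = trained
        te = model.split.test_idx
        self.y_pred_test = trained.predict(model.X[te])
        self.y_true_test = model.y[te]
        self.meta_test = model.meta.iloc[te].reset_index(drop=True)

    @property
    def params(self) -> dict:
        return self.trained.params

    @property
    def cv_score(self) -> float:
        return self.trained.cv_score

    def predict(self, X) -> np.ndarray:
        return self.trained.predict(np.asarray(X, dtype=float))

    def evaluate(self, magnitude_cutoffs=(10.0, 15.0, 20.0)) -> EvaluationReport:
        return evaluate_regression(self.meta_test, self.y_true_test,
                                   self.y_pred_test, magnitude_cutoffs)

    def summary(self) -> str:
        rep = self.evaluate()
        lines = [
            "Synergy regression results",
            "==========================",
            f"family:          {self.trained.spec.family}",
            f"hyperparameters: {self.params}",
            f"CV Pearson r:    {self.cv_score:.4f}",
            f"test Pearson r:  {rep.pearson_overall:.4f}",
            f"test samples:    {len(self.y_true_test)}",
            "",
            "Pearson r by |prediction| cutoff:",
        ]
        for cutoff, (r, n) in sorted(rep.pearson_by_pred_magnitude.items()):
            lines.append(f"  |pred| > {cutoff:>4.0f}: r = {r:.4f}  (n = {n})")
        if rep.ranking:
            in_top1 = sum(v["predicted_rank"] == 1 for v in rep.ranking.values())
            in_top10 = sum(v["predicted_rank"] <= 10 for v in rep.ranking.values())
            lines += ["", f"best combination ranked 1st: {in_top1}/{len(rep.ranking)} cell lines",
                      f"best combination in top 10:  {in_top10}/{len(rep.ranking)} cell lines"]
        return "\n".join(lines)


class SynergyClassification:
    """Synergism-vs-antagonism classifier at a drop-zone threshold.

    Samples with |synergy| <= threshold are dropped before both training
    and evaluation; the classifier is fitted on retained training-fold
    samples only, with the CV folds restricted accordingly.
    """

    def __init__(self, X, y_scores, meta: pd.DataFrame, split: DataSplit,
                 threshold: float, family: str = "extra_trees",
                 grid: dict | None = None, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y_scores = np.asarray(y_scores, dtype=float)
        self.meta = meta.reset_index(drop=True)
        self.split = split
        self.threshold = float(threshold)
        self.spec = ModelSpec(family=family, task="classification", grid=grid, seed=seed)

    def fit(self) -> "SynergyClassificationResults":
        labels = classify_by_threshold(self.y_scores, self.threshold)
        retained = np.flatnonzero(labels != 0)
        keep = np.zeros(len(labels), dtype=bool)
        keep[retained] = True
        train_idx = self.split.train_idx[keep[self.split.train_idx]]
        test_idx = self.split.test_idx[keep[self.split.test_idx]]
        folds = tuple(f[keep[f]] for f in self.split.folds)
        folds = tuple(f for f in folds if len(f))
        sub_split = DataSplit(train_idx=train_idx, test_idx=test_idx,
                              folds=folds, seed=self.split.seed)
        if len(np.unique(labels[train_idx])) < 2:
            # the drop zone removed one class entirely from the training
            # fold; fall back to a constant majority-class predictor
            warnings.warn(
                f"single-class training set at threshold {self.threshold:g}; "
                "using a constant majority-class classifier", stacklevel=2)
            from sklearn.dummy import DummyClassifier
            est = DummyClassifier(strategy="prior")
            est.fit(self.X[train_idx], labels[train_idx])
            trained = TrainedModel(spec=self.spec, params={}, cv_score=float("nan"),
                                   estimator=est, cv_table=pd.DataFrame())
        else:
            trained = grid_search_train(self.spec, sub_split, self.X, labels)
        return SynergyClassificationResults(self, trained, labels, sub_split)


class SynergyClassificationResults:
    def __init__(self, model: SynergyClassification, trained: TrainedModel,
                 labels: np.ndarray, sub_split: DataSplit):
        self.model = model
        self.trained = trained
        self.labels = labels
        self.sub_split = sub_split
        te = sub_split.test_idx
        self.y_pred_test = trained.predict(model.X[te])
        self.y_true_test = labels[te]

    @property
    def params(self) -> dict:
        return self.trained.params

    def f1_test(self) -> float:
        return f1_score(self.y_true_test, self.y_pred_test)

    def summary(self) -> str:
        return "\n".join([
            "Synergy classification results",
            "==============================",
            f"family:          {self.trained.spec.family}",
            f"threshold:       +/-{self.model.threshold:g}",
            f"hyperparameters: {self.params}",
            f"CV F1:           {self.trained.cv_score:.4f}",
            f"test F1:         {self.f1_test():.4f}",
            f"retained test n: {len(self.y_true_test)}",
        ])
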