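"""Multiclass decomposition schemes and imbalance-aware bagging.

Three ways to turn a probabilistic binary learner into a multiclass
classifier:

* **OVA** — one binary task per class (class vs pooled rest);
* **OVO** — one task per unordered class pair, m(m-1)/2 in total, combined
  by summing each pair classifier's class probabilities and taking the
  argmax;
* **Bagged OVO** — the imbalance remedy: the majority class (MCI in the
  reference cohort, close to half the data) is split into two disjoint
  near-halves; two OVO ensembles are trained, each on all minority rows
  plus one half of the majority; their per-class summed probabilities are
  averaged before the argmax.  Each bag therefore sees a flatter class
  distribution than the raw training set while no majority row is wasted.

Evaluation follows a 5x4 nested cross-validation: the inner 4-fold loop
selects hyperparameters by mean balanced accuracy, the outer 5-fold loop
reports held-out balanced accuracy and weighted F1, summarised by mean,
max and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split

from ._common import ConfigurationError, ContractError

__all__ = [
    "BinaryTask",
    "BaggedOvoModel",
    "OvoModel",
    "OvaModel",
    "PairModel",
    "CVResult",
    "decompose_ovo",
    "decompose_ova",
    "split_majority",
    "fit_ova",
    "fit_ovo",
    "fit_bagged_ovo",
    "fit_pair_model",
    "predict_vote",
    "balanced_accuracy",
    "weighted_f1",
    "nested_cv",
    "train_test_split_eval",
    "compare_classifiers_ttest",
]


# ---------------------------------------------------------------------------
# binary task decomposition


@dataclass(frozen=True)
class BinaryTask:
    """One binary subproblem: ``positive`` vs ``negative`` (or the rest)."""

    positive: str
    negative: str | None  # None marks a one-vs-rest task
    rows: np.ndarray | None = None  # row indices the task trains on

    @property
    def is_ova(self) -> bool:
        return self.negative is None


def _classes(classes_or_labels) -> list[str]:
    return sorted(str(c) for c in np.unique(np.asarray(list(classes_or_labels))))


def decompose_ovo(classes, labels: Sequence | None = None) -> list[BinaryTask]:
    """All unordered class pairs — m(m-1)/2 tasks.

    If ``labels`` is given, each task records the row indices of its two
    classes; an OVO classifier trains only on those rows.
    """
    cls = _classes(classes)
    if len(cls) < 2:
        raise ContractError(f"need >= 2 classes, got {cls}")
    labels = None if labels is None else np.asarray(labels)
    tasks = []
    for i, a in enumerate(cls):
        for b in cls[i + 1 :]:
            rows = None
            if labels is not None:
                rows = np.flatnonzero((labels == a) | (labels == b))
            tasks.append(BinaryTask(positive=b, negative=a, rows=rows))
    return tasks


def decompose_ova(classes, labels: Sequence | None = None) -> list[BinaryTask]:
    """One-vs-rest tasks, one per class; every task uses all rows."""
    cls = _classes(classes)
    if len(cls) < 2:
        raise ContractError(f"need >= 2 classes, got {cls}")
    rows = None if labels is None else np.arange(len(labels))
    return [BinaryTask(positive=c, negative=None, rows=rows) for c in cls]


def split_majority(
    labels: Sequence, majority: str, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two row-index sets, each = all minority rows + half the majority.

    The majority rows are randomly partitioned into two disjoint halves
    (sizes differing by at most 1); both returned sets contain every
    non-majority row.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    maj_rows = np.flatnonzero(labels == majority)
    if maj_rows.size == 0:
        raise ContractError(f"majority class {majority!r} absent from labels")
    rest = np.flatnonzero(labels != majority)
    perm = np.random.default_rng(seed).permutation(maj_rows)
    half = (perm.size + 1) // 2
    first = np.sort(np.concatenate([rest, perm[:half]]))
    second = np.sort(np.concatenate([rest, perm[half:]]))
    return first, second


# ---------------------------------------------------------------------------
# base-learner handling


def _probabilistic(estimator):
    """Clone ``estimator``, wrapping margin-only learners with Platt scaling."""
    est = clone(estimator)
    if hasattr(est, "predict_proba"):
        # SVC exposes predict_proba only with probability=True; honour that
        if getattr(est, "probability", True):
            return est
    if hasattr(est, "decision_function"):
        return CalibratedClassifierCV(est, method="sigmoid", cv=3)
    raise ConfigurationError(
        "base learner must expose predict_proba or decision_function "
        f"(got {type(estimator).__name__}); probability calibration required"
    )


def _fit_binary(estimator, X, y):
    est = _probabilistic(estimator)
    est.fit(X, y)
    return est


def _proba_for(est, X, cls: str) -> np.ndarray:
    classes = [str(c) for c in est.classes_]
    return est.predict_proba(X)[:, classes.index(cls)]


# ---------------------------------------------------------------------------
# fitted multiclass models


@dataclass
class OvoModel:
    """Plain one-vs-one ensemble with probability-sum voting."""

    classes_: list[str]
    tasks_: list[BinaryTask]
    estimators_: list  # aligned with tasks_

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X)
        scores = np.zeros((X.shape[0], len(self.classes_)))
        for task, est in zip(self.tasks_, self.estimators_):
            for cls in (task.positive, task.negative):
                scores[:, self.classes_.index(cls)] += _proba_for(est, X, cls)
        return scores

    def predict(self, X) -> np.ndarray:
        # argmax takes the first maximum: alphabetical tie-break via sorted classes_
        idx = np.argmax(self.predict_scores(np.asarray(X)), axis=1)
        return np.asarray(self.classes_)[idx]


@dataclass
class OvaModel:
    """One-vs-rest ensemble; predicts the class with top positive probability."""

    classes_: list[str]
    estimators_: list

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X)
        return np.column_stack(
            [_proba_for(est, X, cls) for cls, est in zip(self.classes_, self.estimators_)]
        )

    def predict(self, X) -> np.ndarray:
        idx = np.argmax(self.predict_scores(np.asarray(X)), axis=1)
        return np.asarray(self.classes_)[idx]


@dataclass
class BaggedOvoModel:
    """Two OVO ensembles over disjoint majority halves, vote-averaged."""

    classes_: list[str]
    majority_: str
    bags_: list[OvoModel]  # two bags
    seed: int = 0

    def predict_scores(self, X) -> np.ndarray:
        X = np.asarray(X)
        return np.mean([bag.predict_scores(X) for bag in self.bags_], axis=0)

    def predict(self, X) -> np.ndarray:
        idx = np.argmax(self.predict_scores(np.asarray(X)), axis=1)
        return np.asarray(self.classes_)[idx]

    @property
    def n_binary_classifiers(self) -> int:
        return sum(len(bag.estimators_) for bag in self.bags_)


def fit_ova(X, y, base_learner, seed: int = 0) -> OvaModel:
    X, y = np.asarray(X), np.asarray(y).astype(str)
    tasks = decompose_ova(y, labels=y)
    ests = []
    for task in tasks:
        target = np.where(y == task.positive, task.positive, f"rest_{task.positive}")
        ests.append(_fit_binary(base_learner, X, target))
    return OvaModel(classes_=[t.positive for t in tasks], estimators_=ests)


def fit_ovo(X, y, base_learner, seed: int = 0) -> OvoModel:
    X, y = np.asarray(X), np.asarray(y).astype(str)
    tasks = decompose_ovo(y, labels=y)
    ests = [_fit_binary(base_learner, X[t.rows], y[t.rows]) for t in tasks]
    return OvoModel(classes_=_classes(y), tasks_=tasks, estimators_=ests)


def fit_bagged_ovo(X, y, base_learner, seed: int = 0) -> BaggedOvoModel:
    """Fit the two-bag OVO ensemble: 2 x m(m-1)/2 binary classifiers."""
    X, y = np.asarray(X), np.asarray(y).astype(str)
    cls, counts = np.unique(y, return_counts=True)
    if cls.size < 2:
        raise ContractError("need >= 2 classes to fit")
    majority = str(cls[np.argmax(counts)])
    bags = []
    for rows in split_majority(y, majority, seed=seed):
        bags.append(fit_ovo(X[rows], y[rows], base_learner, seed=seed))
    return BaggedOvoModel(
        classes_=_classes(y), majority_=majority, bags_=bags, seed=seed
    )


def predict_vote(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and the per-class score matrix behind them."""
    return model.predict(X), model.predict_scores(X)


@dataclass
class PairModel:
    """A single binary pair classifier exposed as a positive-probability model.

    ``predict_proba`` returns (n, 2) with column 1 = the configured positive
    class — by default the alphabetically later label of the pair, so for
    the (MCI, AD) pair set ``positive="AD"`` explicitly to match the
    disease-positive convention.
    """

    pair: tuple[str, str]
    positive: str
    estimator_: object

    def predict_proba(self, X) -> np.ndarray:
        p = _proba_for(self.estimator_, np.asarray(X), self.positive)
        return np.column_stack([1.0 - p, p])


def fit_pair_model(
    X, y, pair: tuple[str, str], base_learner, positive: str | None = None
) -> PairModel:
    """Fit one OVO pair's binary classifier on that pair's rows only."""
    a, b = sorted(str(p) for p in pair)
    if positive is None:
        positive = b
    if positive not in (a, b):
        raise ContractError(f"positive={positive!r} not in pair {(a, b)}")
    y = np.asarray(y).astype(str)
    rows = np.flatnonzero((y == a) | (y == b))
    if rows.size == 0:
        raise ContractError(f"no rows for pair {(a, b)}")
    est = _fit_binary(base_learner, np.asarray(X)[rows], y[rows])
    return PairModel(pair=(a, b), positive=positive, estimator_=est)


# ---------------------------------------------------------------------------
# metrics


def _check_labels(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ContractError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size == 0:
        raise ContractError("empty label vectors")
    return y_true, y_pred


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recalls."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    return float(_skm.balanced_accuracy_score(y_true, y_pred))


def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 scores."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    return float(_skm.f1_score(y_true, y_pred, average="weighted", zero_division=0))


def compare_classifiers_ttest(metric_a, metric_b) -> tuple[float, float]:
    """Paired two-sided t-test on fold-wise metric differences.

    Identical vectors (zero-variance, zero-mean differences) return the
    degenerate (t=0, p=1) rather than NaN.
    """
    a, b = np.asarray(metric_a, float), np.asarray(metric_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("per-fold metric vectors must be 1-D and equal length")
    d = a - b
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return (np.inf if d.mean() > 0 else -np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# evaluation protocols


_FITTERS = {"ova": fit_ova, "ovo": fit_ovo, "bagged-ovo": fit_bagged_ovo}


def _fit_scheme(scheme, X, y, base_learner, params, seed):
    est = clone(base_learner)
    est.set_params(**params)
    return _FITTERS[scheme](X, y, est, seed=seed)


@dataclass
class CVResult:
    """Nested-CV outcome: one record per outer fold plus summary stats."""

    folds: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @staticmethod
    def summarise(folds: list[dict]) -> dict:
        out = {}
        for m in ("balanced_accuracy", "weighted_f1"):
            vals = np.array([f[m] for f in folds], float)
            out[m] = {
                "mean": float(vals.mean()),
                "max": float(vals.max()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }
        return out


def nested_cv(
    X,
    y,
    base_learner,
    hyperparameter_grid: Mapping | Sequence[Mapping] | None = None,
    outer: int = 5,
    inner: int = 4,
    seed: int = 0,
    scheme: str = "bagged-ovo",
) -> CVResult:
    """Stratified 5x4 nested cross-validation of a decomposition scheme.

    The inner loop picks the grid point with the highest mean inner
    balanced accuracy; the winner is refitted on the outer-train split and
    scored on the outer-test split.  A single-point grid degenerates to
    plain outer CV.
    """
    X, y = np.asarray(X), np.asarray(y).astype(str)
    grid = list(ParameterGrid(hyperparameter_grid or {}))
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < outer:
        raise ContractError(
            f"smallest class ({counts.min()} rows) cannot be stratified "
            f"into {outer} outer folds"
        )
    outer_cv = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
    folds = []
    for k, (tr, te) in enumerate(outer_cv.split(X, y)):
        if len(grid) > 1:
            inner_cv = StratifiedKFold(
                n_splits=inner, shuffle=True, random_state=seed + 1
            )
            inner_scores = np.zeros(len(grid))
            for itr, ite in inner_cv.split(X[tr], y[tr]):
                for g, params in enumerate(grid):
                    mdl = _fit_scheme(scheme, X[tr][itr], y[tr][itr],
                                      base_learner, params, seed)
                    inner_scores[g] += balanced_accuracy(
                        y[tr][ite], mdl.predict(X[tr][ite])
                    )
            best = grid[int(np.argmax(inner_scores))]
        else:
            best = grid[0] if grid else {}
        mdl = _fit_scheme(scheme, X[tr], y[tr], base_learner, best, seed)
        pred = mdl.predict(X[te])
        folds.append(
            {
                "fold": k,
                "params": best,
                "balanced_accuracy": balanced_accuracy(y[te], pred),
                "weighted_f1": weighted_f1(y[te], pred),
            }
        )
    return CVResult(folds=folds, summary=CVResult.summarise(folds))


def train_test_split_eval(
    X, y, base_learner, scheme: str = "bagged-ovo",
    test_size: float = 0.2, seed: int = 0, params: Mapping | None = None,
) -> dict:
    """Stratified 80:20 train/test evaluation of one scheme."""
    X, y = np.asarray(X), np.asarray(y).astype(str)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    mdl = _fit_scheme(scheme, Xtr, ytr, base_learner, dict(params or {}), seed)
    pred = mdl.predict(Xte)
    return {
        "scheme": scheme,
        "balanced_accuracy": balanced_accuracy(yte, pred),
        "weighted_f1": weighted_f1(yte, pred),
        "model": mdl,
    }
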