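"""Classification-accuracy fitness for binary feature-group masks.

A mask selects feature groups; the selected columns are z-scored with
training-split statistics only and fed to the requested classifier; mean
accuracy over stratified folds (or repeated stratified hold-outs) is the
fitness.  The all-zero mask is worth 0.0 by definition and never reaches a
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix, mask_to_columns

__all__ = [
    "ClassifierSpec",
    "EvalProtocol",
    "make_classifier",
    "knn_cosine_predict",
    "evaluate_fitness",
    "accuracy_distribution",
    "make_fitness",
]

SUPPORTED_CLASSIFIERS = (
    "knn_cosine",
    "svm_gaussian",
    "svm_cubic",
    "svm_polynomial",
    "random_forest",
)


@dataclass(frozen=True)
class ClassifierSpec:
    name: str = "knn_cosine"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SUPPORTED_CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.name!r}; supported: {SUPPORTED_CLASSIFIERS}"
            )


@dataclass(frozen=True)
class EvalProtocol:
    mode: str = "kfold"  # "kfold" or "holdout"
    k: int = 5
    holdout_fraction: float = 0.2
    repetitions: int = 1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("kfold", "holdout"):
            raise ValueError("mode must be 'kfold' or 'holdout'")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


class MedianHeuristicSVC(BaseEstimator, ClassifierMixin):
    """Gaussian-kernel SVC with the kernel width set by the median heuristic.

    gamma = 1 / (2 * median(pairwise distances)^2), estimated on up to 200
    training rows.
    """

    def __init__(self, C: float = 1.0, max_rows: int = 200):
        self.C = C
        self.max_rows = max_rows

    def fit(self, X, y):
        sub = X if X.shape[0] <= self.max_rows else X[: self.max_rows]
        d = pairwise_distances(sub)
        med = np.median(d[np.triu_indices_from(d, k=1)])
        gamma = 1.0 / (2.0 * med**2) if med > 0 else "scale"
        self.svc_ = SVC(kernel="rbf", gamma=gamma, C=self.C)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(X)


def make_classifier(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.name == "knn_cosine":
        return KNeighborsClassifier(
            n_neighbors=hp.pop("n_neighbors", 5), metric="cosine",
            algorithm="brute", **hp,
        )
    if spec.name == "svm_gaussian":
        return MedianHeuristicSVC(C=hp.pop("C", 1.0))
    if spec.name == "svm_cubic":
        return SVC(kernel="poly", degree=3, C=hp.pop("C", 1.0), gamma="scale", **hp)
    if spec.name == "svm_polynomial":
        return SVC(kernel="poly", degree=2, C=hp.pop("C", 1.0), gamma="scale", **hp)
    if spec.name == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            random_state=hp.pop("random_state", 0), **hp,
        )
    raise AssertionError("unreachable")


def _zscore_train(X_train, X_test):
    """Standardize both splits using training statistics only."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X_train - mu) / sd, (X_test - mu) / sd


def knn_cosine_predict(
    X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray, k: int = 5
) -> np.ndarray:
    """Vectorized k-nearest-neighbor majority vote under cosine distance.

    Equivalent to ``KNeighborsClassifier(k, metric="cosine")`` for binary
    labels with odd ``k`` (no vote ties); used on the wrapper search's hot
    path, where tens of thousands of tiny fits make per-call estimator
    overhead the dominant cost.  The equivalence is asserted in the tests.
    """

    def rows_unit(a):
        n = np.linalg.norm(a, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return a / n

    sims = rows_unit(X_te) @ rows_unit(X_tr).T
    k = min(k, X_tr.shape[0])
    idx = np.argpartition(-sims, kth=k - 1, axis=1)[:, :k]
    return (y_tr[idx].mean(axis=1) > 0.5).astype(np.int64)


def _fit_score(clf_spec, X_tr, y_tr, X_te, y_te) -> float:
    X_tr, X_te = _zscore_train(X_tr, X_te)
    if clf_spec.name == "knn_cosine":
        k = clf_spec.hyperparameters.get("n_neighbors", 5)
        return float(np.mean(knn_cosine_predict(X_tr, y_tr, X_te, k) == y_te))
    clf = make_classifier(clf_spec)
    clf.fit(X_tr, y_tr)
    return float(np.mean(clf.predict(X_te) == y_te))


@lru_cache(maxsize=4096)
def _cached_split(n: int, fraction: float, seed: int, y_bytes: bytes):
    y = np.frombuffer(y_bytes, dtype=np.int64)
    for attempt in range(5):
        tr, te = train_test_split(
            np.arange(n), test_size=fraction,
            random_state=(seed + attempt) % (2**31), stratify=y,
        )
        if len(np.unique(y[tr])) == 2:
            return tr, te
    raise RuntimeError("could not draw a two-class training split")


def _holdout_accuracy(X, y, clf_spec, fraction, seed) -> float:
    tr, te = _cached_split(X.shape[0], fraction, int(seed), y.tobytes())
    return _fit_score(clf_spec, X[tr], y[tr], X[te], y[te])


def evaluate_fitness(
    mask: np.ndarray,
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    proto: EvalProtocol = EvalProtocol(),
) -> float:
    """Mean classification accuracy of the masked feature set in [0, 1]."""
    cols = mask_to_columns(mask, fm)
    if cols.size == 0:
        return 0.0
    X = fm.values[:, cols]
    y = fm.y
    if len(np.unique(y)) < 2:
        raise ValueError("fitness evaluation needs both classes present")
    accs = []
    for rep in range(proto.repetitions):
        seed = (proto.seed + 1009 * rep) % (2**31)
        if proto.mode == "kfold":
            skf = StratifiedKFold(n_splits=proto.k, shuffle=True, random_state=seed)
            for tr, te in skf.split(X, y):
                accs.append(_fit_score(clf_spec, X[tr], y[tr], X[te], y[te]))
        else:
            accs.append(
                _holdout_accuracy(X, y, clf_spec, proto.holdout_fraction, seed)
            )
    return float(np.mean(accs))


def accuracy_distribution(
    masks,
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    reps_per_mask: int = 100,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled hold-out accuracy sample: one score per (mask, repetition).

    Every repetition re-randomizes the stratified train/test split.  Returns
    the pooled sample of size ``len(masks) * reps_per_mask`` and a
    provenance array of (mask index, repetition index) rows.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("masks must be nonempty")
    y = fm.y
    scores = np.empty(len(masks) * reps_per_mask)
    prov = np.empty((scores.size, 2), dtype=np.int64)
    pos = 0
    for mi, mask in enumerate(masks):
        cols = mask_to_columns(np.asarray(mask), fm)
        X = fm.values[:, cols] if cols.size else None
        for rep in range(reps_per_mask):
            if X is None:
                scores[pos] = 0.0
            else:
                s = (seed + 7919 * mi + rep) % (2**31)
                scores[pos] = _holdout_accuracy(X, y, clf_spec, holdout_fraction, s)
            prov[pos] = (mi, rep)
            pos += 1
    return scores, prov


def make_fitness(
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    proto: EvalProtocol = EvalProtocol(),
    active_groups: np.ndarray | None = None,
    cache: bool = True,
):
    """Build a colony fitness callable over (a restriction of) the group space.

    When ``active_groups`` is given, the callable accepts masks of length
    ``len(active_groups)`` and expands them to the full group space with
    inactive bits forced to 0.  Identical masks are memoized (the evaluation
    is deterministic for the protocol's seed), which spares repeated
    classifier fits during a colony run.
    """
    active = None if active_groups is None else np.asarray(active_groups, dtype=np.int64)
    memo: dict[bytes, float] = {}

    def fitness(sub_mask: np.ndarray) -> float:
        sub_mask = np.asarray(sub_mask)
        if active is not None:
            full = np.zeros(fm.n_groups, dtype=np.int8)
            full[active[sub_mask.astype(bool)]] = 1
        else:
            full = sub_mask.astype(np.int8)
        key = full.tobytes()
        if cache and key in memo:
            return memo[key]
        val = evaluate_fitness(full, fm, clf_spec, proto)
        if cache:
            memo[key] = val
        return val

    fitness.expand = lambda sub_mask: (
        np.asarray(sub_mask, dtype=np.int8)
        if active is None
        else _expand(np.asarray(sub_mask), active, fm.n_groups)
    )
    return fitness


def _expand(sub_mask: np.ndarray, active: np.ndarray, d: int) -> np.ndarray:
    full = np.zeros(d, dtype=np.int8)
    full[active[sub_mask.astype(bool)]] = 1
    return full
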