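"""Supervised-learning evaluation harness.

Evaluates a roster of 12 classifiers (rule-based, trees, instance-based,
probabilistic, kernel, ensemble and neural paradigms) on a feature table
under a repeated stratified k-fold cross-validation design.  Every algorithm
sees exactly the same fold partitions, which is what makes the downstream
pairwise statistical comparisons valid: per-fold metric differences are
paired observations.

Also implements correlation-based feature selection (CFS): a best-first
forward search over feature subsets scoring each subset by

    merit(S) = k * r_cf / sqrt(k + k * (k - 1) * r_ff)

where ``k`` is the subset size, ``r_cf`` the mean feature-class correlation
and ``r_ff`` the mean feature-feature inter-correlation — relevance in the
numerator, redundancy in the denominator.  Correlations are symmetrical
uncertainties computed after supervised (entropy/MDL) discretization of the
numeric features.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.preprocessing import StandardScaler
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedGroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ALGORITHM_IDS",
    "OneRClassifier",
    "default_algorithms",
    "CVResult",
    "run_cv",
    "confusion",
    "majority_baseline",
    "mdlp_cut_points",
    "symmetrical_uncertainty",
    "CFSProblem",
    "cfs_select",
]

ALGORITHM_IDS = (
    "1R", "DT", "1NN", "5NN", "NB", "RBF", "SVM", "LR", "AdaB", "Bag", "RF", "MLP",
)


# ---------------------------------------------------------------------------
# 1R — Holte's one-rule classifier
# ---------------------------------------------------------------------------

class OneRClassifier(ClassifierMixin, BaseEstimator):
    """Holte's 1R: classify on a single discretized feature.

    Each numeric feature is bucketed by Holte's supervised procedure: walk the
    sorted values growing a bucket until one class reaches ``min_bucket``
    members, extend it over ties and same-class runs, then cut; adjacent
    buckets predicting the same class are merged.  The feature whose rule
    makes the fewest training errors wins (first feature on ties).  A
    constant feature falls back to a single majority bucket.
    """

    def __init__(self, min_bucket: int = 6):
        self.min_bucket = min_bucket

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        best_err = None
        for j in range(X.shape[1]):
            cuts, bucket_classes = self._build_rule(X[:, j], y_codes)
            pred = bucket_classes[np.searchsorted(cuts, X[:, j], side="right")]
            err = int(np.sum(pred != y_codes))
            if best_err is None or err < best_err:
                best_err = err
                self.feature_ = j
                self.cuts_ = cuts
                self.bucket_classes_ = bucket_classes
        return self

    def _build_rule(
        self, x: np.ndarray, y_codes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y_codes[order]
        n_classes = self.classes_.size
        buckets: list[tuple[float, int]] = []  # (upper cut, majority class)
        counts = np.zeros(n_classes, dtype=int)
        start = 0
        i = 0
        n = xs.size
        while i < n:
            counts[ys[i]] += 1
            majority = int(np.argmax(counts))
            if counts[majority] >= self.min_bucket:
                # extend over equal values and a same-class run, then cut
                while i + 1 < n and (xs[i + 1] == xs[i] or ys[i + 1] == majority):
                    i += 1
                    counts[ys[i]] += 1
                majority = int(np.argmax(counts))
                if i + 1 < n:
                    buckets.append(((xs[i] + xs[i + 1]) / 2.0, majority))
                    counts = np.zeros(n_classes, dtype=int)
                    start = i + 1
                else:
                    buckets.append((np.inf, majority))
                    start = n
            i += 1
        if start < n:  # trailing small bucket
            buckets.append((np.inf, int(np.argmax(counts))))
        elif not buckets or buckets[-1][0] != np.inf:
            last_cut, last_cls = buckets[-1]
            buckets[-1] = (np.inf, last_cls)
        # merge adjacent buckets with the same prediction
        merged: list[tuple[float, int]] = []
        for cut, cls in buckets:
            if merged and merged[-1][1] == cls:
                merged[-1] = (cut, cls)
            else:
                merged.append((cut, cls))
        cuts = np.array([c for c, _ in merged[:-1]], dtype=float)
        classes = np.array([cls for _, cls in merged], dtype=int)
        return cuts, classes

    def predict(self, X):
        check_is_fitted(self, "cuts_")
        X = np.asarray(X, dtype=float)
        idx = np.searchsorted(self.cuts_, X[:, self.feature_], side="right")
        return self.classes_[self.bucket_classes_[idx]]

    def predict_proba(self, X):
        pred = self.predict(X)
        proba = np.zeros((len(pred), self.classes_.size))
        for k, c in enumerate(self.classes_):
            proba[pred == c, k] = 1.0
        return proba


def default_algorithms(seed: int = 0) -> dict[str, BaseEstimator]:
    """The 12-classifier roster with its documented default settings.

    Ensembles combine 10 decision trees each.  Scale-sensitive learners
    (neighbours, kernel machines, logistic regression, perceptron) run behind
    a standardizing scaler, mirroring the internal attribute normalization of
    mainstream toolkits; every estimator is fronted by median imputation so
    occasional undefined descriptor values (e.g. Ce/Cd of a constant window)
    do not abort a fold.  The radial-basis-function network is approximated
    by an RBF-kernel support vector machine; exact parity with any particular
    toolkit's RBF network is a non-goal.
    """
    scaled = lambda est: Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("model", est),
        ]
    )
    plain = lambda est: Pipeline(
        [("impute", SimpleImputer(strategy="median")), ("model", est)]
    )
    return {
        "1R": plain(OneRClassifier()),
        "DT": plain(DecisionTreeClassifier(random_state=seed)),
        "1NN": scaled(KNeighborsClassifier(n_neighbors=1)),
        "5NN": scaled(KNeighborsClassifier(n_neighbors=5)),
        "NB": plain(GaussianNB()),
        "RBF": scaled(
            SVC(kernel="rbf", gamma="scale", random_state=seed,
                decision_function_shape="ovr")
        ),
        "SVM": scaled(
            SVC(kernel="linear", random_state=seed, decision_function_shape="ovr")
        ),
        "LR": scaled(LogisticRegression(max_iter=1000)),
        "AdaB": plain(
            AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=3),
                n_estimators=10,
                random_state=seed,
            )
        ),
        "Bag": plain(
            BaggingClassifier(
                estimator=DecisionTreeClassifier(),
                n_estimators=10,
                random_state=seed,
            )
        ),
        "RF": plain(RandomForestClassifier(n_estimators=10, random_state=seed)),
        "MLP": scaled(
            MLPClassifier(hidden_layer_sizes=(20,), max_iter=500, random_state=seed)
        ),
    }


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold metrics of one algorithm under the shared fold design."""

    algorithm: str
    classes: np.ndarray
    accuracy: np.ndarray  # shape (runs * folds,)
    f1: np.ndarray
    auc: np.ndarray
    confusions: np.ndarray  # shape (runs, k, k): per-run summed fold confusions
    runs: int
    folds: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracy, ddof=1))

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "accuracy_mean": self.mean_accuracy,
            "accuracy_std": self.std_accuracy,
            "f1_mean": float(np.mean(self.f1)),
            "f1_std": float(np.std(self.f1, ddof=1)),
            "auc_mean": float(np.mean(self.auc)),
            "auc_std": float(np.std(self.auc, ddof=1)),
        }


def split_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, feature_names) from a feature table with a ``label`` column."""
    if "label" not in table.columns:
        raise ValueError("feature table needs a 'label' column")
    names = [c for c in table.columns if c != "label"]
    X = table[names].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    if pd.isna(y).any():
        raise ValueError("training table has missing labels")
    return X, y, names


def majority_baseline(table: pd.DataFrame) -> float:
    """Accuracy of always predicting the most prevalent class."""
    y = table["label"]
    return float(y.value_counts(normalize=True).iloc[0])


def _fold_scores(model, X_test: np.ndarray, classes: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X_test)
    return model.decision_function(X_test)


def run_cv(
    table: pd.DataFrame,
    algorithms: Mapping[str, BaseEstimator] | None = None,
    runs: int = 10,
    folds: int = 10,
    seed: int = 0,
    groups: Sequence | None = None,
) -> list[CVResult]:
    """Repeated stratified k-fold evaluation with a shared fold design.

    The ``runs * folds`` partitions are generated once from ``seed``
    (stratified, reshuffled each run) and reused for every algorithm, so the
    per-fold metric vectors of any two algorithms are paired.  F1 is the
    prevalence-weighted per-class mean and AUC the prevalence-weighted
    one-vs-rest area.

    ``groups`` (e.g. subject ids) switches to stratified *group* k-fold: no
    group ever spans a train/test boundary.  Instance-level folds overstate
    accuracy when instances are overlapping windows of the same register —
    temporally adjacent windows are near-duplicates — so grouped folds are
    the honest design whenever a cohort has more groups than folds.
    """
    X, y, _ = split_table(table)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold needs >= {folds} instances per class; "
            f"smallest class has {counts.min()}"
        )
    if algorithms is None:
        algorithms = default_algorithms(seed)
    if groups is None:
        splitter = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=runs, random_state=seed
        )
        partitions = list(splitter.split(X, y))
    else:
        groups = np.asarray(groups)
        rng = np.random.default_rng(seed)
        partitions = []
        for _ in range(runs):
            gkf = StratifiedGroupKFold(
                n_splits=folds, shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            partitions.extend(gkf.split(X, y, groups))

    results = []
    for name, estimator in algorithms.items():
        acc = np.empty(len(partitions))
        f1 = np.empty(len(partitions))
        auc = np.empty(len(partitions))
        conf = np.zeros((runs, classes.size, classes.size))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for i, (train, test) in enumerate(partitions):
                model = clone(estimator)
                model.fit(X[train], y[train])
                pred = model.predict(X[test])
                cm = confusion_matrix(y[test], pred, labels=classes)
                acc[i] = np.trace(cm) / cm.sum()
                f1[i] = f1_score(y[test], pred, labels=classes, average="weighted")
                scores = _fold_scores(model, X[test], classes)
                if classes.size == 2:
                    scores = scores[:, 1] if scores.ndim == 2 else scores
                    auc[i] = roc_auc_score(y[test], scores)
                else:
                    auc[i] = roc_auc_score(
                        y[test], scores, multi_class="ovr",
                        average="weighted", labels=classes,
                    )
                conf[i // folds] += cm
        results.append(
            CVResult(
                algorithm=name, classes=classes, accuracy=acc, f1=f1,
                auc=auc, confusions=conf, runs=runs, folds=folds,
            )
        )
    return results


def confusion(cv: CVResult) -> pd.DataFrame:
    """Mean confusion matrix over runs: rows true class, columns predicted.

    Entries are mean counts per run, so each row sums to that class's
    prevalence in the table.
    """
    mean_cm = cv.confusions.mean(axis=0)
    labels = list(cv.classes)
    return pd.DataFrame(mean_cm, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# entropy / MDL discretization and symmetrical uncertainty
# ---------------------------------------------------------------------------

def _entropy_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def mdlp_cut_points(x: np.ndarray, y_codes: np.ndarray, n_classes: int) -> list[float]:
    """Entropy-minimization cut points with the MDL acceptance criterion.

    Recursively splits the sorted value range at the boundary minimizing the
    weighted class entropy, accepting a split only when its information gain
    exceeds the minimum-description-length cost of encoding it.  A feature
    that earns no cut point carries no (univariate) class information at this
    criterion's resolution.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y_codes[order]

    def recurse(lo: int, hi: int, out: list[float]) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_counts = np.bincount(ys[lo:hi], minlength=n_classes)
        ent_s = _entropy_counts(seg_counts)
        if ent_s == 0.0:
            return
        # candidate cuts: between adjacent distinct values
        left = np.zeros(n_classes)
        best = None
        for i in range(lo, hi - 1):
            left[ys[i]] += 1
            if xs[i + 1] == xs[i]:
                continue
            right = seg_counts - left
            n_left = i - lo + 1
            e1, e2 = _entropy_counts(left), _entropy_counts(right)
            went = (n_left * e1 + (n - n_left) * e2) / n
            if best is None or went < best[0]:
                best = (went, i, e1, e2, n_left)
        if best is None:
            return
        went, i, e1, e2, n_left = best
        gain = ent_s - went
        k = int(np.count_nonzero(seg_counts))
        k1 = int(np.count_nonzero(np.bincount(ys[lo : i + 1], minlength=n_classes)))
        k2 = int(np.count_nonzero(np.bincount(ys[i + 1 : hi], minlength=n_classes)))
        delta = np.log2(3**k - 2) - (k * ent_s - k1 * e1 - k2 * e2)
        if gain <= (np.log2(n - 1) + delta) / n:
            return
        cut = (xs[i] + xs[i + 1]) / 2.0
        recurse(lo, i + 1, out)
        out.append(cut)
        recurse(i + 1, hi, out)

    cuts: list[float] = []
    recurse(0, xs.size, cuts)
    return sorted(cuts)


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU(A, B) = 2 I(A;B) / (H(A) + H(B)) for two discrete code vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    ha = _entropy_counts(np.bincount(a))
    hb = _entropy_counts(np.bincount(b))
    if ha + hb == 0:
        return 0.0
    joint = np.bincount(a * (b.max() + 1) + b)
    hab = _entropy_counts(joint)
    return max(0.0, 2.0 * (ha + hb - hab) / (ha + hb))


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

@dataclass
class CFSProblem:
    """Precomputed correlations backing a CFS search on one table."""

    feature_names: list[str]
    su_cf: np.ndarray  # feature-class symmetrical uncertainty
    su_ff: np.ndarray  # pairwise feature-feature symmetrical uncertainty
    usable: np.ndarray = field(init=False)  # non-constant after discretization

    def __post_init__(self) -> None:
        self.usable = self.su_cf >= 0  # placeholder; set by from_table

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "CFSProblem":
        X, y, names = split_table(table)
        classes, y_codes = np.unique(y, return_inverse=True)
        n_feat = len(names)
        codes = []
        usable = np.zeros(n_feat, dtype=bool)
        for j in range(n_feat):
            col = X[:, j]
            col = np.where(np.isnan(col), np.nanmedian(col), col)
            cuts = mdlp_cut_points(col, y_codes, classes.size)
            code = np.searchsorted(np.asarray(cuts), col, side="right")
            codes.append(code.astype(int))
            usable[j] = len(cuts) > 0
        su_cf = np.array(
            [symmetrical_uncertainty(codes[j], y_codes) for j in range(n_feat)]
        )
        su_ff = np.zeros((n_feat, n_feat))
        for j, k in combinations(range(n_feat), 2):
            su_ff[j, k] = su_ff[k, j] = symmetrical_uncertainty(codes[j], codes[k])
        problem = cls(feature_names=list(names), su_cf=su_cf, su_ff=su_ff)
        problem.usable = usable
        return problem

    def merit(self, subset: Iterable[int]) -> float:
        """Hall's CFS merit of a feature index subset."""
        idx = sorted(set(subset))
        k = len(idx)
        if k == 0:
            return 0.0
        r_cf = float(np.mean(self.su_cf[idx]))
        if k == 1:
            return r_cf
        pairs = [(a, b) for a, b in combinations(idx, 2)]
        r_ff = float(np.mean([self.su_ff[a, b] for a, b in pairs]))
        denom = k + k * (k - 1) * r_ff
        if denom <= 0:
            return 0.0
        return k * r_cf / np.sqrt(denom)


def cfs_select(
    table: pd.DataFrame,
    max_stale: int = 5,
    problem: CFSProblem | None = None,
) -> list[str]:
    """Best-first forward CFS subset search.

    Expands the best open subset by adding one feature at a time and stops
    after ``max_stale`` consecutive expansions fail to improve the best merit
    found.  Constant (never-discretizable) features are excluded before the
    search.  The selected feature names come back ordered by descending
    feature-class correlation.
    """
    if problem is None:
        problem = CFSProblem.from_table(table)
    candidates = [j for j in range(len(problem.feature_names)) if problem.usable[j]]
    if len(candidates) < 1:
        return []

    start = frozenset()
    best_subset, best_merit = start, 0.0
    # heap of (-merit, tiebreak, subset); visited set avoids re-expansion
    counter = 0
    open_heap = [(-0.0, counter, start)]
    visited = {start}
    stale = 0
    while open_heap and stale < max_stale:
        neg_merit, _, subset = heapq.heappop(open_heap)
        improved = False
        for j in candidates:
            if j in subset:
                continue
            child = subset | {j}
            if child in visited:
                continue
            visited.add(child)
            merit = problem.merit(child)
            counter += 1
            heapq.heappush(open_heap, (-merit, counter, child))
            if merit > best_merit + 1e-12:
                best_merit, best_subset = merit, child
                improved = True
        stale = 0 if improved else stale + 1
    ordered = sorted(best_subset, key=lambda j: -problem.su_cf[j])
    return [problem.feature_names[j] for j in ordered]
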