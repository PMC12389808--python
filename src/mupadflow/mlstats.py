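"""Classifier comparison and group-separation statistics.

Eight classifier families (SVM, logistic regression, MLP, kNN, random
forest, LDA, Gaussian naive Bayes, decision tree) are compared on any
:class:`~mupadflow.datasets.ProfileDataset` by exhaustive grid search
under stratified 3-fold cross-validation, selecting the hyperparameter
combination with the highest CV accuracy (ties broken by enumeration
order; no nested CV -- the selected combination's CV score is the
reported score).  "LR" in the eight-model lineup is multinomial logistic
regression: a regression on continuous targets cannot produce
classification metrics.

For the selected model, out-of-fold predictions pooled over the three
folds form a single confusion matrix from which per-class and macro
precision/recall/F1 are computed.

The fitted square-root coefficients are additionally compared across
concentration groups with one-way ANOVA followed by Tukey's HSD and a
compact letter display: groups that share no letter differ at ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datasets import ProfileDataset

__all__ = [
    "FAMILIES",
    "ModelGrid",
    "GridSearchResult",
    "ClassificationReport",
    "AnovaTukeyResult",
    "default_grid",
    "make_estimator",
    "grid_search_cv",
    "evaluate_report",
    "compare_families",
    "anova_tukey",
]

FAMILIES = (
    "svm",
    "logistic",
    "mlp",
    "knn",
    "random_forest",
    "lda",
    "gaussian_nb",
    "decision_tree",
)

# Default search grids; the study's appendix grids are not published, so
# these are package defaults, declared as such.
_DEFAULT_GRIDS: dict[str, list[dict] | dict] = {
    "svm": {
        "kernel": ["linear", "rbf"],
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": ["scale", 0.01, 0.1, 1.0],
    },
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "mlp": {
        "hidden_layer_sizes": [(8,), (32,), (128,)],
        "alpha": [1e-4, 1e-2],
    },
    "knn": {"n_neighbors": [1, 3, 5, 7]},
    "random_forest": {
        "n_estimators": [100, 300, 500],
        "max_depth": [None, 3, 10],
    },
    "lda": [
        {"solver": ["svd"]},
        {"solver": ["lsqr"], "shrinkage": [None, "auto"]},
    ],
    "gaussian_nb": {"var_smoothing": [1e-9, 1e-6]},
    "decision_tree": {"max_depth": [None, 3, 5]},
}


@dataclass(frozen=True)
class ModelGrid:
    """One classifier family plus its hyperparameter search grid."""

    family: str
    grid: list[dict] | dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )
        if not self.grid:
            raise ValueError("grid must be non-empty")


def default_grid(family: str, seed: int = 0) -> ModelGrid:
    if family not in _DEFAULT_GRIDS:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    return ModelGrid(family=family, grid=_DEFAULT_GRIDS[family], seed=seed)


def make_estimator(family: str, seed: int = 0, **params):
    """Instantiate one classifier family with a fixed random state."""
    if family == "svm":
        return SVC(random_state=seed, **params)
    if family == "logistic":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if family == "mlp":
        return MLPClassifier(max_iter=2000, random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "lda":
        return LinearDiscriminantAnalysis(**params)
    if family == "gaussian_nb":
        return GaussianNB(**params)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def _folds(k: int, seed: int) -> StratifiedKFold:
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def _check_dataset(dataset: ProfileDataset, k: int) -> None:
    if not np.all(np.isfinite(dataset.matrix)):
        raise ValueError("features must be finite")
    _, counts = np.unique(dataset.labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= {k} samples for {k}-fold stratified CV"
        )


def _encode_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map class labels (e.g. concentrations in g/L) to integer codes."""
    classes, y = np.unique(labels, return_inverse=True)
    return y, classes


@dataclass
class GridSearchResult:
    """Best grid point of one family under stratified k-fold CV."""

    family: str
    best_params: dict
    fold_accuracies: np.ndarray
    cv_accuracy_mean: float
    cv_accuracy_sd: float

    def __repr__(self) -> str:  # compact: fold array is derivable
        return (
            f"GridSearchResult({self.family}, acc={self.cv_accuracy_mean:.3f}"
            f"+/-{self.cv_accuracy_sd:.3f}, params={self.best_params})"
        )


def grid_search_cv(
    dataset: ProfileDataset,
    model_grid: ModelGrid | str,
    k: int = 3,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive grid search with stratified, seeded k-fold CV.

    Returns the argmax-accuracy hyperparameter combination; ties go to the
    earlier grid point in enumeration order.  The reported accuracy is the
    same CV score used for selection.
    """
    if isinstance(model_grid, str):
        model_grid = default_grid(model_grid, seed=seed)
    _check_dataset(dataset, k)
    search = GridSearchCV(
        make_estimator(model_grid.family, seed=model_grid.seed),
        model_grid.grid,
        scoring="accuracy",
        cv=_folds(k, seed),
        refit=False,
    )
    y, _ = _encode_labels(dataset.labels)
    search.fit(dataset.matrix, y)
    best = search.best_index_
    folds = np.array(
        [search.cv_results_[f"split{i}_test_score"][best] for i in range(k)]
    )
    return GridSearchResult(
        family=model_grid.family,
        best_params=dict(search.cv_results_["params"][best]),
        fold_accuracies=folds,
        cv_accuracy_mean=float(folds.mean()),
        cv_accuracy_sd=float(folds.std(ddof=0)),
    )


@dataclass
class ClassificationReport:
    """Pooled out-of-fold performance of one fitted configuration.

    The confusion matrix pools the out-of-fold predictions of all k folds
    (rows = true class, columns = predicted); precision/recall/F1 are
    computed per class from that single matrix, plus macro averages.
    """

    family: str
    params: dict
    classes: np.ndarray
    confusion: np.ndarray
    fold_accuracies: np.ndarray
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    @property
    def accuracy(self) -> float:
        """Pooled accuracy: trace over total of the confusion matrix."""
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": {k: repr(v) for k, v in self.params.items()},
            "classes": self.classes.tolist(),
            "confusion_matrix": self.confusion.tolist(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "cv_accuracy_mean": self.cv_accuracy_mean,
            "cv_accuracy_sd": self.cv_accuracy_sd,
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def evaluate_report(
    dataset: ProfileDataset,
    family: str,
    params: Mapping | None = None,
    k: int = 3,
    seed: int = 0,
) -> ClassificationReport:
    """Confusion matrix and per-class metrics from pooled out-of-fold predictions."""
    _check_dataset(dataset, k)
    est = make_estimator(family, seed=seed, **dict(params or {}))
    cv = _folds(k, seed)
    x = dataset.matrix
    y, classes = _encode_labels(dataset.labels)
    predicted = cross_val_predict(est, x, y, cv=cv)
    folds = cross_val_score(est, x, y, cv=cv, scoring="accuracy")
    cm = confusion_matrix(y, predicted, labels=np.arange(len(classes)))
    tp = np.diag(cm).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(cm.sum(axis=0) > 0, tp / cm.sum(axis=0), 0.0)
        recall = np.where(cm.sum(axis=1) > 0, tp / cm.sum(axis=1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return ClassificationReport(
        family=family,
        params=dict(params or {}),
        classes=classes,
        confusion=cm,
        fold_accuracies=np.asarray(folds),
        cv_accuracy_mean=float(np.mean(folds)),
        cv_accuracy_sd=float(np.std(folds, ddof=0)),
        precision=precision,
        recall=recall,
        f1=f1,
    )


def compare_families(
    dataset: ProfileDataset,
    families: Sequence[str] = FAMILIES,
    k: int = 3,
    seed: int = 0,
    grids: Mapping[str, ModelGrid] | None = None,
) -> pd.DataFrame:
    """Grid-search every family; return a per-family accuracy table.

    Mirrors the study's model-comparison layout: one row per family with
    the best grid point's CV mean accuracy and across-fold s.d.
    """
    records = []
    for family in families:
        grid = (grids or {}).get(family) or default_grid(family, seed=seed)
        result = grid_search_cv(dataset, grid, k=k, seed=seed)
        records.append(
            {
                "family": family,
                "cv_accuracy_mean": result.cv_accuracy_mean,
                "cv_accuracy_sd": result.cv_accuracy_sd,
                "best_params": repr(result.best_params),
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD with compact letter display


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA, all-pairs Tukey HSD and compact letters.

    ``letters`` maps each group to its letter string; groups sharing no
    letter differ significantly at ``alpha``.  ``f`` and ``p`` are NaN when
    the comparison is degenerate (zero variance everywhere with equal
    means).
    """

    f: float
    p: float
    alpha: float
    groups: list
    pairwise: pd.DataFrame
    letters: dict

    @property
    def all_distinct(self) -> bool:
        """True when no two groups share a letter."""
        seen = "".join(self.letters.values())
        return len(seen) == len(set(seen))


def _compact_letters(groups: Sequence, means: Mapping, significant: set) -> dict:
    """Letter maximal cliques of the not-significantly-different graph.

    Every non-significant pair ends up inside some lettered clique (shares
    a letter); significantly different pairs never co-occur in a clique
    (share none).  Letters are ordered by descending group mean.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for x, y in combinations(groups, 2):
        if frozenset((x, y)) not in significant:
            g.add_edge(x, y)
    rank = {grp: i for i, grp in enumerate(sorted(groups, key=means.get, reverse=True))}
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(rank[m] for m in c))
    letters: dict = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        symbol = chr(ord("a") + i)
        for member in sorted(clique, key=rank.get):
            letters[member] += symbol
    return letters


def anova_tukey(
    values: Iterable[float],
    labels: Iterable,
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA plus Tukey HSD letter grouping.

    Applied to the fitted coefficients, a fully lettered-apart result
    (e.g. a/b/c for the three concentrations) means every pair of
    concentration groups has significantly different mean flow
    coefficients at ``alpha``.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(labels))
    groups = np.unique(labels).tolist()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[labels == grp] for grp in groups]
    if min(len(s) for s in samples) < 2:
        raise ValueError("need >= 2 values per group")
    means = {grp: float(np.mean(s)) for grp, s in zip(groups, samples)}

    within_var = max(float(np.var(s, ddof=1)) for s in samples)
    if within_var == 0.0:
        # zero scatter everywhere: separation is exact, not estimable
        distinct_pairs = {
            frozenset((x, y))
            for x, y in combinations(groups, 2)
            if means[x] != means[y]
        }
        all_equal = not distinct_pairs
        pairwise = pd.DataFrame(
            [
                {
                    "group1": x,
                    "group2": y,
                    "meandiff": means[y] - means[x],
                    "p_adj": np.nan if all_equal else (1.0 if means[x] == means[y] else 0.0),
                    "reject": frozenset((x, y)) in distinct_pairs,
                }
                for x, y in combinations(groups, 2)
            ]
        )
        letters = _compact_letters(groups, means, distinct_pairs)
        return AnovaTukeyResult(
            f=np.nan, p=np.nan, alpha=alpha, groups=groups,
            pairwise=pairwise, letters=letters,
        )

    f, p = stats.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = list(combinations(tukey.groupsunique.tolist(), 2))
    table = pd.DataFrame(
        {
            "group1": [x for x, _ in pairs],
            "group2": [y for _, y in pairs],
            "meandiff": tukey.meandiffs,
            "p_adj": tukey.pvalues,
            "reject": tukey.reject,
        }
    )
    significant = {
        frozenset((x, y))
        for (x, y), rej in zip(pairs, tukey.reject)
        if bool(rej)
    }
    letters = _compact_letters(groups, means, significant)
    return AnovaTukeyResult(
        f=float(f), p=float(p), alpha=alpha, groups=groups,
        pairwise=table, letters=letters,
    )
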