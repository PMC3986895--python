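"""Discriminant classification of calls: stepwise feature selection with
leave-one-out cross-validation, jackknife LDA, and a nested permuted DFA.

The classification model throughout is linear discriminant analysis with a
pooled within-class covariance and equal class priors. Three estimators in
the scikit-learn idiom:

* :class:`StepwiseLDASelector` — greedy forward(-backward) search over
  features maximizing the leave-one-out correct-classification rate.
* :class:`JackknifeLDA` — for every call, an LDA is fitted on all other
  calls and the held-out call assigned; the confusion matrix, accuracy,
  discriminant variance proportions and standardized loadings are exposed as
  fitted attributes.
* :class:`NestedPermutedDFA` — a permutation test of group discriminability
  that respects the nesting of calls within males: the test statistic is a
  cross-classification accuracy (train on a balanced random subset of males
  per group, classify the held-out males' calls), and the null distribution
  permutes group labels across whole males, never across calls, so
  pseudo-replication from repeated calls by one male cannot inflate
  significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClassificationResult",
    "PDFAResult",
    "StepwiseLDASelector",
    "JackknifeLDA",
    "NestedPermutedDFA",
    "stepwise_select",
    "lda_fit_loo",
    "collapse_confusion",
    "pdfa_nested",
]


# ---------------------------------------------------------------------------
# Fast pooled-covariance LDA primitives (equal priors)
# ---------------------------------------------------------------------------


def _lda_train(X: np.ndarray, codes: np.ndarray, n_classes: int):
    """Class means and pooled within-class covariance (unbiased)."""
    d = X.shape[1]
    means = np.empty((n_classes, d))
    scatter = np.zeros((d, d))
    for c in range(n_classes):
        Xc = X[codes == c]
        mu = Xc.mean(axis=0)
        means[c] = mu
        dev = Xc - mu
        scatter += dev.T @ dev
    cov = scatter / max(len(X) - n_classes, 1)
    return means, cov


def _lda_predict(means: np.ndarray, cov: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Assign each row to the class with the highest linear discriminant
    score under equal priors."""
    try:
        W = linalg.solve(cov, means.T, assume_a="pos").T
    except linalg.LinAlgError:
        W = (np.linalg.pinv(cov) @ means.T).T
    bias = -0.5 * np.einsum("ij,ij->i", means, W)
    return np.argmax(X @ W.T + bias, axis=1)


def _loo_assignments(X: np.ndarray, codes: np.ndarray, n_classes: int) -> np.ndarray:
    """Jackknife assignments: refit on all-but-one for every call."""
    n = len(X)
    pred = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        means, cov = _lda_train(X[mask], codes[mask], n_classes)
        pred[i] = _lda_predict(means, cov, X[i:i + 1])[0]
        mask[i] = True
    return pred


def _loo_accuracy(X: np.ndarray, codes: np.ndarray, n_classes: int) -> float:
    with np.errstate(all="ignore"):
        try:
            pred = _loo_assignments(X, codes, n_classes)
        except (linalg.LinAlgError, ValueError):
            return -np.inf
    return float(np.mean(pred == codes))


def _check_collinear(X: np.ndarray, feature_names: list[str]) -> None:
    sds = X.std(axis=0)
    zero = [feature_names[j] for j in np.flatnonzero(sds == 0)]
    if zero:
        raise ValueError(
            f"singular pooled covariance: constant feature(s) {zero}"
        )
    corr = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    dup = [
        (feature_names[a], feature_names[b])
        for a, b in zip(*iu)
        if abs(corr[a, b]) > 1 - 1e-10
    ]
    if dup:
        raise ValueError(
            f"singular pooled covariance: collinear feature pair(s) {dup}"
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _validate_xy(X, y) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    X, names = _as_matrix(X)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per call in y")
    if np.isnan(X).any():
        raise ValueError("X contains missing values in selected columns")
    y = np.asarray(y)
    classes, codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"every group needs at least two calls; too few in {small}")
    return X, names, classes, codes


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    """Jackknife LDA output.

    ``confusion_counts``/``confusion_percent`` are true-group × assigned-group
    (row percentages sum to 100); ``accuracy`` is the percent of held-out
    calls assigned to their true group; ``discriminant_variance`` gives each
    discriminant function's share of the between-group variance.
    """

    classes: np.ndarray
    selected_features: list[str]
    confusion_counts: pd.DataFrame
    confusion_percent: pd.DataFrame
    accuracy: float
    assignments: np.ndarray
    discriminant_variance: np.ndarray | None = None
    standardized_loadings: pd.DataFrame | None = None


@dataclass
class PDFAResult:
    """Nested permuted DFA output; ``p_value`` follows the add-one rule
    (1 + #{permuted >= observed}) / (1 + n_permutations)."""

    observed_accuracy: float
    permuted_accuracies: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None


def _confusion(classes, codes, pred) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (codes, pred), 1)
    counts_df = pd.DataFrame(counts, index=classes, columns=classes)
    percent = counts_df.div(counts_df.sum(axis=1), axis=0) * 100.0
    accuracy = 100.0 * np.trace(counts) / counts.sum()
    return counts_df, percent, float(accuracy)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class JackknifeLDA(ClassifierMixin, BaseEstimator):
    """Leave-one-out (jackknife) linear discriminant classification.

    ``fit`` computes, for every call, the class assigned by an equal-prior
    pooled-covariance LDA trained on all other calls, and assembles the
    confusion matrix and accuracy from those held-out assignments. The
    discriminant variance proportions and standardized loadings come from
    the full-data fit. ``predict`` uses the full-data model.

    Attributes (after fit)
    ----------------------
    classes_, accuracy_, confusion_counts_, confusion_percent_,
    assignments_, explained_variance_ratio_, standardized_loadings_,
    result_ : the same information bundled as a
        :class:`ClassificationResult`.
    """

    def __init__(self, store_loadings: bool = True):
        self.store_loadings = store_loadings

    def fit(self, X, y):
        Xm, names, classes, codes = _validate_xy(X, y)
        _check_collinear(Xm, names)

        self.lda_ = LinearDiscriminantAnalysis(
            priors=np.full(len(classes), 1.0 / len(classes))
        )
        self.lda_.fit(Xm, codes)
        pred = _loo_assignments(Xm, codes, len(classes))

        counts, percent, accuracy = _confusion(classes, codes, pred)
        self.classes_ = classes
        self.feature_names_ = names
        self.assignments_ = classes[pred]
        self.confusion_counts_ = counts
        self.confusion_percent_ = percent
        self.accuracy_ = accuracy
        self.explained_variance_ratio_ = self.lda_.explained_variance_ratio_

        loadings = None
        if self.store_loadings:
            _, cov = _lda_train(Xm, codes, len(classes))
            # standardized coefficients: raw scalings x pooled within-class SD
            raw = self.lda_.scalings_
            loadings = pd.DataFrame(
                raw * np.sqrt(np.diag(cov))[:, None],
                index=names,
                columns=[f"LD{i + 1}" for i in range(raw.shape[1])],
            )
        self.standardized_loadings_ = loadings
        self.result_ = ClassificationResult(
            classes=classes,
            selected_features=list(names),
            confusion_counts=counts,
            confusion_percent=percent,
            accuracy=accuracy,
            assignments=self.assignments_,
            discriminant_variance=np.asarray(self.explained_variance_ratio_),
            standardized_loadings=loadings,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "lda_")
        Xm, _ = _as_matrix(X)
        return self.classes_[self.lda_.predict(Xm)]


class StepwiseLDASelector(BaseEstimator):
    """Greedy forward(-backward) feature selection maximizing the
    leave-one-out correct-classification rate of an equal-prior LDA.

    A step is taken only if it improves the LOO rate by at least
    ``improvement_min`` (default: one call, 1/n). Candidates are examined in
    name-sorted order and ties go to the earlier candidate, so the search is
    deterministic. If no single feature beats chance (the majority-class
    rate), the selection is empty and a warning is emitted.
    """

    def __init__(self, improvement_min: float | None = None,
                 backward: bool = True):
        self.improvement_min = improvement_min
        self.backward = backward

    def fit(self, X, y):
        Xm, names, classes, codes = _validate_xy(X, y)
        n, k = len(Xm), len(classes)
        tol = self.improvement_min if self.improvement_min is not None else 1.0 / n
        order = sorted(range(len(names)), key=lambda j: names[j])

        chance = float(np.bincount(codes).max()) / n
        selected: list[int] = []
        score = chance
        while True:
            best_j, best_s = None, -np.inf
            for j in order:
                if j in selected:
                    continue
                s = _loo_accuracy(Xm[:, selected + [j]], codes, k)
                if s >= score + tol and s > best_s:
                    best_j, best_s = j, s
            if best_j is None:
                break
            selected.append(best_j)
            score = best_s

            if self.backward and len(selected) > 2:
                improved = True
                while improved and len(selected) > 2:
                    improved = False
                    for j in list(selected[:-1]):  # never drop the newest
                        rest = [i for i in selected if i != j]
                        s = _loo_accuracy(Xm[:, rest], codes, k)
                        if s >= score + tol:
                            selected, score, improved = rest, s, True
                            break

        if not selected:
            warnings.warn(
                "stepwise selection found no feature improving over chance; "
                "returning an empty selection",
                UserWarning,
                stacklevel=2,
            )
        self.feature_names_ = names
        self.support_ = np.isin(np.arange(len(names)), selected)
        self.selected_features_ = [names[j] for j in selected]
        self.loo_score_ = score
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_features_]
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


class NestedPermutedDFA(BaseEstimator):
    """Permutation test of group discriminability with calls nested in males.

    The statistic is a cross-classification accuracy: per subset draw, a
    balanced random subset of males per group (``train_fraction`` of the
    smallest group's male count, at least one male left out per group) trains
    an equal-prior LDA on their calls, the remaining males' calls are
    classified, and accuracies are averaged over ``n_subset_draws`` draws.
    The null distribution re-computes the statistic after permuting group
    labels across whole males (preserving male-level group sizes), never
    across calls.
    """

    def __init__(self, n_permutations: int = 1000, n_subset_draws: int = 100,
                 train_fraction: float = 2 / 3, random_state: int | None = None):
        self.n_permutations = n_permutations
        self.n_subset_draws = n_subset_draws
        self.train_fraction = train_fraction
        self.random_state = random_state

    def fit(self, X, y, groups):
        Xm, names, classes, codes = _validate_xy(X, y)
        groups = np.asarray(groups)
        if len(groups) != len(Xm):
            raise ValueError("groups must give one nesting unit per call")

        unit_ids, unit_index = np.unique(groups, return_inverse=True)
        n_units = len(unit_ids)
        unit_class = np.full(n_units, -1)
        for u in range(n_units):
            cu = np.unique(codes[unit_index == u])
            if len(cu) > 1:
                raise ValueError(
                    f"design violation: unit {unit_ids[u]!r} spans several "
                    "groups; the test factor must be constant within units"
                )
            unit_class[u] = cu[0]
        units_per_class = np.bincount(unit_class, minlength=len(classes))
        if units_per_class.min() < 2:
            raise ValueError(
                "need at least two nesting units per group for a nested pDFA"
            )

        min_units = int(units_per_class.min())
        k_train = max(1, min(int(np.ceil(self.train_fraction * min_units)),
                             min_units - 1))
        rng = np.random.default_rng(self.random_state)
        unit_calls = [np.flatnonzero(unit_index == u) for u in range(n_units)]
        k = len(classes)

        def statistic(assignment: np.ndarray, n_draws: int) -> float:
            call_labels = assignment[unit_index]
            acc = 0.0
            for _ in range(n_draws):
                train_units: list[int] = []
                for c in range(k):
                    members = np.flatnonzero(assignment == c)
                    train_units.extend(
                        rng.choice(members, size=k_train, replace=False)
                    )
                train_mask = np.zeros(n_units, dtype=bool)
                train_mask[train_units] = True
                tr = np.concatenate([unit_calls[u] for u in np.flatnonzero(train_mask)])
                te = np.concatenate([unit_calls[u] for u in np.flatnonzero(~train_mask)])
                means, cov = _lda_train(Xm[tr], call_labels[tr], k)
                pred = _lda_predict(means, cov, Xm[te])
                acc += float(np.mean(pred == call_labels[te]))
            return 100.0 * acc / n_draws

        observed = statistic(unit_class, self.n_subset_draws)
        permuted = np.empty(self.n_permutations)
        for p in range(self.n_permutations):
            permuted[p] = statistic(rng.permutation(unit_class),
                                    self.n_subset_draws)

        self.classes_ = classes
        self.feature_names_ = names
        self.observed_accuracy_ = observed
        self.permuted_accuracies_ = permuted
        self.n_units_ = n_units
        self.k_train_ = k_train
        self.p_value_ = float(
            (1 + np.sum(permuted >= observed - 1e-12)) / (1 + self.n_permutations)
        )
        self.result_ = PDFAResult(
            observed_accuracy=observed,
            permuted_accuracies=permuted,
            p_value=self.p_value_,
            n_permutations=self.n_permutations,
            seed=self.random_state,
        )
        return self


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def stepwise_select(X, y, improvement_min: float | None = None) -> list[str]:
    """Feature names chosen by :class:`StepwiseLDASelector`."""
    sel = StepwiseLDASelector(improvement_min=improvement_min).fit(X, y)
    return sel.selected_features_


def lda_fit_loo(X, y) -> ClassificationResult:
    """Jackknife LDA; see :class:`JackknifeLDA`."""
    return JackknifeLDA().fit(X, y).result_


def collapse_confusion(
    result: ClassificationResult, mapping: dict
) -> ClassificationResult:
    """Aggregate a result to coarser labels (e.g. populations to species).

    ``mapping`` must cover every class label; counts are summed over mapped
    rows and columns and the accuracy recomputed. Discriminant quantities do
    not survive aggregation and are dropped.
    """
    missing = [c for c in result.classes if c not in mapping]
    if missing:
        raise ValueError(f"mapping does not cover classes {missing}")
    counts = result.confusion_counts.copy()
    counts.index = [mapping[c] for c in counts.index]
    counts.columns = [mapping[c] for c in counts.columns]
    counts = counts.T.groupby(level=0).sum().T.groupby(level=0).sum()
    superclasses = np.asarray(counts.index)
    percent = counts.div(counts.sum(axis=1), axis=0) * 100.0
    accuracy = 100.0 * np.trace(counts.to_numpy()) / counts.to_numpy().sum()
    return ClassificationResult(
        classes=superclasses,
        selected_features=list(result.selected_features),
        confusion_counts=counts,
        confusion_percent=percent,
        accuracy=float(accuracy),
        assignments=np.asarray([mapping[a] for a in result.assignments]),
    )


def pdfa_nested(
    X, y, groups, n_permutations: int = 1000, seed: int | None = None,
    n_subset_draws: int = 100,
) -> PDFAResult:
    """Nested permuted DFA; see :class:`NestedPermutedDFA`."""
    est = NestedPermutedDFA(
        n_permutations=n_permutations,
        n_subset_draws=n_subset_draws,
        random_state=seed,
    ).fit(X, y, groups=groups)
    return est.result_
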