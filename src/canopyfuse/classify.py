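"""Classification protocol: scaling, RBF-SVM / LDA, LOOCV, subset searches.

The protocol evaluates feature subsets by leave-one-out cross-validation
(every specimen predicted by a model trained on all the others), with
features scaled to [-1, 1] and, for the RBF SVM, the kernel parameters
(C, gamma) tuned on a coarse grid by seeded inner cross-validation.
Subset searches are exhaustive over singles and pairs; the best-performing
fraction of pairs from each sensor is combined into four-feature sets
(one structural pair x one spectral pair); a greedy forward selection over
four iterations serves as the cheap alternative, and a linear discriminant
gives the reference classifier.

Determinism: LOOCV itself has no randomness; all inner-CV shuffles derive
from the single spec seed; tuning ties break toward the smallest C, then
the smallest gamma; ranked results order ties lexicographically by feature
names and the full tied set is reported, never one arbitrary winner.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "EvaluationResult",
    "ScaledFeatureTable",
    "SearchResult",
    "confusion_summary",
    "evaluate_subsets",
    "exhaustive_search",
    "form_quadruples",
    "forward_select",
    "loocv_evaluate",
    "scale_features",
    "select_top_fraction",
    "tune_rbf",
]

#: Coarse default tuning grid (three per axis, spanning several orders of
#: magnitude); the full LibSVM-guide grid is available via
#: :meth:`ClassifierSpec.full_grid`.
DEFAULT_C_GRID = (2.0**0, 2.0**5, 2.0**10)
DEFAULT_GAMMA_GRID = (2.0**-7, 2.0**-3, 2.0**1)


@dataclass(frozen=True)
class ClassifierSpec:
    """Family, tuning grids and seed for one classification run."""

    family: str = "svm_rbf"  # or "lda"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 5
    seed: int = 0
    tune: str = "per_subset"  # or "none" (use fixed c/gamma below)
    c_fixed: float = 2.0**5
    gamma_fixed: float = 2.0**-3

    def __post_init__(self) -> None:
        if self.family not in ("svm_rbf", "lda"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "svm_rbf":
            if not self.c_grid or not self.gamma_grid:
                raise ValueError("svm_rbf needs non-empty C and gamma grids")
            if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
                raise ValueError("C and gamma grid values must be positive")

    @classmethod
    def full_grid(cls, **kw) -> "ClassifierSpec":
        """The LibSVM guide's full grid: C = 2^-5..2^15, gamma = 2^-15..2^3."""
        return cls(
            c_grid=tuple(2.0**e for e in range(-5, 16, 2)),
            gamma_grid=tuple(2.0**e for e in range(-15, 4, 2)),
            **kw,
        )


@dataclass
class ScaledFeatureTable:
    """A feature table with per-feature scaling to [-1, 1].

    ``mode='global'`` scales once on all specimens (the classical protocol:
    scale first, then cross-validate); ``mode='per_fold'`` stores the raw
    values and refits min/max on each LOOCV training fold, the
    leakage-safe alternative.  Constant features map to 0.
    """

    frame: pd.DataFrame  # scaled (global) or raw (per_fold) feature values
    label: str  # column holding class labels
    feature_cols: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    mode: str = "global"

    def X(self, subset: Sequence[str]) -> np.ndarray:
        missing = [c for c in subset if c not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown feature column(s): {missing}")
        return self.frame[list(subset)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.label].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


def _minmax_scale(X: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> np.ndarray:
    span = maxs - mins
    out = np.zeros_like(X, dtype=float)
    ok = span > 0
    out[:, ok] = 2.0 * (X[:, ok] - mins[ok]) / span[ok] - 1.0
    return out


def scale_features(
    table: pd.DataFrame,
    label: str,
    feature_cols: Sequence[str] | None = None,
    mode: str = "global",
) -> ScaledFeatureTable:
    """Scale feature columns to [-1, 1] by per-feature min/max.

    ``x' = 2 (x - min) / (max - min) - 1``; a constant column maps to 0.
    Selected columns must be complete — specimens with missing values must
    be dropped (or the columns excluded) before scaling.
    """
    if mode not in ("global", "per_fold"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    if feature_cols is None:
        feature_cols = [
            c
            for c in table.columns
            if c not in ("specimen_id", "species", "habit")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    feature_cols = list(feature_cols)
    values = table[feature_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = [c for c, has in zip(feature_cols, np.isnan(values).any(0)) if has]
        raise ValueError(f"missing values in feature column(s): {bad}")
    mins, maxs = values.min(axis=0), values.max(axis=0)
    frame = table.copy()
    if mode == "global":
        frame[feature_cols] = _minmax_scale(values, mins, maxs)
    return ScaledFeatureTable(
        frame=frame,
        label=label,
        feature_cols=feature_cols,
        mins=mins,
        maxs=maxs,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    """LOOCV outcome for one feature subset."""

    subset: tuple[str, ...]
    labels: list[str]  # class label order of the confusion matrix
    matrix: np.ndarray  # rows = predicted, columns = reference
    y_true: np.ndarray
    y_pred: np.ndarray
    accuracy: float  # overall, percent
    params: tuple[float, float] | None = None  # (C, gamma) when tuned

    def producer_accuracy(self) -> dict[str, float]:
        return confusion_summary(self.matrix, self.labels)[2]

    def user_accuracy(self) -> dict[str, float]:
        return confusion_summary(self.matrix, self.labels)[1]


def _make_estimator(spec: ClassifierSpec, c: float, gamma: float):
    if spec.family == "lda":
        return LinearDiscriminantAnalysis()
    # one-vs-one voting, unweighted classes: the LibSVM defaults; keeping
    # classes unweighted reproduces the bias toward well-represented species
    return SVC(kernel="rbf", C=c, gamma=gamma, decision_function_shape="ovo")


def tune_rbf(
    scaled: ScaledFeatureTable, subset: Sequence[str], spec: ClassifierSpec
) -> tuple[float, float]:
    """Pick (C, gamma) by seeded stratified inner cross-validation.

    Returns the grid point with the highest mean inner-CV accuracy; ties
    break toward the smallest C, then the smallest gamma.  Deterministic
    given the spec seed.
    """
    X = scaled.X(subset)
    y = scaled.y
    if scaled.mode == "per_fold":
        X = _minmax_scale(X, X.min(0), X.max(0))
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(spec.inner_folds, counts.min(), len(y) // 2))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))
    best = (-1.0, None)
    for c in sorted(spec.c_grid):
        for gamma in sorted(spec.gamma_grid):
            correct = 0
            for tr, te in folds:
                est = _make_estimator(spec, c, gamma)
                est.fit(X[tr], y[tr])
                correct += int((est.predict(X[te]) == y[te]).sum())
            acc = correct / len(y)
            if acc > best[0]:
                best = (acc, (c, gamma))
    return best[1]


def loocv_evaluate(
    scaled: ScaledFeatureTable,
    subset: Sequence[str],
    spec: ClassifierSpec,
    params: tuple[float, float] | None = None,
) -> EvaluationResult:
    """Leave-one-out evaluation of one feature subset.

    Each of the n specimens is predicted by a model trained on the other
    n - 1.  For the RBF SVM, (C, gamma) are tuned once per subset by inner
    CV (or taken from ``params`` / the spec's fixed values).  The confusion
    matrix is accumulated over the held-out predictions with rows =
    predicted, columns = reference.
    """
    subset = tuple(subset)
    X = scaled.X(subset)
    y = scaled.y
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("LOOCV needs at least 2 classes")
    if spec.family == "svm_rbf":
        if params is None:
            if spec.tune == "per_subset":
                params = tune_rbf(scaled, subset, spec)
            else:
                params = (spec.c_fixed, spec.gamma_fixed)
        c, gamma = params
    else:
        c = gamma = None
        params = None

    n = len(y)
    y_pred = np.empty(n, dtype=object)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        X_tr, X_te = X[tr], X[i : i + 1]
        if scaled.mode == "per_fold":
            mins, maxs = X_tr.min(0), X_tr.max(0)
            X_tr = _minmax_scale(X_tr, mins, maxs)
            X_te = _minmax_scale(X_te, mins, maxs)
        est = _make_estimator(spec, c, gamma)
        est.fit(X_tr, y[tr])
        y_pred[i] = est.predict(X_te)[0]

    k = len(classes)
    pos = {lab: j for j, lab in enumerate(classes)}
    matrix = np.zeros((k, k), dtype=int)
    for t, p in zip(y, y_pred):
        matrix[pos[p], pos[t]] += 1  # rows predicted, columns reference
    accuracy = 100.0 * np.trace(matrix) / n
    return EvaluationResult(
        subset=subset,
        labels=classes,
        matrix=matrix,
        y_true=np.asarray(y),
        y_pred=y_pred.astype(str),
        accuracy=accuracy,
        params=params,
    )


# ---------------------------------------------------------------------------
# Subset searches
# ---------------------------------------------------------------------------


@dataclass
class SearchResult:
    """Ranked subsets with their LOOCV results.

    ``results`` is sorted by accuracy (non-increasing), ties ordered
    lexicographically by feature names so tied subsets sit adjacently and
    the ranking is reproducible.
    """

    results: list[EvaluationResult]
    arity: int
    selection_fraction: float | None = None
    n_selected: int | None = None

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.results])

    @property
    def subsets(self) -> list[tuple[str, ...]]:
        return [r.subset for r in self.results]

    def best(self) -> EvaluationResult:
        return self.results[0]

    def best_tied(self) -> list[EvaluationResult]:
        """Every subset achieving the top accuracy (never one arbitrary winner)."""
        top = self.results[0].accuracy
        return [r for r in self.results if r.accuracy == top]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": [" + ".join(r.subset) for r in self.results],
                "accuracy": [r.accuracy for r in self.results],
            }
        )


def _sorted_results(results: list[EvaluationResult]) -> list[EvaluationResult]:
    return sorted(results, key=lambda r: (-r.accuracy, r.subset))


def evaluate_subsets(
    scaled: ScaledFeatureTable,
    subsets: Iterable[Sequence[str]],
    spec: ClassifierSpec,
) -> list[EvaluationResult]:
    """LOOCV-evaluate a list of subsets, returned ranked."""
    return _sorted_results([loocv_evaluate(scaled, s, spec) for s in subsets])


def exhaustive_search(
    scaled: ScaledFeatureTable,
    pool: Sequence[str],
    arity: int,
    spec: ClassifierSpec,
) -> SearchResult:
    """Evaluate every unordered ``arity``-subset of the feature pool.

    C(len(pool), arity) evaluations; the ranking is independent of pool
    order because ties are broken by feature names.
    """
    if arity not in (1, 2):
        raise ValueError("exhaustive search supports arity 1 or 2")
    if len(pool) < arity:
        raise ValueError("pool smaller than subset arity")
    combos = itertools.combinations(sorted(pool), arity)
    results = [loocv_evaluate(scaled, c, spec) for c in combos]
    return SearchResult(results=_sorted_results(results), arity=arity)


def select_top_fraction(
    result: SearchResult, fraction: float = 0.10
) -> list[EvaluationResult]:
    """The best-performing fraction of ranked subsets, ties included.

    The nominal cutoff is ``k = ceil(fraction * N)``; every subset tying
    the k-th subset's accuracy is also selected, so the realised fraction
    may exceed the nominal one.
    """
    if not result.results:
        raise ValueError("empty search result")
    n = len(result.results)
    k = min(n, max(1, math.ceil(fraction * n)))
    threshold = result.results[k - 1].accuracy
    selected = [r for r in result.results if r.accuracy >= threshold]
    result.selection_fraction = fraction
    result.n_selected = len(selected)
    return selected


def form_quadruples(
    structural_pairs: Sequence[Sequence[str] | EvaluationResult],
    spectral_pairs: Sequence[Sequence[str] | EvaluationResult],
) -> list[tuple[str, ...]]:
    """All four-feature sets: one structural pair x one spectral pair.

    The Cartesian product, |A| * |B| quadruples; duplicates are impossible
    because the two pools are disjoint.
    """

    def as_subset(x) -> tuple[str, ...]:
        return tuple(x.subset) if isinstance(x, EvaluationResult) else tuple(x)

    return [
        as_subset(a) + as_subset(b)
        for a in structural_pairs
        for b in spectral_pairs
    ]


def forward_select(
    scaled: ScaledFeatureTable,
    pool: Sequence[str],
    spec: ClassifierSpec,
    target_size: int = 4,
) -> tuple[tuple[str, ...], list[tuple[str, float]]]:
    """Greedy forward selection over ``target_size`` iterations.

    Iteration 1 locks the best single feature; each later iteration locks
    the best extension of the locked set, re-evaluated by full LOOCV.  The
    best extension is taken even when it does not improve on the previous
    round (a fixed number of iterations is run).  Returns the selected
    features in lock order and the per-iteration (feature, accuracy)
    history.
    """
    if len(pool) < target_size:
        raise ValueError("pool smaller than target size")
    locked: list[str] = []
    history: list[tuple[str, float]] = []
    remaining = sorted(pool)
    for _ in range(target_size):
        best: tuple[float, str] | None = None
        for feat in remaining:
            res = loocv_evaluate(scaled, locked + [feat], spec)
            if best is None or res.accuracy > best[0]:
                best = (res.accuracy, feat)
        acc, feat = best
        locked.append(feat)
        remaining.remove(feat)
        history.append((feat, acc))
    return tuple(locked), history


# ---------------------------------------------------------------------------
# Confusion-matrix arithmetic
# ---------------------------------------------------------------------------


def confusion_summary(
    matrix: np.ndarray, labels: Sequence[str]
) -> tuple[float, dict[str, float], dict[str, float]]:
    """(overall, user-per-class, producer-per-class) accuracies in percent.

    With rows = predicted and columns = reference:
    overall = 100 * trace / total; user_i = 100 * m_ii / row-sum_i
    (commission view); producer_j = 100 * m_jj / column-sum_j (omission
    view).  A zero row or column leaves the corresponding accuracy
    undefined (NaN).  Values are full precision; round only for display.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(m < 0):
        raise ValueError("confusion matrix must be non-negative")
    if m.shape[0] != len(labels):
        raise ValueError("label count must match matrix size")
    total = m.sum()
    overall = 100.0 * np.trace(m) / total if total else float("nan")
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    user = {
        lab: (100.0 * m[i, i] / row[i] if row[i] else float("nan"))
        for i, lab in enumerate(labels)
    }
    producer = {
        lab: (100.0 * m[j, j] / col[j] if col[j] else float("nan"))
        for j, lab in enumerate(labels)
    }
    return overall, user, producer
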