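"""Classification protocol: scaling, LOOCV, tuning, subset searches."""

import numpy as np
import pandas as pd
import pytest

from canopyfuse.classify import (
    ClassifierSpec,
    SearchResult,
    confusion_summary,
    exhaustive_search,
    form_quadruples,
    forward_select,
    loocv_evaluate,
    scale_features,
    select_top_fraction,
    tune_rbf,
)


def make_table(X: np.ndarray, y, names=None) -> pd.DataFrame:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["label"] = list(y)
    return df


def scaled_from(X, y, names=None, mode="global"):
    df = make_table(X, y, names)
    return scale_features(df, label="label", mode=mode)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


def test_scaling_maps_to_unit_interval():
    s = scaled_from(np.array([[0.0], [5.0], [10.0]]), ["a", "a", "b"])
    np.testing.assert_allclose(s.frame["f0"], [-1.0, 0.0, 1.0])


def test_scaling_constant_column_maps_to_zero():
    s = scaled_from(np.array([[3.0], [3.0], [3.0]]), ["a", "b", "a"])
    np.testing.assert_allclose(s.frame["f0"], 0.0)


def test_scaling_is_idempotent():
    s1 = scaled_from(np.array([[1.0], [4.0], [9.0]]), ["a", "a", "b"])
    s2 = scale_features(s1.frame, label="label", feature_cols=["f0"])
    np.testing.assert_allclose(s1.frame["f0"], s2.frame["f0"])


def test_scaling_rejects_missing_values():
    df = make_table(np.array([[1.0], [np.nan]]), ["a", "b"])
    with pytest.raises(ValueError, match="f0"):
        scale_features(df, label="label")


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------


def _separated_data(rng, n_per=12, gap=10.0):
    x = np.concatenate([rng.normal(0, 1, n_per), rng.normal(gap, 1, n_per)])
    y = ["a"] * n_per + ["b"] * n_per
    return x[:, None], y


def nearest_centroid_loocv(x, y):
    """Independent fold-by-fold oracle for well-separated 1-D data."""
    x = np.ravel(x)
    y = np.asarray(y)
    preds = []
    for i in range(len(x)):
        mask = np.arange(len(x)) != i
        labs = sorted(set(y[mask]))
        cents = {l: x[mask][y[mask] == l].mean() for l in labs}
        preds.append(min(labs, key=lambda l: abs(x[i] - cents[l])))
    return np.array(preds)


@pytest.mark.parametrize("family", ["svm_rbf", "lda"])
def test_loocv_perfect_on_separated_classes(family, rng):
    x, y = _separated_data(rng)
    s = scaled_from(x, y)
    res = loocv_evaluate(s, ("f0",), ClassifierSpec(family=family, seed=0))
    assert res.accuracy == 100.0
    # the nearest-centroid oracle agrees on every fold
    np.testing.assert_array_equal(res.y_pred, nearest_centroid_loocv(x, y))


def test_loocv_confusion_bookkeeping(rng):
    x, y = _separated_data(rng, gap=1.0)  # overlapping: errors happen
    s = scaled_from(x, y)
    res = loocv_evaluate(s, ("f0",), ClassifierSpec(seed=0))
    # column sums equal true class counts
    np.testing.assert_array_equal(res.matrix.sum(axis=0), [12, 12])
    # overall equals the count-weighted mean of producer accuracies
    overall, _, producer = confusion_summary(res.matrix, res.labels)
    weighted = sum(producer[l] * 12 for l in res.labels) / 24
    assert overall == pytest.approx(weighted)
    assert res.accuracy == pytest.approx(overall)


def test_singleton_class_producer_accuracy_is_zero(rng):
    """A one-specimen class can never be predicted correctly under LOOCV:
    its only member is absent from every training fold it is tested on."""
    x = np.concatenate([rng.normal(0, 1, 10), rng.normal(8, 1, 10), [20.0]])
    y = ["a"] * 10 + ["b"] * 10 + ["c"]
    s = scaled_from(x[:, None], y)
    res = loocv_evaluate(s, ("f0",), ClassifierSpec(seed=0))
    assert res.producer_accuracy()["c"] == 0.0


def test_loocv_unknown_column_errors(rng):
    x, y = _separated_data(rng)
    s = scaled_from(x, y)
    with pytest.raises(KeyError, match="nope"):
        loocv_evaluate(s, ("nope",), ClassifierSpec(seed=0))


def test_loocv_null_accuracy_never_beats_chance(rng):
    """Pure-noise feature, balanced classes: LOOCV extracts no skill.

    The mean accuracy over seeded replicates must not exceed chance
    (0.5) by more than 3 standard errors; it routinely falls *below*
    chance because the held-out specimen's class is always the training
    minority (the classic pessimistic LOOCV bias).
    """
    accs = []
    for seed in range(40):
        r = np.random.default_rng(seed)
        x = r.normal(size=30)[:, None]
        y = ["a"] * 15 + ["b"] * 15
        s = scaled_from(x, y)
        accs.append(loocv_evaluate(s, ("f0",), ClassifierSpec(seed=seed)).accuracy / 100)
    accs = np.array(accs)
    se = accs.std() / np.sqrt(len(accs))
    assert accs.mean() <= 0.5 + 3 * se


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------


def test_tune_rbf_separable_reaches_perfect_inner_cv(rng):
    x, y = _separated_data(rng)
    s = scaled_from(x, y)
    spec = ClassifierSpec(seed=1)
    c, gamma = tune_rbf(s, ("f0",), spec)
    assert (c, gamma) in {(ci, gi) for ci in spec.c_grid for gi in spec.gamma_grid}
    res = loocv_evaluate(s, ("f0",), spec, params=(c, gamma))
    assert res.accuracy == 100.0


def test_tune_rbf_grid_of_one_returns_it(rng):
    x, y = _separated_data(rng)
    s = scaled_from(x, y)
    spec = ClassifierSpec(c_grid=(7.0,), gamma_grid=(0.3,), seed=0)
    assert tune_rbf(s, ("f0",), spec) == (7.0, 0.3)


def test_tune_rbf_ties_break_to_smallest_c_then_gamma(rng):
    """Among grid points tying the best inner-CV accuracy (recomputed here
    with an independent fold loop), the smallest (C, gamma) wins."""
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    x, y = _separated_data(rng, gap=50.0)
    s = scaled_from(x, y)
    spec = ClassifierSpec(c_grid=(1.0, 100.0), gamma_grid=(0.5, 0.01), seed=0)
    X, yv = s.X(("f0",)), s.y
    folds = list(
        StratifiedKFold(5, shuffle=True, random_state=spec.seed).split(X, yv)
    )
    scores = {}
    for c in spec.c_grid:
        for g in spec.gamma_grid:
            correct = 0
            for tr, te in folds:
                est = SVC(kernel="rbf", C=c, gamma=g).fit(X[tr], yv[tr])
                correct += int((est.predict(X[te]) == yv[te]).sum())
            scores[(c, g)] = correct / len(yv)
    top = max(scores.values())
    expected = min(k for k, v in scores.items() if v == top)
    assert len([v for v in scores.values() if v == top]) > 1  # real tie
    assert tune_rbf(s, ("f0",), spec) == expected


# ---------------------------------------------------------------------------
# Searches
# ---------------------------------------------------------------------------


def _four_feature_table(rng, n_per=10):
    n = 2 * n_per
    y = ["a"] * n_per + ["b"] * n_per
    strong = np.concatenate([rng.normal(0, 1, n_per), rng.normal(6, 1, n_per)])
    weak = np.concatenate([rng.normal(0, 1, n_per), rng.normal(1.2, 1, n_per)])
    noise1, noise2 = rng.normal(size=n), rng.normal(size=n)
    X = np.column_stack([strong, weak, noise1, noise2])
    return scaled_from(X, y, names=["strong", "weak", "n1", "n2"])


def test_exhaustive_search_counts_and_order_invariance(rng):
    s = _four_feature_table(rng)
    spec = ClassifierSpec(seed=0, tune="none")
    res = exhaustive_search(s, ["strong", "weak", "n1", "n2"], 2, spec)
    assert len(res.results) == 6  # C(4, 2)
    res_perm = exhaustive_search(s, ["n2", "weak", "strong", "n1"], 2, spec)
    assert [r.subset for r in res.results] == [r.subset for r in res_perm.results]
    np.testing.assert_allclose(res.accuracies, res_perm.accuracies)
    only = exhaustive_search(s, ["n1", "n2"], 2, spec)
    assert len(only.results) == 1


def test_exhaustive_search_singles_rank_signal_first(rng):
    s = _four_feature_table(rng)
    res = exhaustive_search(
        s, ["strong", "n1", "n2"], 1, ClassifierSpec(seed=0, tune="none")
    )
    assert res.best().subset == ("strong",)


def _fake_search(accs):
    from canopyfuse.classify import EvaluationResult

    results = [
        EvaluationResult(
            subset=(f"f{i}",),
            labels=["a", "b"],
            matrix=np.eye(2, dtype=int),
            y_true=np.array(["a", "b"]),
            y_pred=np.array(["a", "b"]),
            accuracy=float(a),
        )
        for i, a in enumerate(accs)
    ]
    return SearchResult(results=sorted(results, key=lambda r: -r.accuracy), arity=1)


def test_select_top_fraction_tie_handling():
    assert len(select_top_fraction(_fake_search([5, 4, 3, 3, 2]), 0.4)) == 2
    assert len(select_top_fraction(_fake_search([5, 4, 4, 4, 2]), 0.4)) == 4
    assert len(select_top_fraction(_fake_search([5, 4, 3, 3, 2]), 1.0)) == 5


def test_select_top_fraction_is_monotone():
    res = _fake_search([9, 8, 7, 7, 7, 5, 4, 3, 2, 1])
    sizes = [len(select_top_fraction(res, f)) for f in (0.1, 0.3, 0.5, 0.8, 1.0)]
    assert all(a <= b for a, b in zip(sizes, sizes[1:]))


def test_form_quadruples_cartesian_product():
    a = [("s1", "s2"), ("s3", "s4")]
    b = [("c1", "c2"), ("c3", "c4"), ("c5", "c6")]
    quads = form_quadruples(a, b)
    assert len(quads) == 6
    assert len(set(quads)) == 6
    assert all(len(q) == 4 for q in quads)
    assert form_quadruples([], b) == []


def test_forward_select_single_equals_exhaustive_winner(rng):
    s = _four_feature_table(rng)
    spec = ClassifierSpec(seed=0, tune="none")
    sel, hist = forward_select(s, ["strong", "weak", "n1", "n2"], spec, target_size=1)
    best = exhaustive_search(s, ["strong", "weak", "n1", "n2"], 1, spec).best()
    assert sel == best.subset
    assert hist[0][1] == best.accuracy


def test_forward_select_full_pool_matches_all_features(rng):
    s = _four_feature_table(rng)
    spec = ClassifierSpec(seed=0, tune="none")
    sel, hist = forward_select(s, ["strong", "weak", "n1", "n2"], spec, target_size=4)
    assert sorted(sel) == ["n1", "n2", "strong", "weak"]
    all_res = loocv_evaluate(s, sorted(sel), spec)
    assert hist[-1][1] == pytest.approx(all_res.accuracy)


def test_forward_select_cannot_beat_exhaustive_on_xor(rng):
    """Two features that only separate jointly defeat greedy selection."""
    n = 40
    bits = rng.integers(0, 2, size=(n, 2))
    y = np.where(bits[:, 0] ^ bits[:, 1], "a", "b")
    X = np.column_stack(
        [
            bits[:, 0] + rng.normal(0, 0.1, n),
            bits[:, 1] + rng.normal(0, 0.1, n),
            rng.normal(0, 1, n) + 0.3 * (y == "a"),  # weak marginal feature
        ]
    )
    s = scaled_from(X, y, names=["x1", "x2", "weak"])
    spec = ClassifierSpec(seed=0, tune="none", c_fixed=32.0, gamma_fixed=1.0)
    _, hist = forward_select(s, ["x1", "x2", "weak"], spec, target_size=2)
    pairs = exhaustive_search(s, ["x1", "x2", "weak"], 2, spec)
    assert hist[-1][1] <= pairs.best().accuracy
    assert pairs.best().subset == ("x1", "x2")


# ---------------------------------------------------------------------------
# Confusion arithmetic
# ---------------------------------------------------------------------------


def test_confusion_summary_identity_and_uniform():
    overall, user, producer = confusion_summary(np.eye(3, dtype=int) * 4, ["a", "b", "c"])
    assert overall == 100.0
    assert all(v == 100.0 for v in user.values())
    assert all(v == 100.0 for v in producer.values())
    overall2, user2, producer2 = confusion_summary(np.ones((2, 2), dtype=int), ["a", "b"])
    assert overall2 == 50.0
    assert all(v == 50.0 for v in user2.values()) and all(
        v == 50.0 for v in producer2.values()
    )


def test_confusion_summary_zero_column_is_nan():
    m = np.array([[2, 1, 0], [0, 0, 0], [1, 1, 0]])
    _, user, producer = confusion_summary(m, ["a", "b", "c"])
    assert np.isnan(user["b"])  # never predicted b... row sum 0
    assert np.isnan(producer["c"])  # class c absent from the reference


def test_confusion_summary_validates_input():
    with pytest.raises(ValueError):
        confusion_summary(np.ones((2, 3)), ["a", "b"])
    with pytest.raises(ValueError):
        confusion_summary(-np.ones((2, 2)), ["a", "b"])


# ---------------------------------------------------------------------------
# Scaling mode
# ---------------------------------------------------------------------------


def test_per_fold_scaling_matches_global_on_clean_data(rng):
    x, y = _separated_data(rng)
    res_g = loocv_evaluate(
        scaled_from(x, y, mode="global"), ("f0",), ClassifierSpec(seed=0)
    )
    res_f = loocv_evaluate(
        scaled_from(x, y, mode="per_fold"), ("f0",), ClassifierSpec(seed=0)
    )
    assert res_g.accuracy == res_f.accuracy == 100.0
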