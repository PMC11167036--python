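"""Splitting, classifiers, ROC/AUC, baselines and the DeLong paired test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from txharmony.errors import DataError
from txharmony.models import (
    ClassifierSpec,
    DEFAULT_SPECS,
    ModelEval,
    delong_test,
    random_feature_baseline,
    roc_auc,
    split_balanced,
    train_classifier,
)
from txharmony.simulate import generate_multistudy_counts

from conftest import small_cohort_config


def _eval_from_scores(scores, y, kind="a") -> ModelEval:
    from sklearn.metrics import roc_auc_score, roc_curve

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    fpr, tpr, _ = roc_curve(y, scores)
    return ModelEval(
        kind=kind, scores=scores, y=y, fpr=fpr, tpr=tpr,
        auc=float(roc_auc_score(y, scores)), accuracy=float("nan"),
    )


# ----------------------------------------------------------------------- split


def _toy_meta(n=10, study="S1"):
    return pd.DataFrame(
        {
            "study_id": study,
            "class": ["spaceflown"] * (n // 2) + ["ground"] * (n - n // 2),
            "strain": "C57BL/6J",
            "age_weeks": 16,
            "sex": "F",
        },
        index=pd.Index([f"{study}_s{i}" for i in range(n)], name="sample_id"),
    )


def test_split_single_study_8_2():
    plan = split_balanced(_toy_meta(10), frac=0.8, seed=0)
    assert len(plan.train_samples) == 8 and len(plan.test_samples) == 2
    test_classes = _toy_meta(10).loc[plan.test_samples, "class"]
    assert sorted(test_classes) == ["ground", "spaceflown"]


def test_split_six_study_template_audit():
    bundles, _ = generate_multistudy_counts(small_cohort_config(seed=2))
    meta = pd.concat([b.metadata for b in bundles])
    plan = split_balanced(meta, frac=0.8, seed=1)
    frac_test = len(plan.test_samples) / len(meta)
    assert abs(frac_test - 0.2) <= 0.05
    train_studies = set(meta.loc[plan.train_samples, "study_id"])
    assert train_studies == set(meta["study_id"])
    # class proportions preserved within +-1 per study cell
    for sid, sub in meta.groupby("study_id"):
        got = (sub.loc[sub.index.intersection(plan.test_samples), "class"] == "spaceflown").sum()
        n_sf = (sub["class"] == "spaceflown").sum()
        expected = n_sf * 0.2
        assert abs(got - expected) <= 1.5


def test_split_deterministic():
    meta = _toy_meta(20)
    p1 = split_balanced(meta, seed=5)
    p2 = split_balanced(meta, seed=5)
    pd.testing.assert_series_equal(p1.assignment, p2.assignment)


# ----------------------------------------------------------------- classifiers


def test_all_kinds_fit_separable_toy(separable_xy):
    X, y = separable_xy
    for kind in ("rf", "svm", "lda"):
        model = train_classifier(X, y, DEFAULT_SPECS[kind])
        preds = (model.scores(X) > model.score_threshold).astype(int)
        assert (preds == y).all(), kind


def test_lda_shrinkage_handles_p_much_greater_than_n():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(0, 1, (20, 500)), columns=[f"g{i}" for i in range(500)])
    y = np.array([0, 1] * 10)
    model = train_classifier(X, y, DEFAULT_SPECS["lda"])
    assert np.isfinite(model.scores(X)).all()
    assert len(model.coefficients) == 500


def test_rf_seeded_predictions_reproducible(separable_xy):
    X, y = separable_xy
    m1 = train_classifier(X, y, ClassifierSpec("rf", seed=7))
    m2 = train_classifier(X, y, ClassifierSpec("rf", seed=7))
    np.testing.assert_array_equal(m1.scores(X), m2.scores(X))
    assert m1.oob_accuracy is not None


def test_classifier_input_validation(separable_xy):
    X, y = separable_xy
    with pytest.raises(DataError, match="single class"):
        train_classifier(X, np.zeros(len(y), dtype=int), DEFAULT_SPECS["svm"])
    Xn = X.copy()
    Xn.iloc[0, 0] = np.nan
    with pytest.raises(DataError, match="NaN"):
        train_classifier(Xn, y, DEFAULT_SPECS["svm"])


# -------------------------------------------------------------------- ROC/AUC


def test_auc_matches_mann_whitney_concordance():
    """Scores (0.1, 0.4 | 0.35, 0.8): 3 of 4 positive/negative pairs concordant."""
    ev = _eval_from_scores([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert ev.auc == pytest.approx(0.75)


def test_auc_extremes():
    assert _eval_from_scores([0, 0, 1, 1], [0, 0, 1, 1]).auc == pytest.approx(1.0)
    assert _eval_from_scores([0.3] * 6, [0, 0, 0, 1, 1, 1]).auc == pytest.approx(0.5)


def test_roc_curve_shape(separable_xy):
    X, y = separable_xy
    model = train_classifier(X, y, DEFAULT_SPECS["svm"])
    ev = roc_auc(model, X, y)
    assert ev.fpr[0] == 0.0 and ev.tpr[0] == 0.0
    assert ev.fpr[-1] == 1.0 and ev.tpr[-1] == 1.0
    assert (np.diff(ev.fpr) >= 0).all() and (np.diff(ev.tpr) >= 0).all()
    assert ev.auc == pytest.approx(np.trapezoid(ev.tpr, ev.fpr))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_invariant_under_monotone_score_transforms(seed):
    rng = np.random.default_rng(seed)
    y = np.array([0] * 5 + [1] * 5)
    scores = rng.normal(0, 1, 10)
    base = _eval_from_scores(scores, y).auc
    assert _eval_from_scores(np.exp(scores), y).auc == pytest.approx(base)
    assert _eval_from_scores(3 * scores + 11, y).auc == pytest.approx(base)


def test_one_class_test_set_rejected(separable_xy):
    X, y = separable_xy
    model = train_classifier(X, y, DEFAULT_SPECS["svm"])
    with pytest.raises(DataError, match="single class"):
        roc_auc(model, X, np.ones(len(y), dtype=int))


# ------------------------------------------------------------------- baseline


def test_baseline_k_all_genes_has_no_sampling_variance(separable_xy):
    X, y = separable_xy
    meta = _toy_meta(len(y))
    meta["class"] = np.where(y == 1, "spaceflown", "ground")
    meta.index = X.index
    plan = split_balanced(meta, frac=0.8, seed=0)
    res = random_feature_baseline(
        X, y, plan, k=X.shape[1], specs={"svm": ClassifierSpec("svm")}, n_iter=4, seed=0
    )
    assert np.ptp(res.aucs["svm"]) == 0.0
    assert res.means["svm"] == pytest.approx(res.aucs["svm"][0])


def test_baseline_seeded_reproducible(separable_xy):
    X, y = separable_xy
    meta = _toy_meta(len(y))
    meta.index = X.index
    meta["class"] = np.where(y == 1, "spaceflown", "ground")
    plan = split_balanced(meta, frac=0.8, seed=0)
    r1 = random_feature_baseline(X, y, plan, k=1, specs={"svm": ClassifierSpec("svm")}, n_iter=5, seed=9)
    r2 = random_feature_baseline(X, y, plan, k=1, specs={"svm": ClassifierSpec("svm")}, n_iter=5, seed=9)
    np.testing.assert_array_equal(r1.aucs["svm"], r2.aucs["svm"])
    assert r1.subsets == r2.subsets


# --------------------------------------------------------------------- DeLong


def _delong_brute_force(sa, sb, y):
    """Direct structural-components computation with explicit loops."""
    sa, sb, y = np.asarray(sa, float), np.asarray(sb, float), np.asarray(y)
    pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
    m, n = len(pos), len(neg)

    def psi(x, yv):
        return 1.0 if x > yv else (0.5 if x == yv else 0.0)

    def components(s):
        v10 = [sum(psi(s[i], s[j]) for j in neg) / n for i in pos]
        v01 = [sum(psi(s[i], s[j]) for i in pos) / m for j in neg]
        return np.array(v10), np.array(v01)

    v10a, v01a = components(sa)
    v10b, v01b = components(sb)
    auc_a, auc_b = v10a.mean(), v01a.mean()
    assert auc_a == pytest.approx(auc_b)  # internal consistency of placements

    def cov(u, v):
        return ((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1)

    var = (
        cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)
    ) / m + (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    return v10a.mean() - v10b.mean(), var


def test_delong_self_comparison_is_null():
    y = np.array([0, 0, 0, 1, 1, 1])
    ev = _eval_from_scores([0.1, 0.2, 0.3, 0.25, 0.6, 0.9], y)
    res = delong_test(ev, ev)
    assert res["auc_diff"] == 0.0
    assert res["p"] == 1.0


def test_delong_variance_matches_brute_force_enumeration():
    y = np.array([0, 0, 0, 1, 1, 1])
    sa = [0.1, 0.45, 0.3, 0.25, 0.6, 0.9]
    sb = [0.2, 0.1, 0.5, 0.4, 0.3, 0.8]
    res = delong_test(_eval_from_scores(sa, y, "a"), _eval_from_scores(sb, y, "b"))
    diff, var = _delong_brute_force(sa, sb, y)
    assert res["auc_diff"] == pytest.approx(diff, abs=1e-12)
    assert res["variance"] == pytest.approx(var, abs=1e-12)


def test_delong_placement_auc_equals_rank_auc():
    rng = np.random.default_rng(3)
    y = np.array([0] * 7 + [1] * 5)
    s = rng.normal(0, 1, 12)
    from txharmony.models import _placements

    v10, v01 = _placements(s, y)
    ev = _eval_from_scores(s, y)
    assert v10.mean() == pytest.approx(ev.auc)
    assert v01.mean() == pytest.approx(ev.auc)


def test_delong_p_tends_to_one_under_vanishing_jitter():
    rng = np.random.default_rng(1)
    y = np.array([0] * 10 + [1] * 10)
    s = rng.normal(0, 1, 20) + y
    prev_p = 0.0
    for eps in (1e-1, 1e-3, 1e-6):
        jittered = s + eps * rng.normal(0, 1, 20)
        res = delong_test(_eval_from_scores(s, y), _eval_from_scores(jittered, y))
        assert res["p"] >= prev_p - 1e-9
        prev_p = res["p"]
    assert prev_p > 0.99


def test_delong_rejects_mismatched_samples():
    y1 = np.array([0, 0, 1, 1])
    y2 = np.array([0, 1, 0, 1])
    with pytest.raises(DataError, match="identical test labels"):
        delong_test(_eval_from_scores([1, 2, 3, 4], y1), _eval_from_scores([1, 2, 3, 4], y2))
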