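import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyromics.classification import (
    CVConfig,
    complete_feature_filter,
    label_samples,
    nested_cv,
    roc_auc,
    weighted_importance,
)
from thyromics.preprocess import log10_transform
from thyromics.synthetic import make_design, simulate_hormones


# -------------------------------------------------------------------- labelling
def test_full_design_yields_64_labeled_samples(cohort):
    _, _, samples = cohort
    labeled = label_samples(samples)
    assert len(labeled) == 64
    counts = labeled["state"].value_counts()
    assert counts["euthyroid"] == 32
    assert counts["hyperthyroid"] == 32
    assert "w12" not in set(labeled["time_point"])


def test_three_subjects_yield_twelve_labeled():
    design, subjects = make_design(n_subjects=3, n_outliers=0, seed=1)
    samples = simulate_hormones(design, subjects, seed=2)
    assert len(label_samples(samples)) == 12


def test_empty_input_gives_empty_output(cohort):
    _, _, samples = cohort
    labeled = label_samples(samples.iloc[:0])
    assert labeled.empty


def test_unknown_time_point_is_named_in_error(cohort):
    _, _, samples = cohort
    bad = samples.copy()
    bad.loc[bad.index[0], "time_point"] = "w99"
    with pytest.raises(ValueError, match="w99"):
        label_samples(bad)


# ------------------------------------------------------------- complete filter
def test_complete_feature_filter(cohort):
    _, _, samples = cohort
    labeled = label_samples(samples)
    m = pd.DataFrame(1.0, index=samples.index, columns=["full", "holey"])
    m.loc[labeled.index[3], "holey"] = np.nan
    assert complete_feature_filter(m, labeled) == ["full"]
    # missingness at the dropped w12 visit does not disqualify a feature
    w12 = samples.index[samples["time_point"] == "w12"][0]
    m.loc[w12, "full"] = np.nan
    assert "full" in complete_feature_filter(m, labeled)


# ---------------------------------------------------------- weighted importance
def test_equal_weights_reduce_to_plain_mean():
    gini = np.array([[1.0, 0.0], [0.0, 1.0]])
    np.testing.assert_allclose(weighted_importance(gini, [0.7, 0.7]), [0.5, 0.5])


def test_weighted_importance_hand_example():
    gini = np.array([[1.0], [4.0]])
    assert weighted_importance(gini, [1.0, 0.5])[0] == pytest.approx(2.0)


def test_weighted_importance_is_permutation_symmetric():
    rng = np.random.default_rng(1)
    gini = rng.random((6, 4))
    w = rng.random(6)
    base = weighted_importance(gini, w)
    perm = rng.permutation(6)
    np.testing.assert_allclose(weighted_importance(gini[perm], w[perm]), base)


def test_weighted_importance_rejects_zero_weights():
    with pytest.raises(ValueError):
        weighted_importance(np.ones((2, 3)), [0.0, 0.0])


# ------------------------------------------------------------------------- ROC
def test_roc_extremes():
    auc, _, _ = roc_auc([0.9, 0.8, 0.1, 0.2],
                        ["hyperthyroid", "hyperthyroid", "euthyroid", "euthyroid"])
    assert auc == pytest.approx(1.0)
    auc, _, _ = roc_auc([0.5] * 4,
                        ["hyperthyroid", "hyperthyroid", "euthyroid", "euthyroid"])
    assert auc == pytest.approx(0.5)


def test_roc_concordance_example():
    """3 positives vs 1 negative, 2 concordant pairs of 3 -> AUC = 2/3."""
    labels = ["hyperthyroid"] * 3 + ["euthyroid"]
    auc, _, _ = roc_auc([0.9, 0.8, 0.2, 0.3], labels)
    assert auc == pytest.approx(2 / 3)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], ["euthyroid", "euthyroid"])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0]),
             min_size=2, max_size=20),
    st.data(),
)
def test_roc_matches_pairwise_concordance(scores, data):
    """Trapezoidal AUC equals concordance probability with ties counted 1/2."""
    n = len(scores)
    labels = data.draw(
        st.lists(st.sampled_from(["euthyroid", "hyperthyroid"]), min_size=n, max_size=n)
    )
    if len(set(labels)) < 2:
        labels[0], labels[-1] = "euthyroid", "hyperthyroid"
    auc, _, _ = roc_auc(scores, labels)
    pos = [s for s, l in zip(scores, labels) if l == "hyperthyroid"]
    neg = [s for s, l in zip(scores, labels) if l == "euthyroid"]
    conc = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
    assert auc == pytest.approx(conc, abs=1e-12)


# ------------------------------------------------------------------- nested CV
SMALL_CV = dict(n_outer=3, n_inner=4, n_trees=25, panel_size=5)


@pytest.fixture(scope="module")
def labeled_data(cohort, clean_log_layer):
    _, _, samples = cohort
    logm, catalog = clean_log_layer
    labeled = label_samples(samples)
    kept = complete_feature_filter(logm, labeled)
    return logm[kept], labeled, catalog


def test_nested_cv_mechanics(labeled_data):
    matrix, labeled, _ = labeled_data
    cv = nested_cv(matrix, labeled, CVConfig(seed=5, **SMALL_CV))
    assert len(cv.outer) == 3
    for loop in cv.outer:
        assert loop.n_inner_fits == 4
        assert len(loop.panel) == 5
        assert 0.0 <= loop.auc <= 1.0
        assert np.all((loop.inner_aucs >= 0) & (loop.inner_aucs <= 1))
    assert len(cv.panel) == 5
    assert cv.mean_auc == pytest.approx(np.mean([o.auc for o in cv.outer]))


def test_outer_validation_never_leaks_into_training(labeled_data):
    matrix, labeled, _ = labeled_data
    cv = nested_cv(matrix, labeled, CVConfig(seed=6, **SMALL_CV))
    n = len(labeled)
    for loop in cv.outer:
        assert len(np.intersect1d(loop.train_idx, loop.valid_idx)) == 0
        assert len(loop.train_idx) + len(loop.valid_idx) == n


def test_nested_cv_deterministic_given_seed(labeled_data):
    matrix, labeled, _ = labeled_data
    a = nested_cv(matrix, labeled, CVConfig(seed=7, **SMALL_CV))
    b = nested_cv(matrix, labeled, CVConfig(seed=7, **SMALL_CV))
    assert a.panel == b.panel
    np.testing.assert_allclose(a.outer_aucs, b.outer_aucs)


def test_panel_prefers_planted_features(labeled_data):
    matrix, labeled, catalog = labeled_data
    cv = nested_cv(matrix, labeled, CVConfig(seed=8, n_outer=4, n_inner=6,
                                             n_trees=60, panel_size=8))
    planted = set(catalog.index[catalog["true_beta"] != 0]) & set(matrix.columns)
    overlap = len(set(cv.panel) & planted) / len(cv.panel)
    assert overlap >= 0.75
    assert cv.mean_auc > 0.8


def test_subject_aware_splits_keep_subjects_together(labeled_data):
    matrix, labeled, _ = labeled_data
    cv = nested_cv(
        matrix, labeled,
        CVConfig(seed=9, subject_aware=True, **SMALL_CV),
    )
    subjects = labeled["subject_id"].to_numpy()
    for loop in cv.outer:
        assert not set(subjects[loop.train_idx]) & set(subjects[loop.valid_idx])


def test_panel_size_cannot_exceed_features(labeled_data):
    matrix, labeled, _ = labeled_data
    with pytest.raises(ValueError):
        nested_cv(matrix.iloc[:, :3], labeled, CVConfig(seed=1, panel_size=15))
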