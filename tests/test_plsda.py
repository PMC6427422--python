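import numpy as np
import pytest
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

import seednir as sn
from seednir.errors import (AlignmentError, ConfigurationError, LabelError,
                            SplitError)
from seednir.plsda import (classify_by_baseline, cv_error_by_lv,
                           stratified_kfold_indices)


def _random_instance(rng, n=12, p=8):
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < 0.5).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return X, y


# ----------------------------------------------------------------- fitting
def test_rank_one_data_fits_exactly_with_one_lv():
    rng = np.random.default_rng(0)
    t = rng.standard_normal(15)
    p = rng.standard_normal(6)
    X = np.outer(t, p)
    y = (t > 0).astype(float)
    # y is a thresholding of the single latent direction: not exactly linear
    # in t, so use the continuous response residual on an exactly linear y
    y_lin = 0.5 + 0.25 * t
    model = sn.fit_nipals(X, (y_lin > y_lin.mean()).astype(float), 1)
    # the X factorization itself must be exact at 1 LV for rank-1 X
    resid = (X - X.mean(0)) - model.x_scores_ @ model.x_loadings_.T
    assert np.linalg.norm(resid) < 1e-10


def test_nipals_matches_sklearn_pls_oracle():
    """Regression coefficients agree with an independent PLS implementation
    on 20 random 12x8 instances, 3 LVs."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        X, y = _random_instance(rng)
        model = sn.fit_nipals(X, y, 3)
        oracle = PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(model.coef_, oracle.coef_.ravel(), atol=1e-8)


def test_full_rank_pls_equals_least_squares():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((20, 5))
    y = (rng.random(20) < 0.5).astype(float)
    model = sn.fit_nipals(X, y, 5)
    Xc = np.column_stack([np.ones(20), X])
    beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
    ols_fit = Xc @ beta
    assert np.allclose(model.decision_function(X), ols_fit, atol=1e-8)


def test_score_orthogonality_and_monotone_residual():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((25, 12))
    y = (rng.random(25) < 0.5).astype(float)
    model = sn.fit_nipals(X, y, 6)
    T = model.x_scores_
    G = T.T @ T
    off = G - np.diag(np.diag(G))
    norms = np.sqrt(np.diag(G))
    assert np.all(np.abs(off) < 1e-8 * np.outer(norms, norms))
    # ||E_X|| non-increasing in A
    Xc = X - X.mean(0)
    prev = np.linalg.norm(Xc)
    for a in range(1, 7):
        resid = Xc - T[:, :a] @ model.x_loadings_[:, :a].T
        cur = np.linalg.norm(resid)
        assert cur <= prev + 1e-12
        prev = cur


def test_beta_prediction_equals_factor_expansion():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((18, 9))
    y = (rng.random(18) < 0.5).astype(float)
    model = sn.fit_nipals(X, y, 4)
    via_beta = model.decision_function(X)
    via_factors = model.scores(X) @ model.y_loadings_ + model.y_mean_
    assert np.allclose(via_beta, via_factors, atol=1e-10)


def test_sample_order_permutation_leaves_coefficients_unchanged():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((30, 10))
    y = (rng.random(30) < 0.5).astype(float)
    perm = rng.permutation(30)
    b1 = sn.fit_nipals(X, y, 4).coef_
    b2 = sn.fit_nipals(X[perm], y[perm], 4).coef_
    assert np.allclose(b1, b2, atol=1e-10)


def test_single_class_y_rejected():
    X = np.random.default_rng(0).standard_normal((10, 4))
    with pytest.raises(LabelError, match="both classes"):
        sn.fit_nipals(X, np.ones(10), 2)


def test_too_many_components_rejected():
    X = np.random.default_rng(0).standard_normal((6, 4))
    y = np.array([0, 1, 0, 1, 0, 1], dtype=float)
    with pytest.raises(ConfigurationError):
        sn.fit_nipals(X, y, 6)


# ----------------------------------------------------------- prediction
def test_zero_lv_model_predicts_class_mean():
    X = np.random.default_rng(1).standard_normal((10, 4))
    y = np.array([0, 1] * 5, dtype=float)
    model = sn.fit_nipals(X, y, 0)
    assert np.allclose(model.decision_function(X), 0.5)


def test_duplicated_rows_get_identical_predictions():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((14, 6))
    y = (rng.random(14) < 0.5).astype(float)
    model = sn.fit_nipals(X, y, 3)
    two = np.vstack([X[3], X[3]])
    out = model.decision_function(two)
    assert out[0] == out[1]


def test_wavenumber_alignment_checked_for_spectra_sets(tiny_set):
    labelled = tiny_set.subset([0, 1])
    X = np.vstack([labelled.absorbance] * 6)
    y = np.array([1.0, 0.0] * 6)
    model = sn.fit_nipals(X, y, 1, wavenumbers=labelled.wavenumbers)
    shifted = sn.SpectraSet(
        wavenumbers=labelled.wavenumbers + 4.0,
        absorbance=labelled.absorbance,
        sample_ids=labelled.sample_ids,
        variety=labelled.variety, label=labelled.label)
    with pytest.raises(AlignmentError, match="cm"):
        model.decision_function(shifted)


# ----------------------------------------------------------- baseline rule
@pytest.mark.parametrize("y_hat,label,flag", [
    (0.9, 1, False),
    (0.1, 0, False),
    (1.7, 1, True),    # outside band, nearest class = viable
    (-0.6, 0, True),
    (0.5, 1, False),   # tie goes to viable (closed lower bound)
])
def test_baseline_rule_cases(y_hat, label, flag):
    labels, flags = classify_by_baseline(np.array([y_hat]))
    assert labels[0] == label and flags[0] == flag


def test_baseline_out_of_range_rejected():
    with pytest.raises(ConfigurationError):
        classify_by_baseline(np.array([0.5]), baseline=1.5)


# ----------------------------------------------------------- LV selection
def test_separable_rank_two_data_selects_few_lvs():
    rng = np.random.default_rng(21)
    n = 60
    y = np.array([0.0, 1.0] * (n // 2))
    t1 = y - 0.5 + 0.01 * rng.standard_normal(n)
    t2 = rng.standard_normal(n)
    directions = rng.standard_normal((2, 20))
    X = np.outer(t1, directions[0]) + np.outer(t2, directions[1])
    a = sn.select_num_lvs(X, y, max_lv=6, folds=5, seed=0)
    assert a <= 3
    assert cv_error_by_lv(X, y, 6, folds=5, seed=0)[a - 1] == 0.0


def test_pure_noise_labels_select_one_lv_by_tie_rule():
    rng = np.random.default_rng(33)
    X = rng.standard_normal((60, 15))
    y = np.array([0.0, 1.0] * 30)
    errors = cv_error_by_lv(X, y, 5, folds=5, seed=1)
    assert np.all(errors > 0.3)  # nothing to learn
    a = sn.select_num_lvs(X, y, 5, folds=5, seed=1)
    assert a == int(np.argmin(errors)) + 1


def test_training_response_residual_non_increasing_in_lv():
    """||y - y_hat||^2 on the training set shrinks (weakly) with each added
    latent variable; the thresholded 0/1 error has no such guarantee."""
    rng = np.random.default_rng(8)
    X = rng.standard_normal((40, 12))
    y = (rng.random(40) < 0.5).astype(float)
    sses = []
    for a in range(1, 7):
        model = sn.fit_nipals(X, y, a)
        sses.append(np.sum((model.decision_function(X) - y) ** 2))
    assert all(s2 <= s1 + 1e-10 for s1, s2 in zip(sses, sses[1:]))


def test_stratified_folds_require_enough_samples_per_class():
    y = np.array([0.0] * 3 + [1.0] * 20)
    with pytest.raises(SplitError):
        stratified_kfold_indices(y, folds=5, seed=0)


# ----------------------------------------------------------- diagnostics
def _fitted_model(seed=13, n=40, p=12, a=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < 0.5).astype(float)
    return sn.fit_nipals(X, y, a), X


def test_t2_zero_at_training_centroid():
    model, X = _fitted_model()
    rep = model.diagnostics(model.x_mean_[None, :])
    assert rep.t2[0] == pytest.approx(0.0, abs=1e-16)


def test_q_zero_for_sample_in_score_plane():
    model, X = _fitted_model()
    t = np.array([1.3, -0.4, 0.8])
    x = model.x_mean_ + t @ model.x_loadings_.T
    rep = model.diagnostics(x[None, :])
    assert rep.q[0] == pytest.approx(0.0, abs=1e-10)


def test_t2_limit_matches_f_quantile_oracle():
    a_lv, n, conf = 2, 520, 0.989
    rng = np.random.default_rng(2)
    X = rng.standard_normal((n, 30))
    y = (rng.random(n) < 0.5).astype(float)
    model = sn.fit_nipals(X, y, a_lv)
    rep = model.diagnostics(X, confidence=conf)
    expected = a_lv * (n - 1) / (n - a_lv) * stats.f.ppf(conf, a_lv, n - a_lv)
    assert rep.t2_limit == pytest.approx(expected, abs=1e-6)


def test_outlier_flag_requires_both_statistics():
    model, X = _fitted_model()
    rep = model.diagnostics(X)
    assert np.array_equal(rep.outlier_flags, rep.t2_flags & rep.q_flags)
    assert np.all(rep.t2 >= 0) and np.all(rep.q >= 0)
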