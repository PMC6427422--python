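"""NIPALS PLS-DA: two-class partial least squares discriminant analysis.

The classifier regresses the 0/1 class code y (nonviable=0, viable=1) on the
spectral matrix X through latent variables extracted by NIPALS with
deflation:

    X = T P' + E_X,   y = U q' + e_y,   y_hat = (x - x_mean) b + y_mean

with b = W (P'W)^{-1} q'.  X columns are mean-centered only (no variance
scaling), the convention for absorbance spectra.  Classification applies a
symmetric band of half-width 0.5 around each class code: y_hat >= 0.5 is
viable, y_hat < 0.5 nonviable; responses outside [-0.5, 1.5] are assigned to
the nearest class and flagged ``outside_baseline``, so every sample is
counted.

Model-space diagnostics follow standard chemometrics practice: per-sample
Hotelling's T^2 in score space (limit from the F distribution) and Q
residuals (squared distance from the latent plane, limit by the
Jackson-Mudholkar approximation), with outliers flagged only when both
statistics exceed their limits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataset import SpectraSet
from .errors import (AlignmentError, ConfigurationError, ConvergenceError,
                     LabelError, SplitError)

# ----------------------------------------------------------------------
# NIPALS core
# ----------------------------------------------------------------------
def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int,
                 tol: float = 1e-10, max_iter: int = 500,
                 allow_early_stop: bool = False):
    """Extract up to ``n_components`` PLS1 factors from centered X, y.

    Returns (W, P, q, T, U).  With ``allow_early_stop`` the extraction ends
    quietly when X or y rank is exhausted (used by cross-validation); without
    it a :class:`ConvergenceError` is raised.
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.astype(float).copy()
    W, P, T, U, q = [], [], [], [], []
    scale = max(np.linalg.norm(Xc) * np.linalg.norm(yc), 1e-300)
    for a in range(n_components):
        u = y.copy()
        if np.linalg.norm(X.T @ u) < 1e-13 * scale:
            if allow_early_stop:
                break
            raise ConvergenceError(
                f"component {a + 1}: covariance between X and y residuals "
                "is numerically zero (rank exhausted)")
        w_old = None
        for _ in range(max_iter):
            w = X.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm < 1e-300:
                raise ConvergenceError(f"component {a + 1}: zero weight vector")
            w = w / w_norm
            t = X @ w
            tt = t @ t
            if tt < 1e-300:
                raise ConvergenceError(f"component {a + 1}: zero score vector")
            qa = (y @ t) / tt
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
            # update u from the y side (u = y q / q'q; proportional to y for
            # a univariate response, so the loop converges on iteration 2)
            u = y * qa / max(qa * qa, 1e-300) if qa != 0.0 else y.copy()
        else:
            raise ConvergenceError(
                f"component {a + 1}: NIPALS did not converge in {max_iter} "
                "iterations")
        pa = X.T @ t / tt
        X = X - np.outer(t, pa)
        y = y - qa * t
        W.append(w); P.append(pa); T.append(t); q.append(qa); U.append(u)
    A = len(W)
    W = np.column_stack(W) if A else np.zeros((p, 0))
    P = np.column_stack(P) if A else np.zeros((p, 0))
    T = np.column_stack(T) if A else np.zeros((n, 0))
    U = np.column_stack(U) if A else np.zeros((n, 0))
    return W, P, np.asarray(q), T, U, X  # X is the final X-residual E_X


def _beta(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Regression coefficients using the first ``a`` factors."""
    if a == 0:
        return np.zeros(W.shape[0])
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


# ----------------------------------------------------------------------
# diagnostics containers
# ----------------------------------------------------------------------
@dataclass
class DiagnosticReport:
    """Per-sample Hotelling's T^2 and Q residuals with confidence limits.

    ``outlier_flags`` requires both statistics beyond their limits; the
    single-criterion flags are kept for inspection.
    """

    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    confidence: float
    outlier_flags: np.ndarray
    t2_flags: np.ndarray
    q_flags: np.ndarray

    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())


# ----------------------------------------------------------------------
# the estimator
# ----------------------------------------------------------------------
class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Two-class PLS-DA with NIPALS factor extraction.

    Parameters
    ----------
    n_components : int
        Number of latent variables A (0 gives the mean-only model).
    baseline : float
        Half-width of the classification band around each class code.
    tol, max_iter : float, int
        NIPALS convergence control (tolerance on the weight vector).
    """

    def __init__(self, n_components: int = 2, baseline: float = 0.5,
                 tol: float = 1e-10, max_iter: int = 500):
        self.n_components = n_components
        self.baseline = baseline
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y, wavenumbers: np.ndarray | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape != (n,):
            raise LabelError(f"y length {y.shape} != n_samples {n}")
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))):
            raise LabelError("y must be coded 0 (nonviable) / 1 (viable)")
        if classes.size < 2:
            raise LabelError("both classes must be present in y")
        A = int(self.n_components)
        if A < 0 or A > min(n - 1, p):
            raise ConfigurationError(
                f"n_components={A} outside [0, min(n-1, p)] = "
                f"[0, {min(n - 1, p)}]")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        W, P, q, T, U, Ex = _nipals_pls1(Xc, yc, A, self.tol, self.max_iter)
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = T
        self.y_scores_ = U
        self.coef_ = _beta(W, P, q, A)
        self.n_components_ = A
        self.n_features_in_ = p
        self.n_samples_ = n
        self.classes_ = np.array([0, 1])
        self.wavenumbers_ = (None if wavenumbers is None
                             else np.asarray(wavenumbers, dtype=float))
        # training score variance (n-1) for T^2 and residual spectrum for the
        # Jackson-Mudholkar Q limit
        self.score_var_ = (T.var(axis=0, ddof=1) if A else np.zeros(0))
        sv = np.linalg.svd(Ex, compute_uv=False) if n and p else np.zeros(0)
        lam = sv ** 2 / max(n - 1, 1)
        self.residual_eigenvalues_ = lam[lam > 1e-12 * (lam[0] if lam.size else 1)]
        return self

    # -- prediction --------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise ConfigurationError("model is not fitted")

    def _matrix(self, data) -> np.ndarray:
        if isinstance(data, SpectraSet):
            if self.wavenumbers_ is not None:
                a, b = data.wavenumbers, self.wavenumbers_
                if a.shape != b.shape or not np.allclose(a, b, rtol=1e-9):
                    k = (np.flatnonzero(a[:min(len(a), len(b))] !=
                                        b[:min(len(a), len(b))])
                         if a.shape == b.shape else np.array([0]))
                    first = a[k[0]] if k.size and k[0] < len(a) else a[-1]
                    raise AlignmentError(
                        f"wavenumber axis mismatch (first differing value "
                        f"near {first} cm^-1); apply the stored preprocessing "
                        "chain before prediction")
            return data.absorbance
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise AlignmentError(
                f"X has {X.shape[1]} variables, model expects "
                f"{self.n_features_in_}")
        return X

    def decision_function(self, X) -> np.ndarray:
        """Continuous response y_hat = (x - x_mean) b + y_mean."""
        self._check_fitted()
        X = self._matrix(X)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        labels, _ = classify_by_baseline(self.decision_function(X), self.baseline)
        return labels

    def predict_with_flags(self, X):
        return classify_by_baseline(self.decision_function(X), self.baseline)

    # -- diagnostics -------------------------------------------------------
    def scores(self, X) -> np.ndarray:
        """Predicted latent scores T = (X - x_mean) W (P'W)^{-1}."""
        self._check_fitted()
        X = self._matrix(X)
        if self.n_components_ == 0:
            return np.zeros((X.shape[0], 0))
        R = self.x_weights_ @ np.linalg.inv(
            self.x_loadings_.T @ self.x_weights_)
        return (X - self.x_mean_) @ R

    def diagnostics(self, X, confidence: float = 0.989) -> DiagnosticReport:
        """Hotelling's T^2 / Q residual report for an aligned set
        (typically the calibration set)."""
        self._check_fitted()
        A, n = self.n_components_, self.n_samples_
        if A < 1:
            raise ConfigurationError("diagnostics require at least one LV")
        if n <= A:
            raise ConfigurationError(
                f"T^2 limit undefined for n={n} <= A={A}")
        Xm = self._matrix(X)
        T = self.scores(Xm)
        t2 = np.sum(T ** 2 / self.score_var_, axis=1)
        resid = (Xm - self.x_mean_) - T @ self.x_loadings_.T
        qstat = np.sum(resid ** 2, axis=1)
        t2_limit = (A * (n - 1) / (n - A)
                    * stats.f.ppf(confidence, A, n - A))
        q_limit = jackson_mudholkar_limit(self.residual_eigenvalues_, confidence)
        t2_flags = t2 > t2_limit
        q_flags = qstat > q_limit
        return DiagnosticReport(
            t2=t2, q=qstat, t2_limit=float(t2_limit), q_limit=float(q_limit),
            confidence=confidence, outlier_flags=t2_flags & q_flags,
            t2_flags=t2_flags, q_flags=q_flags)


def jackson_mudholkar_limit(eigenvalues: np.ndarray, confidence: float) -> float:
    """Q-residual confidence limit from residual eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 0.0
    th1, th2, th3 = lam.sum(), (lam ** 2).sum(), (lam ** 3).sum()
    if th2 <= 0:
        return float(th1)
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2 ** 2)
    if abs(h0) < 1e-12:
        h0 = 1e-12
    c = stats.norm.ppf(confidence)
    term = (c * np.sqrt(2.0 * th2 * h0 ** 2) / th1
            + 1.0 + th2 * h0 * (h0 - 1.0) / th1 ** 2)
    if term <= 0:
        return 0.0
    return float(th1 * term ** (1.0 / h0))


# ----------------------------------------------------------------------
# baseline classification rule
# ----------------------------------------------------------------------
def classify_by_baseline(y_hat: np.ndarray, baseline: float = 0.5):
    """Assign 0/1 labels by the symmetric band rule.

    y_hat in [0.5, 1 + baseline] -> viable (1); [-baseline, 0.5) ->
    nonviable (0); a tie at exactly 0.5 is viable (closed lower bound of the
    viable band).  Responses outside [-baseline, 1 + baseline] go to the
    nearest class code and are flagged so every sample stays accounted for.
    """
    if not 0.0 < baseline < 1.0:
        raise ConfigurationError("baseline must be in (0, 1)")
    y_hat = np.asarray(y_hat, dtype=float)
    labels = (y_hat >= 0.5).astype(int)
    flags = (y_hat < -baseline) | (y_hat > 1.0 + baseline)
    return labels, flags


# ----------------------------------------------------------------------
# cross-validated LV selection
# ----------------------------------------------------------------------
def stratified_kfold_indices(y: np.ndarray, folds: int, seed: int):
    """Per-class round-robin fold assignment after a seeded shuffle."""
    y = np.asarray(y)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < folds:
            raise SplitError(
                f"class {cls} has {idx.size} samples, fewer than {folds} "
                "folds: some fold would miss the class")
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % folds
    return [(np.flatnonzero(assignment != k), np.flatnonzero(assignment == k))
            for k in range(folds)]


def cv_error_by_lv(X, y, max_lv: int, folds: int = 10, seed: int = 0,
                   baseline: float = 0.5) -> np.ndarray:
    """Pooled misclassification rate (±0.5 rule) for A = 1..max_lv."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if max_lv < 1:
        raise ConfigurationError("max_lv must be >= 1")
    wrong = np.zeros(max_lv)
    for train, test in stratified_kfold_indices(y, folds, seed):
        a_cap = min(max_lv, len(train) - 1, X.shape[1])
        Xc = X[train] - X[train].mean(axis=0)
        yc = y[train] - y[train].mean()
        W, P, q, _, _, _ = _nipals_pls1(Xc, yc, a_cap, allow_early_stop=True)
        a_got = W.shape[1]
        Xt = X[test] - X[train].mean(axis=0)
        for a in range(1, max_lv + 1):
            b = _beta(W, P, q, min(a, a_got))
            y_hat = Xt @ b + y[train].mean()
            labels, _ = classify_by_baseline(y_hat, baseline)
            wrong[a - 1] += np.sum(labels != y[test])
    return wrong / len(y)


def select_num_lvs(X, y, max_lv: int, folds: int = 10, seed: int = 0,
                   baseline: float = 0.5) -> int:
    """Number of latent variables minimizing CV error (ties -> smallest A)."""
    errors = cv_error_by_lv(X, y, max_lv, folds=folds, seed=seed,
                            baseline=baseline)
    return int(np.argmin(errors)) + 1


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------
def fit_nipals(X, y, n_lv: int, tol: float = 1e-10,
               max_iter: int = 500, wavenumbers=None) -> PLSDAClassifier:
    """Fit a PLS-DA model with ``n_lv`` latent variables."""
    model = PLSDAClassifier(n_components=n_lv, tol=tol, max_iter=max_iter)
    return model.fit(X, y, wavenumbers=wavenumbers)


def predict_response(model: PLSDAClassifier, data) -> np.ndarray:
    return model.decision_function(data)


def diagnostics(model: PLSDAClassifier, X, confidence: float = 0.989):
    return model.diagnostics(X, confidence=confidence)
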