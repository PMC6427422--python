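"""Variable importance in projection (VIP) and threshold-based wavelength
selection.

For a fitted PLS-DA model with A components, weights w_a and explained
response sum of squares SSY_a = q_a^2 (t_a' t_a):

    VIP_j = sqrt( p * sum_a (w_ja / ||w_a||)^2 SSY_a / sum_a SSY_a )

with the normalized-weight convention, which guarantees the identity
sum_j VIP_j^2 = p.  Variables with VIP >= threshold are retained; the
threshold is chosen by scanning a grid (default 0.8..1.5 step 0.1) and
scoring a refitted reduced model by cross-validated accuracy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateSpectrumError
from .plsda import PLSDAClassifier, cv_error_by_lv, fit_nipals, select_num_lvs

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.8, 1.5001, 0.1), 10))


@dataclass
class VIPResult:
    """Per-variable VIP scores with (optionally) a selected threshold.

    ``scan_table`` rows are (threshold, n_selected, cv_accuracy) with
    ``cv_accuracy`` None when a threshold selects zero variables.
    """

    scores: np.ndarray
    threshold: float | None = None
    selected_mask: np.ndarray | None = None
    scan_table: list = field(default_factory=list)

    @property
    def n_selected(self) -> int | None:
        return None if self.selected_mask is None else int(self.selected_mask.sum())


def compute_vip(model: PLSDAClassifier) -> VIPResult:
    """VIP scores of a fitted model (normalization identity sum VIP^2 = p)."""
    if not hasattr(model, "coef_"):
        raise ConfigurationError("model is not fitted")
    if model.n_components_ < 1:
        raise ConfigurationError("VIP requires at least one latent variable")
    W = model.x_weights_
    T = model.x_scores_
    q = model.y_loadings_
    p = W.shape[0]
    ssy = q ** 2 * np.einsum("ij,ij->j", T, T)
    total = ssy.sum()
    if total <= 0:
        raise DegenerateSpectrumError(
            "explained response variance is zero (constant y after centering)")
    w_norm = W / np.linalg.norm(W, axis=0, keepdims=True)
    scores = np.sqrt(p * (w_norm ** 2 @ ssy) / total)
    return VIPResult(scores=scores)


def threshold_scan(X, y, thresholds=DEFAULT_THRESHOLDS, max_lv: int = 10,
                   folds: int = 10, seed: int = 0,
                   baseline: float = 0.5) -> VIPResult:
    """Scan VIP thresholds; refit on each selected subset and record CV
    accuracy.

    The winning threshold maximizes accuracy; ties prefer fewer variables,
    then the smaller threshold.  A threshold selecting zero variables is
    recorded with accuracy None.
    """
    thresholds = np.sort(np.asarray(list(thresholds), dtype=float))
    if thresholds.size == 0:
        raise ConfigurationError("threshold grid is empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()

    a_full = select_num_lvs(X, y, max_lv, folds=folds, seed=seed,
                            baseline=baseline)
    full = fit_nipals(X, y, a_full)
    vip = compute_vip(full)

    table = []
    best = None  # (-accuracy, n_selected, threshold)
    for thr in thresholds:
        mask = vip.scores >= thr
        n_sel = int(mask.sum())
        if n_sel == 0:
            table.append((float(thr), 0, None))
            continue
        a_cap = min(max_lv, n_sel)
        errors = cv_error_by_lv(X[:, mask], y, a_cap, folds=folds, seed=seed,
                                baseline=baseline)
        acc = float(1.0 - errors.min())
        table.append((float(thr), n_sel, acc))
        key = (-acc, n_sel, float(thr))
        if best is None or key < best:
            best = key
    if best is None:
        raise ConfigurationError("every threshold selected zero variables")
    thr = best[2]
    return VIPResult(scores=vip.scores, threshold=thr,
                     selected_mask=vip.scores >= thr, scan_table=table)
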