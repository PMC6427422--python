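"""Dataset splitting, confusion-matrix metrics and ROC analysis.

Conventions: viable (code 1) is the positive class.  Metrics follow the
chemometrics definitions

    sensitivity = tp / (tp + fn)        specificity = tn / (tn + fp)
    NER = (sensitivity + specificity)/2 ER = 1 - NER
    PREC = tp / (tp + fp)               FPR = fp / (fp + tn)

NER (non-error rate) is the mean of the class-wise sensitivities; on a
class-balanced set it coincides with overall accuracy, so both are reported.
Metrics with a zero denominator are reported as ``None`` rather than NaN.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraSet, UNKNOWN
from .errors import ConfigurationError, DataError, LabelError, SplitError


# ----------------------------------------------------------------------
@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.total == 0:
            raise ConfigurationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def layout(self) -> str:
        """Printable 2x2 layout, predicted class in columns."""
        return ("                 predicted\n"
                "               viable  nonviable\n"
                f"true viable    {self.tp:6d}  {self.fn:9d}\n"
                f"true nonviable {self.fp:6d}  {self.tn:9d}\n")


@dataclass
class EvalReport:
    """Confusion counts, proportion metrics and (optionally) the ROC sweep."""

    cm: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    ner: float | None
    er: float | None
    prec: float | None
    fpr: float | None
    accuracy: float
    roc_points: list = field(default_factory=list)
    auc: float | None = None
    crossing_threshold: float | None = None
    seed: int | None = None

    def rounded(self) -> dict:
        """Display rounding: 3 decimals for sensitivity, 2 elsewhere."""
        r = {"sensitivity": None if self.sensitivity is None
             else round(self.sensitivity, 3)}
        for k in ("specificity", "ner", "er", "prec", "fpr", "accuracy"):
            v = getattr(self, k)
            r[k] = None if v is None else round(v, 2)
        return r


# ----------------------------------------------------------------------
def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Counts with viable (1) as the positive class."""
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_labels, dtype=int).ravel()
    if t.shape != p.shape:
        raise LabelError("true and predicted label lengths differ")
    if not np.all(np.isin(t, (0, 1))) or not np.all(np.isin(p, (0, 1))):
        raise LabelError("labels must be coded 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Proportion metrics from a confusion matrix (no ROC fields)."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ner = None if sens is None or spec is None else (sens + spec) / 2.0
    return EvalReport(
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        ner=ner,
        er=None if ner is None else 1.0 - ner,
        prec=_ratio(cm.tp, cm.tp + cm.fp),
        fpr=_ratio(cm.fp, cm.fp + cm.tn),
        accuracy=(cm.tp + cm.tn) / cm.total,
    )


# ----------------------------------------------------------------------
def roc_curve(y_hat, true_labels):
    """Threshold sweep over the continuous responses.

    At each threshold t (sorted unique responses plus -inf/+inf sentinels)
    samples with y_hat >= t are called viable.  Returns
    (roc_points, auc, crossing_threshold) where roc_points is a list of
    (threshold, sensitivity, specificity), AUC is the trapezoid over
    (FPR, sensitivity), and the crossing threshold is where
    sensitivity = specificity (linear interpolation between sweep points).
    """
    s = np.asarray(y_hat, dtype=float).ravel()
    t = np.asarray(true_labels, dtype=int).ravel()
    if s.shape != t.shape:
        raise LabelError("score and label lengths differ")
    n_pos, n_neg = int(np.sum(t == 1)), int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise LabelError("both classes must be present for a ROC curve")
    thresholds = np.concatenate(([-np.inf], np.unique(s), [np.inf]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = s >= thr
        sens[i] = np.sum(pred & (t == 1)) / n_pos
        spec[i] = np.sum(~pred & (t == 0)) / n_neg
    fpr = 1.0 - spec
    # fpr is non-increasing in threshold; integrate in increasing-fpr order
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    d = sens - spec  # non-increasing in threshold
    crossing = None
    exact = np.flatnonzero(np.abs(d) < 1e-12)
    finite = np.isfinite(thresholds)
    if exact.size and finite[exact[0]]:
        crossing = float(thresholds[exact[0]])
    else:
        for i in range(len(d) - 1):
            if d[i] >= 0 >= d[i + 1]:
                lo, hi = thresholds[i], thresholds[i + 1]
                if not np.isfinite(lo):
                    crossing = float(hi) if np.isfinite(hi) else None
                elif not np.isfinite(hi) or d[i] == d[i + 1]:
                    crossing = float(lo)
                else:
                    crossing = float(lo + d[i] * (hi - lo) / (d[i] - d[i + 1]))
                break
        if crossing is None:
            crossing = float(thresholds[int(np.argmin(np.abs(d)))])
    points = [(float(thr), float(se), float(sp))
              for thr, se, sp in zip(thresholds, sens, spec)]
    return points, auc, crossing


def evaluate(true_labels, y_hat, baseline: float = 0.5,
             seed: int | None = None) -> EvalReport:
    """Full report: ±baseline classification, confusion metrics and ROC."""
    from .plsda import classify_by_baseline

    t = np.asarray(true_labels, dtype=int).ravel()
    if t.size == 0:
        raise DataError("empty test set: nothing to evaluate")
    pred, _ = classify_by_baseline(np.asarray(y_hat, dtype=float), baseline)
    report = metrics(confusion(t, pred))
    points, auc, crossing = roc_curve(y_hat, t)
    report.roc_points = points
    report.auc = auc
    report.crossing_threshold = crossing
    report.seed = seed
    return report


# ----------------------------------------------------------------------
def stratified_split(sset: SpectraSet, validation_fraction: float | None = None,
                     validation_counts=None, seed: int = 0):
    """Per-class random partition into (calibration, validation).

    Exactly one of ``validation_fraction`` (applied per class, rounded) or
    ``validation_counts`` (an int per class, or a dict label -> count) must
    be given.  Calibration and validation are disjoint by construction.
    """
    if (validation_fraction is None) == (validation_counts is None):
        raise ConfigurationError(
            "give exactly one of validation_fraction or validation_counts")
    if np.any(sset.label == UNKNOWN):
        raise LabelError("cannot stratify a set containing 'unknown' labels")
    rng = np.random.default_rng(seed)
    val_idx = []
    for cls in sorted(set(sset.label)):
        idx = np.flatnonzero(sset.label == cls)
        if validation_fraction is not None:
            if not 0.0 <= validation_fraction <= 1.0:
                raise ConfigurationError("validation_fraction outside [0, 1]")
            k = int(round(validation_fraction * idx.size))
        else:
            k = (validation_counts.get(cls)
                 if isinstance(validation_counts, dict) else validation_counts)
            if k is None:
                raise ConfigurationError(f"no validation count for class {cls!r}")
        if not 0 <= k <= idx.size:
            raise SplitError(
                f"requested {k} validation samples for class {cls!r} "
                f"with only {idx.size} available")
        perm = rng.permutation(idx)
        val_idx.append(perm[:k])
    val_idx = np.sort(np.concatenate(val_idx)) if val_idx else np.array([], int)
    mask = np.zeros(sset.n_samples, dtype=bool)
    mask[val_idx.astype(int)] = True
    return sset.subset(~mask), sset.subset(mask)
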