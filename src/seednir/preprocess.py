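"""Spectral preprocessing: row normalization, SNV, MSC, Savitzky-Golay
derivatives and wavenumber-region trimming.

All transforms are row-independent (each spectrum is treated on its own,
except MSC whose reference is estimated from the calibration set) and are
exposed both as scikit-learn-style transformers operating on 2-D arrays and
as functions operating on :class:`~seednir.dataset.SpectraSet`.

A :class:`PreprocessChain` bundles a trim interval plus an ordered list of
steps, learns any data-dependent state (the MSC reference) from calibration
data only, and can be serialized for replay on new spectra — so validation
and test data are always corrected against the calibration reference.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectraSet
from .errors import ConfigurationError, DegenerateSpectrumError

_EPS = 1e-12

NORM_MODES = ("max", "mean", "range")


def _check_divisor(div: np.ndarray, ids, what: str) -> None:
    bad = np.flatnonzero(np.abs(div) < _EPS)
    if bad.size:
        ident = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise DegenerateSpectrumError(
            f"{what} is (numerically) zero for sample {ident!r}"
        )


# ----------------------------------------------------------------------
# array-level kernels
# ----------------------------------------------------------------------
def normalize_rows(X: np.ndarray, mode: str, ids=None) -> np.ndarray:
    """Per-row normalization: ``max`` -> x/max, ``mean`` -> x/mean,
    ``range`` -> (x - min)/(max - min)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if mode == "max":
        div = X.max(axis=1)
        _check_divisor(div, ids, "row maximum")
        return X / div[:, None]
    if mode == "mean":
        div = X.mean(axis=1)
        _check_divisor(div, ids, "row mean")
        return X / div[:, None]
    if mode == "range":
        lo, hi = X.min(axis=1), X.max(axis=1)
        _check_divisor(hi - lo, ids, "row range")
        return (X - lo[:, None]) / (hi - lo)[:, None]
    raise ConfigurationError(f"unknown normalization mode {mode!r}; "
                             f"expected one of {NORM_MODES}")


def snv_rows(X: np.ndarray, ids=None) -> np.ndarray:
    """Standard normal variate: per-row (x - mean)/sd with sample SD (n-1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    _check_divisor(sd.ravel(), ids, "row standard deviation")
    return (X - mu) / sd


def msc_rows(X: np.ndarray, reference: np.ndarray | None = None,
             ids=None) -> np.ndarray:
    """Multiplicative scatter correction.

    Each row x is regressed on the reference spectrum, x ~ a + b*ref (OLS),
    and returned as (x - a)/b.  Default reference: column mean of ``X``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ConfigurationError(
            f"MSC reference length {ref.shape} != n_wavenumbers {X.shape[1]}")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom < _EPS:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    _check_divisor(b, ids, "MSC slope")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def savgol_rows(X: np.ndarray, derivative_order: int = 1,
                window_points: int = 9, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay derivative along the spectral axis, per index step.

    Edges are handled by polynomial extrapolation within the terminal window
    (scipy ``mode='interp'``).  Derivatives are with respect to the grid
    index; callers wanting per-cm^-1 units divide by step**order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window_points % 2 == 0:
        raise ConfigurationError(
            f"window_points must be odd, got {window_points}. A chemometrics "
            "'k-point window' names k points per side: use 2*k + 1 "
            "(e.g. a 4-point window -> window_points=9).")
    if polyorder < derivative_order:
        raise ConfigurationError("polyorder must be >= derivative_order")
    if window_points <= polyorder:
        raise ConfigurationError("window_points must exceed polyorder")
    if window_points > X.shape[1]:
        raise ConfigurationError("window_points exceeds spectrum length")
    return savgol_filter(X, window_length=window_points, polyorder=polyorder,
                         deriv=derivative_order, axis=1, mode="interp")


# ----------------------------------------------------------------------
# SpectraSet-level operations
# ----------------------------------------------------------------------
def normalize(sset: SpectraSet, mode: str) -> SpectraSet:
    return sset.with_absorbance(normalize_rows(sset.absorbance, mode,
                                               ids=sset.sample_ids))


def snv(sset: SpectraSet) -> SpectraSet:
    return sset.with_absorbance(snv_rows(sset.absorbance, ids=sset.sample_ids))


def msc(sset: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    return sset.with_absorbance(msc_rows(sset.absorbance, reference,
                                         ids=sset.sample_ids))


def savgol_derivative(sset: SpectraSet, derivative_order: int = 1,
                      window_points: int = 9, polyorder: int = 2,
                      per_wavenumber: bool = False) -> SpectraSet:
    out = savgol_rows(sset.absorbance, derivative_order, window_points, polyorder)
    if per_wavenumber:
        out = out / sset.step ** derivative_order
    return sset.with_absorbance(out)


def trim_region(sset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep columns with lo <= wn <= hi (closed interval on grid values)."""
    if not lo < hi:
        raise ConfigurationError("trim requires lo < hi")
    mask = (sset.wavenumbers >= lo) & (sset.wavenumbers <= hi)
    if not mask.any():
        raise ConfigurationError(
            f"trim interval [{lo}, {hi}] does not overlap the data range "
            f"[{sset.wavenumbers[0]}, {sset.wavenumbers[-1]}]")
    return sset.select_wavenumbers(mask)


# ----------------------------------------------------------------------
# scikit-learn transformers
# ----------------------------------------------------------------------
class RowNormalizer(BaseEstimator, TransformerMixin):
    """Stateless per-row normalization (mode: max, mean or range)."""

    def __init__(self, mode: str = "max"):
        self.mode = mode

    def fit(self, X, y=None):
        self.n_features_in_ = np.atleast_2d(X).shape[1]
        return self

    def transform(self, X):
        return normalize_rows(X, self.mode)


class SNV(BaseEstimator, TransformerMixin):
    """Standard normal variate (per-row standardization, sample SD)."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.atleast_2d(X).shape[1]
        return self

    def transform(self, X):
        return snv_rows(X)


class MSC(BaseEstimator, TransformerMixin):
    """Multiplicative scatter correction against the calibration mean.

    ``fit`` stores the column-mean reference (or a user-supplied one), so new
    data are corrected against the calibration reference — no leakage.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.reference_ = (X.mean(axis=0) if self.reference is None
                           else np.asarray(self.reference, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return msc_rows(X, self.reference_)


class SavitzkyGolayDerivative(BaseEstimator, TransformerMixin):
    """Savitzky-Golay derivative filter along the spectral axis."""

    def __init__(self, derivative_order: int = 1, window_points: int = 9,
                 polyorder: int = 2):
        self.derivative_order = derivative_order
        self.window_points = window_points
        self.polyorder = polyorder

    def fit(self, X, y=None):
        self.n_features_in_ = np.atleast_2d(X).shape[1]
        return self

    def transform(self, X):
        return savgol_rows(X, self.derivative_order, self.window_points,
                           self.polyorder)


# ----------------------------------------------------------------------
# chain
# ----------------------------------------------------------------------
_STEP_PARAMS = {
    "max_norm": (), "mean_norm": (), "range_norm": (), "snv": (),
    "msc": (),
    "savgol": ("derivative_order", "window_points", "polyorder"),
}


class PreprocessChain:
    """Ordered preprocessing recipe: trim interval then a list of steps.

    ``steps`` is a list of dicts like ``{"op": "savgol",
    "derivative_order": 1, "window_points": 9, "polyorder": 2}`` with ops in
    {max_norm, mean_norm, range_norm, snv, msc, savgol}.  ``fit`` learns the
    MSC reference(s) from the calibration set; ``apply`` replays the exact
    chain on any spectra sharing the raw axis.
    """

    def __init__(self, steps=None, trim=None, name: str | None = None):
        self.steps = [dict(s) for s in (steps or [])]
        self.trim = tuple(trim) if trim is not None else None
        self.name = name or "chain"
        for s in self.steps:
            op = s.get("op")
            if op not in _STEP_PARAMS:
                raise ConfigurationError(f"unknown preprocessing op {op!r}")
        self._references = None
        self.trained_wavenumbers_ = None

    @property
    def fitted(self) -> bool:
        return self._references is not None

    def _run(self, sset: SpectraSet, references, learn: bool) -> SpectraSet:
        out = sset
        if self.trim is not None:
            out = trim_region(out, *self.trim)
        for i, step in enumerate(self.steps):
            op = step["op"]
            if op in ("max_norm", "mean_norm", "range_norm"):
                out = normalize(out, op.split("_")[0])
            elif op == "snv":
                out = snv(out)
            elif op == "msc":
                if learn:
                    references[i] = out.absorbance.mean(axis=0)
                out = msc(out, references[i])
            elif op == "savgol":
                out = savgol_derivative(
                    out,
                    derivative_order=step.get("derivative_order", 1),
                    window_points=step.get("window_points", 9),
                    polyorder=step.get("polyorder", 2))
        return out

    def fit(self, calibration: SpectraSet) -> "PreprocessChain":
        refs: dict = {}
        out = self._run(calibration, refs, learn=True)
        self._references = refs
        self.trained_wavenumbers_ = out.wavenumbers.copy()
        return self

    def fit_apply(self, calibration: SpectraSet) -> SpectraSet:
        refs: dict = {}
        out = self._run(calibration, refs, learn=True)
        self._references = refs
        self.trained_wavenumbers_ = out.wavenumbers.copy()
        return out

    def apply(self, sset: SpectraSet) -> SpectraSet:
        if not self.fitted:
            raise ConfigurationError("PreprocessChain must be fitted before apply()")
        return self._run(sset, self._references, learn=False)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {"name": self.name, "trim": list(self.trim) if self.trim else None,
             "steps": [dict(s) for s in self.steps]}
        if self.fitted:
            d["msc_references"] = {str(i): r.tolist()
                                   for i, r in self._references.items()}
            d["trained_wavenumbers"] = self.trained_wavenumbers_.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessChain":
        chain = cls(steps=d.get("steps"), trim=d.get("trim"), name=d.get("name"))
        if "trained_wavenumbers" in d:
            chain._references = {int(i): np.asarray(r, dtype=float)
                                 for i, r in d.get("msc_references", {}).items()}
            chain.trained_wavenumbers_ = np.asarray(d["trained_wavenumbers"],
                                                    dtype=float)
        return chain
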