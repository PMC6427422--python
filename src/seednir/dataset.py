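"""Spectra container and delimited-table I/O.

A :class:`SpectraSet` holds an absorbance matrix (samples x wavenumbers)
together with the wavenumber axis (cm^-1, strictly ascending, uniformly
spaced) and per-sample metadata: id, variety and viability label.  Labels use
the 0/1 response coding standard in two-class PLS-DA: nonviable -> 0,
viable -> 1; ``unknown`` is a legal label for prediction-only data.

The on-disk format is a UTF-8 CSV with columns
``sample_id,variety,label,<wn1>,<wn2>,...`` where the remaining headers are
wavenumbers in cm^-1.  Floats are written with ``repr`` so a write/read
round trip is exact.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, LabelError

VIABLE = "viable"
NONVIABLE = "nonviable"
UNKNOWN = "unknown"
LABELS = (VIABLE, NONVIABLE, UNKNOWN)

#: 0/1 response coding used throughout the package.
CLASS_CODE = {NONVIABLE: 0, VIABLE: 1}
CODE_CLASS = {0: NONVIABLE, 1: VIABLE}

METADATA_COLUMNS = ("sample_id", "variety", "label")

_AXIS_RTOL = 1e-9


def _validate_axis(wavenumbers: np.ndarray) -> None:
    if wavenumbers.ndim != 1 or wavenumbers.size == 0:
        raise FormatError("wavenumber axis must be a non-empty 1-D vector")
    if not np.all(np.isfinite(wavenumbers)):
        raise FormatError("wavenumber axis contains non-finite values")
    if wavenumbers.size > 1:
        d = np.diff(wavenumbers)
        if np.any(d <= 0):
            raise FormatError("wavenumbers must be strictly increasing")
        step = d.mean()
        if np.any(np.abs(d - step) > _AXIS_RTOL * abs(step)):
            raise FormatError("wavenumber axis is not uniformly spaced")


@dataclass(eq=False)
class SpectraSet:
    """Absorbance matrix plus axis and per-sample metadata.

    Parameters
    ----------
    wavenumbers : array of float, shape (p,)
        Strictly ascending, uniformly spaced axis in cm^-1.
    absorbance : array of float, shape (n, p)
        Absorbance units; all values finite.
    sample_ids : array of str, shape (n,)
        Unique identifiers.
    variety : array of str, shape (n,)
    label : array of str, shape (n,)
        Each in {"viable", "nonviable", "unknown"}.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    variety: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variety = np.asarray(self.variety, dtype=object)
        self.label = np.asarray(self.label, dtype=object)
        _validate_axis(self.wavenumbers)
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise FormatError(
                f"absorbance has {p} columns but axis has {self.wavenumbers.size}"
            )
        for name, arr in (("sample_ids", self.sample_ids),
                          ("variety", self.variety), ("label", self.label)):
            if arr.shape != (n,):
                raise FormatError(f"{name} length {arr.shape} != n_samples {n}")
        if not np.all(np.isfinite(self.absorbance)):
            raise FormatError("absorbance matrix contains non-finite values")
        if len(set(self.sample_ids)) != n:
            raise FormatError("sample_ids are not unique")
        bad = set(self.label) - set(LABELS)
        if bad:
            raise LabelError(f"unrecognized labels: {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    @property
    def step(self) -> float:
        if self.wavenumbers.size < 2:
            return float("nan")
        return float(np.diff(self.wavenumbers).mean())

    def y(self) -> np.ndarray:
        """0/1 class codes (nonviable=0, viable=1); error if any label is unknown."""
        if np.any(self.label == UNKNOWN):
            raise LabelError("dataset contains 'unknown' labels; no class code available")
        return np.array([CLASS_CODE[l] for l in self.label], dtype=int)

    def is_labelled(self) -> bool:
        return bool(np.all(self.label != UNKNOWN))

    # ------------------------------------------------------------------
    def with_absorbance(self, absorbance: np.ndarray,
                        wavenumbers: np.ndarray | None = None) -> "SpectraSet":
        """Copy with a new matrix (and optionally a new axis); metadata shared."""
        return SpectraSet(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            absorbance=absorbance,
            sample_ids=self.sample_ids,
            variety=self.variety,
            label=self.label,
        )

    def subset(self, rows) -> "SpectraSet":
        """Row subset by integer or boolean index."""
        rows = np.asarray(rows)
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[rows],
            sample_ids=self.sample_ids[rows],
            variety=self.variety[rows],
            label=self.label[rows],
        )

    def select_wavenumbers(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        return self.with_absorbance(self.absorbance[:, mask],
                                    wavenumbers=self.wavenumbers[mask])

    def equals(self, other: "SpectraSet", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Field-by-field equality (exact by default)."""
        return (
            self.absorbance.shape == other.absorbance.shape
            and np.allclose(self.wavenumbers, other.wavenumbers, rtol=rtol, atol=atol)
            and np.allclose(self.absorbance, other.absorbance, rtol=rtol, atol=atol)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.variety, other.variety)
            and np.array_equal(self.label, other.label)
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def write_spectra(sset: SpectraSet, path) -> None:
    """Write a SpectraSet as CSV (see module docstring for the dialect)."""
    meta = pd.DataFrame({
        "sample_id": sset.sample_ids,
        "variety": sset.variety,
        "label": sset.label,
    })
    spectra = pd.DataFrame(sset.absorbance,
                           columns=[repr(float(w)) for w in sset.wavenumbers])
    pd.concat([meta.reset_index(drop=True), spectra], axis=1).to_csv(path, index=False)


def read_spectra(path) -> SpectraSet:
    """Read a spectra CSV; wavenumber columns are sorted ascending on load."""
    df = pd.read_csv(path, dtype={c: str for c in METADATA_COLUMNS})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing metadata columns: {missing}")
    wn_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not wn_cols:
        raise FormatError("no wavenumber columns found")
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from None
    order = np.argsort(wn)
    X = df[wn_cols].to_numpy(dtype=float)[:, order]
    ids = df["sample_id"].to_numpy(dtype=object)
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_id values in file")
    return SpectraSet(
        wavenumbers=wn[order],
        absorbance=X,
        sample_ids=ids,
        variety=df["variety"].to_numpy(dtype=object),
        label=df["label"].to_numpy(dtype=object),
    )
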