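import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import seednir as sn
from seednir.errors import ConfigurationError, DegenerateSpectrumError
from seednir.preprocess import (PreprocessChain, msc_rows, normalize_rows,
                                savgol_rows, snv_rows)


def _set(X, wn=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    wn = np.arange(p, dtype=float) * 4 + 4000 if wn is None else wn
    return sn.SpectraSet(wavenumbers=wn, absorbance=X,
                         sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
                         variety=np.array(["V1"] * n, dtype=object),
                         label=np.array(["unknown"] * n, dtype=object))


# ---------------------------------------------------------------- normalize
@pytest.mark.parametrize("row,mode,expected", [
    ([2.0, 4.0], "max", [0.5, 1.0]),
    ([1.0, 3.0], "range", [0.0, 1.0]),
    ([2.0, 4.0], "mean", [2 / 3, 4 / 3]),
])
def test_normalize_examples(row, mode, expected):
    out = normalize_rows(np.array([row]), mode)
    assert np.allclose(out[0], expected, atol=1e-15)


def test_normalize_mean_result_has_unit_mean():
    out = normalize_rows(np.random.default_rng(0).random((5, 30)) + 0.5, "mean")
    assert np.allclose(out.mean(axis=1), 1.0, atol=1e-12)


def test_normalize_degenerate_names_sample(tiny_set):
    flat = tiny_set.with_absorbance(np.zeros_like(tiny_set.absorbance))
    with pytest.raises(DegenerateSpectrumError, match="'a'"):
        sn.normalize(flat, "max")


# ---------------------------------------------------------------- snv
def test_snv_example_and_moments():
    out = snv_rows(np.array([[1.0, 2.0, 3.0]]))
    assert np.allclose(out[0], [-1.0, 0.0, 1.0], atol=1e-14)
    X = np.random.default_rng(1).random((8, 40))
    out = snv_rows(X)
    assert np.all(np.abs(out.mean(axis=1)) < 1e-12)
    assert np.all(np.abs(out.std(axis=1, ddof=1) - 1) < 1e-12)


def test_snv_idempotent_and_affine_invariant():
    X = np.random.default_rng(2).random((6, 25))
    once = snv_rows(X)
    assert np.allclose(snv_rows(once), once, atol=1e-12)
    corrupted = 3.0 + 1.7 * X  # b > 0 affine corruption per row
    assert np.allclose(snv_rows(corrupted), once, atol=1e-10)


def test_snv_constant_row_rejected():
    with pytest.raises(DegenerateSpectrumError):
        snv_rows(np.ones((1, 10)))


# ---------------------------------------------------------------- msc
def test_msc_identity_and_affine_case():
    ref = np.linspace(0.2, 1.0, 30) + np.sin(np.linspace(0, 6, 30)) * 0.1
    assert np.allclose(msc_rows(ref[None, :], ref)[0], ref, atol=1e-12)
    assert np.allclose(msc_rows((3.0 + 2.0 * ref)[None, :], ref)[0], ref,
                       atol=1e-10)


def test_msc_matches_normal_equation_oracle():
    rng = np.random.default_rng(3)
    ref = rng.random(20)
    X = rng.random((10, 20))
    out = msc_rows(X, ref)
    for i, x in enumerate(X):
        # independent closed-form two-parameter least squares
        A = np.column_stack([np.ones(20), ref])
        a, b = np.linalg.solve(A.T @ A, A.T @ x)
        assert np.allclose(out[i], (x - a) / b, atol=1e-10)


def test_msc_recovers_unscattered_spectra(quiet_config):
    """MSC against the true underlying spectrum inverts the generator's
    affine scatter model exactly when noise is zero (within one class and
    variety all unscattered spectra coincide)."""
    base = quiet_config.to_dict()
    base["variety_baselines"] = {"V1": (0.0, 0.0)}
    base["germination_rates"] = {"V1": 0.87}
    clean = sn.simulate_spectra(sn.SimulationConfig(**base), 1, seed=0)
    template = clean.absorbance[clean.label == "viable"][0]
    scattered_cfg = sn.SimulationConfig(**{**base, "scatter_slope_sd": 0.2,
                                           "scatter_offset_sd": 0.1})
    scattered = sn.simulate_spectra(scattered_cfg, 5, seed=1)
    viable = scattered.subset(scattered.label == "viable")
    corrected = sn.msc(viable, reference=template)
    assert np.allclose(corrected.absorbance,
                       np.tile(template, (viable.n_samples, 1)), atol=1e-8)


# ---------------------------------------------------------------- savgol
def test_savgol_constant_and_ramp():
    const = savgol_rows(np.full((1, 50), 3.7), derivative_order=1)
    assert np.allclose(const, 0.0, atol=1e-12)
    ramp = savgol_rows(0.25 * np.arange(50)[None, :], derivative_order=1)
    assert np.allclose(ramp, 0.25, atol=1e-10)


def test_savgol_second_derivative_exact_on_quadratic():
    i = np.arange(60, dtype=float)
    q = 0.5 * i ** 2 - 3 * i + 2          # second finite difference = 1.0
    out = savgol_rows(q[None, :], derivative_order=2, window_points=9,
                      polyorder=2)
    assert np.allclose(out, 1.0, atol=1e-8)


def test_savgol_even_window_message_explains_mapping():
    with pytest.raises(ConfigurationError, match="2\\*k \\+ 1"):
        savgol_rows(np.zeros((1, 20)), window_points=4)


# ---------------------------------------------------------------- trim
def test_trim_grid_counts():
    s = sn.simulate_spectra(sn.SimulationConfig(), 1)
    assert sn.trim_region(s, 4000, 9000).n_wavenumbers == 1251
    assert sn.trim_region(s, 5000, 5000.5).n_wavenumbers == 1  # one grid point
    assert sn.trim_region(s, 4002, 4006).n_wavenumbers == 1    # only 4004
    assert np.array_equal(sn.trim_region(s, 4002, 4006).wavenumbers, [4004.0])


def test_trim_outside_range_rejected(tiny_set):
    with pytest.raises(ConfigurationError, match="overlap"):
        sn.trim_region(tiny_set, 9990, 9999)


# ------------------------------------------------------- shared properties
@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_transforms_commute_with_row_permutation(seed):
    rng = np.random.default_rng(seed)
    X = rng.random((6, 30)) + 0.5
    perm = rng.permutation(6)
    for fn in (lambda a: normalize_rows(a, "max"), snv_rows,
               lambda a: msc_rows(a, a.mean(axis=0)),
               lambda a: savgol_rows(a, 1, 9, 2)):
        assert np.allclose(fn(X)[perm], fn(X[perm]), atol=1e-12)


def test_transforms_preserve_shape(tiny_set):
    labelled = tiny_set
    for fn in (lambda s: sn.normalize(s, "mean"), sn.snv, sn.msc,
               lambda s: sn.savgol_derivative(s, 1, window_points=3,
                                              polyorder=1)):
        assert fn(labelled).absorbance.shape == labelled.absorbance.shape


# ---------------------------------------------------------------- chain
def test_chain_replays_msc_reference_from_calibration():
    cfg = sn.SimulationConfig(rng_seed=5)
    data = sn.simulate_spectra(cfg, 6)
    cal, val = sn.stratified_split(data, validation_counts=4, seed=0)
    chain = PreprocessChain(steps=[{"op": "msc"}], trim=(4000, 9000))
    cal_p = chain.fit_apply(cal)
    val_p = chain.apply(val)
    # round trip through the serialized document
    chain2 = PreprocessChain.from_dict(chain.to_dict())
    assert np.array_equal(chain2.apply(val).absorbance, val_p.absorbance)
    # the stored reference comes from calibration, not from the applied set
    ref = chain.to_dict()["msc_references"]["0"]
    trimmed_cal = sn.trim_region(cal, 4000, 9000)
    assert np.allclose(ref, trimmed_cal.absorbance.mean(axis=0))
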