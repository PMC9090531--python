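"""Preprocessing tests with independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirsimca import (
    DesignEntry,
    NoiseModel,
    PreprocessConfig,
    SamplingDesign,
    WavelengthGrid,
    crop,
    default_recipe_library,
    msc_apply,
    msc_fit,
    preprocess_pipeline,
    savgol_derivative,
    simulate,
)
from conftest import make_spectrum_set


# ---------------------------------------------------------------- crop

def test_crop_inclusive_definition():
    grid = np.arange(900.0, 1700.0, 3.52)
    data = make_spectrum_set(np.random.default_rng(0).normal(size=(3, grid.size)), grid)
    out = crop(data, 1085.0, 1601.0)
    lam = out.grid.values
    assert np.all((lam >= 1085.0) & (lam <= 1601.0))
    assert out.metadata.equals(data.metadata)


def test_crop_identity_and_count_oracle():
    grid = WavelengthGrid.default()
    data = make_spectrum_set(np.ones((2, len(grid))), grid.values)
    full = crop(data, grid.values[0], grid.values[-1])
    assert np.array_equal(full.absorbance, data.absorbance)
    out = crop(data, 1085.0, 1601.0)
    # independent brute-force scan of the grid
    expected = sum(1 for w in grid.values if 1085.0 <= w <= 1601.0)
    assert out.n_channels == expected


def test_crop_errors():
    data = make_spectrum_set(np.ones((2, 64)))
    with pytest.raises(ValueError, match="no channels"):
        crop(data, 10.0, 20.0)
    with pytest.raises(ValueError, match="at least 8"):
        crop(data, 900.0, 930.0)


# ---------------------------------------------------------------- savgol

def test_savgol_constant_gives_zero():
    data = make_spectrum_set(np.full((2, 64), 3.7))
    out = savgol_derivative(data, 11, 2, 2)
    assert np.allclose(out.absorbance, 0.0, atol=1e-12)
    half = 5
    assert np.array_equal(out.grid.values, data.grid.values[half:-half])


@given(a=st.floats(-5, 5), b=st.floats(-5, 5), c=st.floats(-5, 5))
def test_savgol_exact_on_quadratic(a, b, c):
    """SG with polyorder 2 reproduces the 2nd derivative of any quadratic."""
    lam = np.linspace(1000.0, 1300.0, 80)
    lam0 = lam.mean()
    x = a * (lam - lam0) ** 2 + b * (lam - lam0) + c
    data = make_spectrum_set(x[None, :], lam)
    out = savgol_derivative(data, 11, 2, 2)
    assert np.allclose(out.absorbance, 2 * a, atol=1e-9 + 1e-9 * abs(a))


def test_savgol_matches_windowed_polyfit_oracle():
    """Brute-force oracle: per-channel quadratic LSQ fit over the window."""
    rng = np.random.default_rng(5)
    lam = np.linspace(900.0, 1700.0, 120)
    x = rng.normal(size=lam.size)
    data = make_spectrum_set(x[None, :], lam)
    window, half = 11, 5
    out = savgol_derivative(data, window, 2, 2)
    for k in range(half, lam.size - half):
        lw = lam[k - half:k + half + 1]
        xw = x[k - half:k + half + 1]
        coef = np.polyfit(lw - lam[k], xw, 2)  # c2 z^2 + c1 z + c0
        assert out.absorbance[0, k - half] == pytest.approx(2 * coef[0], abs=1e-8)


def test_savgol_errors():
    data = make_spectrum_set(np.ones((1, 40)))
    with pytest.raises(ValueError, match="odd"):
        savgol_derivative(data, 10, 2, 2)
    with pytest.raises(ValueError, match="exceed"):
        savgol_derivative(data, 3, 3, 2)
    with pytest.raises(ValueError, match="deriv"):
        savgol_derivative(data, 11, 2, 3)
    with pytest.raises(ValueError, match="channel count"):
        savgol_derivative(data, 41, 2, 2)


# ---------------------------------------------------------------- MSC

def test_msc_fit_is_mean():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(7, 50))
    ref = msc_fit(make_spectrum_set(X))
    assert np.allclose(ref.values, X.mean(axis=0))
    r = rng.normal(size=50)
    ref2 = msc_fit(make_spectrum_set(np.vstack([r, 2 * r])))
    assert np.allclose(ref2.values, 1.5 * r)


def test_msc_fit_errors():
    with pytest.raises(ValueError, match="at least 2"):
        msc_fit(make_spectrum_set(np.ones((1, 40))))
    with pytest.raises(ValueError, match="constant"):
        msc_fit(make_spectrum_set(np.ones((3, 40))))


@given(a=st.floats(-10, 10), b=st.floats(0.1, 10))
def test_msc_inverts_affine_distortion(a, b):
    rng = np.random.default_rng(2)
    r = rng.normal(size=60)
    ref = msc_fit(make_spectrum_set(np.vstack([r, r, r + rng.normal(0, 1e-9, 60)])))
    distorted = make_spectrum_set((a + b * r)[None, :])
    out = msc_apply(distorted, ref)
    assert np.allclose(out.absorbance[0], r, atol=1e-7)


def test_msc_matches_normal_equation_oracle():
    rng = np.random.default_rng(3)
    r = rng.normal(size=80)
    X = rng.normal(size=(5, 80))
    ref = msc_fit(make_spectrum_set(np.vstack([r, 3 * r])))  # ref = 2r
    out = msc_apply(make_spectrum_set(X), ref)
    for i in range(5):
        b, a = np.polyfit(ref.values, X[i], 1)  # oracle OLS x = a + b*ref
        assert np.allclose(out.absorbance[i], (X[i] - a) / b, atol=1e-9)


def test_msc_zero_slope_error_names_sample():
    r = np.linspace(0.0, 1.0, 40)
    ref = msc_fit(make_spectrum_set(np.vstack([r, r * 2])))
    flat = make_spectrum_set(np.ones((1, 40)))
    with pytest.raises(ValueError, match="TestBrand_s0000"):
        msc_apply(flat, ref)


def test_msc_idempotence():
    """Re-correcting an already mean-corrected set changes nothing (<1e-8)."""
    rng = np.random.default_rng(4)
    base = np.abs(rng.normal(1, 0.3, 50)).cumsum()
    X = np.array([a + b * base for a, b in rng.normal([0, 1], [0.2, 0.1], (8, 2))])
    data = make_spectrum_set(X)
    ref1 = msc_fit(data)
    corrected = msc_apply(data, ref1)
    ref2 = msc_fit(corrected)
    twice = msc_apply(corrected, ref2)
    assert np.max(np.abs(twice.absorbance - corrected.absorbance)) < 1e-8


# ---------------------------------------------------------------- pipeline

def _scatter_only_noise():
    return NoiseModel(
        multiplicative_scatter_sd=0.1,
        additive_offset_sd=0.05,
        baseline_slope_sd=0.0,
        batch_amplitude_sd=0.0,
        channel_noise_sd_core=0.0,
        channel_noise_sd_edges=0.0,
    )


def test_pipeline_removes_simulated_scatter():
    """Mult/add scatter with no channel noise vanishes after crop+SG+MSC."""
    lib = default_recipe_library()
    design = SamplingDesign((DesignEntry(lib["Maloxine"], 1, 20, "licit"),))
    data = simulate(design, _scatter_only_noise(), WavelengthGrid.default(), seed=9)
    assert data.absorbance.var(axis=0).max() > 1e-5  # scatter is really there
    prep, _ = preprocess_pipeline(data, PreprocessConfig())
    assert prep.absorbance.var(axis=0).max() < 1e-10


def test_pipeline_training_then_test_mode_identical():
    rng = np.random.default_rng(6)
    data = make_spectrum_set(rng.normal(size=(6, 228)).cumsum(axis=1),
                             WavelengthGrid.default().values)
    cfg = PreprocessConfig()
    out_train, ref = preprocess_pipeline(data, cfg)
    out_test, _ = preprocess_pipeline(data, cfg, ref)
    assert np.array_equal(out_train.absorbance, out_test.absorbance)


def test_pipeline_equals_manual_stage_composition():
    rng = np.random.default_rng(7)
    data = make_spectrum_set(rng.normal(size=(5, 228)).cumsum(axis=1),
                             WavelengthGrid.default().values)
    cfg = PreprocessConfig()
    out, ref = preprocess_pipeline(data, cfg)
    manual = crop(data, cfg.crop_low, cfg.crop_high)
    manual = savgol_derivative(manual, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
    manual_ref = msc_fit(manual)
    manual = msc_apply(manual, manual_ref)
    assert np.array_equal(out.absorbance, manual.absorbance)
    assert np.array_equal(ref.values, manual_ref.values)


def test_pipeline_order_is_crop_first():
    """crop->SG->MSC is pinned: applying SG before crop gives different output."""
    rng = np.random.default_rng(8)
    grid = WavelengthGrid.default()
    # noisy edges make the order matter through the MSC reference
    X = rng.normal(size=(6, 228)).cumsum(axis=1)
    data = make_spectrum_set(X, grid.values)
    cfg = PreprocessConfig()
    pipe, _ = preprocess_pipeline(data, cfg)
    alt = savgol_derivative(data, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
    alt = msc_apply(alt, msc_fit(alt))
    alt = crop(alt, cfg.crop_low, cfg.crop_high)
    common = np.isin(np.round(alt.grid.values, 6), np.round(pipe.grid.values, 6))
    assert not np.allclose(alt.absorbance[:, common], pipe.absorbance)
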