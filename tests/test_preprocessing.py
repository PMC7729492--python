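"""Water-vapor compensation, vector normalization and the analysis chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gaussian
from ftiri.errors import (ConfigurationError, DegenerateSpectrumError,
                          RangeError)
from ftiri.hypermap import SpectralAxis
from ftiri.preprocessing import (analysis_axis, compensate_water_vapor,
                                 normalize_map, preprocess_for_analysis,
                                 preprocess_map, vector_normalize)
from ftiri.synthetic import class_config, simulate_map
from ftiri.vapor import VAPOR_WINDOW, vapor_reference


@pytest.fixture(scope="module")
def axis():
    return SpectralAxis(800.0 + 4.0 * np.arange(801))


# ---------------------------------------------------------------------------
# vapor compensation
# ---------------------------------------------------------------------------

def test_constructed_alpha_recovered_exactly(axis):
    """clean + 0.7 * reference recovers alpha = 0.7 and the clean spectrum."""
    w = axis.wavenumbers
    clean = gaussian(w, 2925, 14, 0.3) + gaussian(w, 1160, 14, 0.2)
    out, alpha = compensate_water_vapor(
        clean + 0.7 * vapor_reference(w), axis)
    assert alpha == pytest.approx(0.7, abs=1e-6)
    np.testing.assert_allclose(out, clean, atol=1e-6)


def test_uncontaminated_spectrum_unchanged(axis):
    w = axis.wavenumbers
    clean = gaussian(w, 2925, 14, 0.3) + gaussian(w, 1160, 14, 0.2)
    out, alpha = compensate_water_vapor(clean, axis)
    assert alpha == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(out, clean, atol=1e-9)


def test_noisy_vapor_lines_suppressed(axis):
    """With simulator-default noise, vapor residual RMS drops >= 90%."""
    w = axis.wavenumbers
    sel = (w >= VAPOR_WINDOW[0]) & (w <= VAPOR_WINDOW[1])
    rng = np.random.default_rng(0)
    clean = class_config("III").cytoplasm.spectrum(w)
    reductions = []
    for _ in range(20):
        noise = rng.normal(0.0, 0.002, size=w.size)
        x = clean + noise + 0.03 * vapor_reference(w)
        out, _ = compensate_water_vapor(x, axis)
        before = np.sqrt(np.mean((x - clean - noise)[sel] ** 2))
        after = np.sqrt(np.mean((out - clean - noise)[sel] ** 2))
        reductions.append(1.0 - after / before)
    assert min(reductions) >= 0.90


def test_zero_reference_rejected(axis):
    with pytest.raises(ConfigurationError, match="identically zero"):
        compensate_water_vapor(np.ones(801), axis,
                               reference=np.zeros(801))


def test_negative_fit_clamped_at_zero(axis):
    w = axis.wavenumbers
    x = -0.5 * vapor_reference(w)
    out, alpha = compensate_water_vapor(x, axis)
    assert alpha == 0.0
    np.testing.assert_array_equal(out, x)


# ---------------------------------------------------------------------------
# vector normalization
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(scale=st.floats(0.01, 100.0),
       seed=st.integers(0, 2**16))
def test_normalization_scale_invariance(scale, seed):
    axis = SpectralAxis(900.0 + 2.0 * np.arange(200))
    rng = np.random.default_rng(seed)
    spectrum = rng.uniform(0.1, 1.0, size=200)
    a, _ = vector_normalize(spectrum, axis)
    b, _ = vector_normalize(scale * spectrum, axis)
    np.testing.assert_allclose(a, b, atol=1e-9)
    assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-9)


def test_unit_impulse_unchanged():
    axis = SpectralAxis(900.0 + 2.0 * np.arange(50))
    impulse = np.zeros(50)
    impulse[17] = 1.0
    out, norm = vector_normalize(impulse, axis)
    np.testing.assert_array_equal(out, impulse)
    assert norm == 1.0


def test_constant_becomes_inverse_sqrt_n():
    n = 64
    axis = SpectralAxis(900.0 + 2.0 * np.arange(n))
    out, _ = vector_normalize(np.full(n, 3.7), axis)
    np.testing.assert_allclose(out, 1.0 / np.sqrt(n), rtol=1e-12)


def test_zero_spectrum_in_range_degenerate():
    axis = SpectralAxis(900.0 + 2.0 * np.arange(100))
    values = np.zeros(100)
    values[80:] = 1.0   # nonzero only outside the requested range
    with pytest.raises(DegenerateSpectrumError):
        vector_normalize(values, axis, lo=900.0, hi=1000.0)


def test_out_of_range_window_rejected():
    axis = SpectralAxis(900.0 + 2.0 * np.arange(100))
    with pytest.raises(RangeError):
        vector_normalize(np.ones(100), axis, lo=800.0, hi=1000.0)


# ---------------------------------------------------------------------------
# analysis-level chain
# ---------------------------------------------------------------------------

def test_straight_line_input_degenerates(axis):
    w = axis.wavenumbers
    with pytest.raises(DegenerateSpectrumError):
        preprocess_for_analysis(0.001 * w + 0.2, axis)


def test_pure_gaussian_only_normalized(axis):
    """A band on zero baseline: the baseline step changes ~nothing."""
    w = axis.wavenumbers
    g = gaussian(w, 1655, 20, 1.0)
    out, out_axis, record = preprocess_for_analysis(g, axis)
    expected = np.interp(out_axis.wavenumbers, w, g)
    expected /= np.linalg.norm(expected)
    np.testing.assert_allclose(out, expected, atol=1e-6)
    assert [r["step"] for r in record] == [
        "interpolate", "two_point_baseline", "vector_normalization"]


def test_affine_offsets_removed_exactly(axis):
    """Gaussian + (a*nu + b) preprocesses identically to the Gaussian alone."""
    w = axis.wavenumbers
    g = gaussian(w, 1655, 20, 1.0)
    with_line = g + 0.001 * w + 0.2
    a, _, _ = preprocess_for_analysis(g, axis)
    b, _, _ = preprocess_for_analysis(with_line, axis)
    np.testing.assert_allclose(a, b, atol=1e-6)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(slope=st.floats(-0.01, 0.01), offset=st.floats(-1.0, 1.0),
       seed=st.integers(0, 2**16))
def test_two_point_baseline_annihilates_any_affine_term(slope, offset, seed):
    axis = SpectralAxis(800.0 + 4.0 * np.arange(801))
    w = axis.wavenumbers
    rng = np.random.default_rng(seed)
    base = gaussian(w, 1655, 20, rng.uniform(0.5, 2.0)) + \
        gaussian(w, 2925, 14, rng.uniform(0.1, 0.5))
    a, _, _ = preprocess_for_analysis(base, axis)
    b, _, _ = preprocess_for_analysis(base + slope * w + offset, axis)
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_chain_is_idempotent(axis):
    w = axis.wavenumbers
    spectrum = gaussian(w, 1655, 20, 1.0) + gaussian(w, 2925, 14, 0.3) + \
        0.001 * w + 0.1
    once, once_axis, _ = preprocess_for_analysis(spectrum, axis)
    twice, _, _ = preprocess_for_analysis(once, once_axis)
    np.testing.assert_allclose(twice, once, atol=1e-9)
    assert once[0] == 0.0 and once[-1] == 0.0
    assert np.linalg.norm(once) == pytest.approx(1.0, abs=1e-9)


def test_insufficient_range_names_missing_ends():
    axis = SpectralAxis(1000.0 + 2.0 * np.arange(500))
    with pytest.raises(RangeError, match="low end .* 1000"):
        preprocess_for_analysis(np.ones(500), axis)
    axis = SpectralAxis(900.0 + 2.0 * np.arange(500))
    with pytest.raises(RangeError, match="high end .* 1898"):
        preprocess_for_analysis(np.ones(500), axis)


def test_analysis_axis_spans_exact_range():
    ax = analysis_axis()
    assert ax.lo == 900.0 and ax.hi == 3050.0
    assert np.allclose(np.diff(ax.wavenumbers), 2.0)


# ---------------------------------------------------------------------------
# map-level chain
# ---------------------------------------------------------------------------

def test_map_chain_preserves_shape_axis_and_zeroes_background():
    cfg = class_config("III", map_height_um=81.92, map_width_um=81.92,
                       n_droplets=0, seed=1)
    hmap, truth = simulate_map(cfg)
    pre = preprocess_map(hmap)
    assert pre.shape == hmap.shape
    assert pre.axis == hmap.axis
    norms = np.linalg.norm(pre.spectra(), axis=1)
    labels = truth.mask.labels.ravel()
    np.testing.assert_allclose(norms[labels == 1], 1.0, atol=1e-9)
    # vapor+noise-only background pixels are zeroed, not blown up
    assert np.all(norms[labels == 0] == 0.0)
    steps = [s["step"] for s in pre.metadata["steps"]]
    assert steps == ["water_vapor_compensation", "vector_normalization"]


def test_normalize_map_is_scale_invariant():
    cfg = class_config("III", map_height_um=81.92, map_width_um=81.92,
                       n_droplets=0, vapor_amplitude=0.0, seed=1)
    hmap, _ = simulate_map(cfg)
    doubled = type(hmap)(axis=hmap.axis, cube=2.0 * hmap.cube,
                         pixel_um=hmap.pixel_um)
    a = normalize_map(hmap)
    b = normalize_map(doubled)
    np.testing.assert_allclose(a.cube, b.cube, atol=1e-12)
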