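"""Band integration against closed forms and a fine-grid Riemann oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image
from scipy.stats import norm

from conftest import gaussian, riemann_area
from ftiri.bands import (BandDefinition, BandImage, ColorScale, IMAGING_BANDS,
                         RATIO_BANDS, band_image, integrate_band,
                         render_false_color)
from ftiri.errors import RangeError
from ftiri.hypermap import HyperMap, SpectralAxis
from ftiri.preprocessing import analysis_axis, normalize_map
from ftiri.synthetic import class_config, simulate_map


@pytest.fixture(scope="module")
def axis():
    return analysis_axis()


def test_constant_spectrum_rectangle(axis):
    area = integrate_band(np.full(len(axis), 2.0), axis,
                          BandDefinition("box", 1000, 1100))
    assert area == pytest.approx(200.0, rel=1e-12)


def test_gaussian_partial_area_matches_normal_cdf(axis):
    """Trapezoid on the 2 cm^-1 axis vs the Phi-difference closed form."""
    w = axis.wavenumbers
    g = gaussian(w, 1655, 20, 1.0)
    area = integrate_band(g, axis, BandDefinition("PRT", 1717, 1486))
    exact = 20.0 * np.sqrt(2 * np.pi) * (
        norm.cdf((1717 - 1655) / 20) - norm.cdf((1486 - 1655) / 20))
    assert exact == pytest.approx(50.08, abs=0.01)
    assert area == pytest.approx(exact, rel=2e-3)


def test_off_grid_edges_agree_with_riemann_oracle(axis):
    """Shifting band edges off the grid by 0.4 cm^-1 changes nothing beyond
    the trapezoid error bound set by a 0.1 cm^-1 Riemann oracle."""
    w = axis.wavenumbers
    bands_model = [(2925.0, 14.0, 0.3), (1655.0, 22.0, 0.6)]
    spectrum = sum(gaussian(w, c, s, a) for c, s, a in bands_model)
    for lo, hi in ((2820.0, 3002.0), (1486.0, 1717.0)):
        on_grid = integrate_band(spectrum, axis, BandDefinition("b", lo, hi))
        off_grid = integrate_band(spectrum, axis,
                                  BandDefinition("b", lo + 0.4, hi + 0.4))
        oracle_on = riemann_area(bands_model, lo, hi)
        oracle_off = riemann_area(bands_model, lo + 0.4, hi + 0.4)
        assert on_grid == pytest.approx(oracle_on, rel=5e-3)
        assert off_grid == pytest.approx(oracle_off, rel=5e-3)
        assert abs((on_grid - off_grid) - (oracle_on - oracle_off)) < 0.05


def test_all_ratio_and_imaging_bands_against_oracle(axis):
    """Every named window agrees with the 0.1 cm^-1 oracle within 0.5% on a
    realistic composition."""
    comp = class_config("III").cytoplasm
    bands_model = [(b.center, b.width, b.amplitude) for b in comp.bands]
    w = axis.wavenumbers
    spectrum = sum(gaussian(w, c, s, a) for c, s, a in bands_model)
    for band in list(RATIO_BANDS) + list(IMAGING_BANDS.values()):
        got = integrate_band(spectrum, axis, band)
        want = riemann_area(bands_model, band.lo, band.hi)
        assert got == pytest.approx(want, rel=5e-3), band.name


@settings(max_examples=30, deadline=None, derandomize=True)
@given(split=st.floats(1001.0, 1499.0), seed=st.integers(0, 2**16))
def test_adjacent_band_additivity(split, seed):
    axis = analysis_axis()
    rng = np.random.default_rng(seed)
    spectrum = rng.normal(0.0, 1.0, size=len(axis))
    whole = integrate_band(spectrum, axis, BandDefinition("w", 1000, 1500))
    left = integrate_band(spectrum, axis, BandDefinition("l", 1000, split))
    right = integrate_band(spectrum, axis, BandDefinition("r", split, 1500))
    assert left + right == pytest.approx(whole, abs=1e-9)


def test_integration_linear_in_spectrum(axis):
    rng = np.random.default_rng(1)
    a = rng.normal(size=len(axis))
    b = rng.normal(size=len(axis))
    band = BandDefinition("b", 1100, 1900)
    assert integrate_band(2.5 * a - b, axis, band) == pytest.approx(
        2.5 * integrate_band(a, axis, band) - integrate_band(b, axis, band),
        abs=1e-9)


def test_negative_absorbance_integrates_with_sign(axis):
    area = integrate_band(np.full(len(axis), -1.0), axis,
                          BandDefinition("b", 1000, 1100))
    assert area == pytest.approx(-100.0, rel=1e-12)


def test_band_outside_spectrum_range_rejected():
    axis = SpectralAxis(1200.0 + 2.0 * np.arange(100))
    with pytest.raises(RangeError, match="outside spectrum range"):
        integrate_band(np.ones(100), axis, BandDefinition("b", 1000, 1100))


def test_local_baseline_switch_subtracts_chord(axis):
    w = axis.wavenumbers
    spectrum = 0.001 * w + 0.2    # pure line: chord removes everything
    band = BandDefinition("b", 1000, 1500)
    assert integrate_band(spectrum, axis, band) != 0.0
    assert integrate_band(spectrum, axis, band,
                          local_baseline=True) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# band images
# ---------------------------------------------------------------------------

def test_all_zero_map_gives_all_zero_image(axis):
    hmap = HyperMap(axis=axis, cube=np.zeros((4, 5, len(axis))), pixel_um=2.56)
    img = band_image(hmap, BandDefinition("b", 1000, 1500))
    assert img.values.shape == (4, 5)
    assert np.all(img.values == 0.0)


def test_droplet_lipid_contrast_localized():
    """Lipid image peaks inside droplets; protein image is flat across the
    cytoplasm."""
    cfg = class_config("III", map_height_um=81.92, map_width_um=81.92,
                       thickness_cv=0.0, noise_sd=0.0, vapor_amplitude=0.0,
                       n_droplets=5, seed=3)
    hmap, truth = simulate_map(cfg)
    lipid = band_image(hmap, IMAGING_BANDS["lipids"]).values
    protein = band_image(hmap, IMAGING_BANDS["proteins"]).values
    droplets = truth.droplet_mask
    plain = truth.mask.labels.astype(bool) & ~droplets
    assert lipid[droplets].min() > 2.0 * lipid[plain].max()
    # protein amplitudes are untouched in droplets; only the CH2-bend tail
    # leaks marginally into the 1480-1700 window
    np.testing.assert_allclose(protein[droplets].mean(),
                               protein[plain].mean(), rtol=1e-2)


def test_global_factor_cancelled_by_map_normalization():
    cfg = class_config("III", map_height_um=81.92, map_width_um=81.92,
                       n_droplets=0, vapor_amplitude=0.0, seed=4)
    hmap, _ = simulate_map(cfg)
    doubled = HyperMap(axis=hmap.axis, cube=2.0 * hmap.cube,
                       pixel_um=hmap.pixel_um)
    band = IMAGING_BANDS["lipids"]
    img_a = band_image(normalize_map(hmap), band)
    img_b = band_image(normalize_map(doubled), band)
    np.testing.assert_allclose(img_a.values, img_b.values, atol=1e-12)


# ---------------------------------------------------------------------------
# false-color rendering
# ---------------------------------------------------------------------------

def read_pixels(path):
    return np.asarray(Image.open(path))


def test_uniform_extremes_render_blue_and_white(tmp_path):
    scale = ColorScale(0.0, 6.0)
    band = BandDefinition("b", 1000, 1100)
    white = render_and_read(tmp_path / "w.png",
                            BandImage(np.full((2, 2), 6.0), band), scale)
    blue = render_and_read(tmp_path / "b.png",
                           BandImage(np.zeros((2, 2)), band), scale)
    assert np.all(white == 255)
    assert np.all(blue[..., 2] == 255) and np.all(blue[..., :2] == 0)


def render_and_read(path, image, scale):
    render_false_color(image, scale, path)
    return read_pixels(path)


def test_out_of_range_values_clamped(tmp_path):
    scale = ColorScale(0.0, 6.0)
    band = BandDefinition("b", 1000, 1100)
    img = BandImage(np.array([[-1.0, 11.0]]), band)
    rgb = render_and_read(tmp_path / "c.png", img, scale)
    assert tuple(rgb[0, 0]) == (0, 0, 255)       # below lo -> blue
    assert tuple(rgb[0, 1]) == (255, 255, 255)   # above hi -> white


def test_rendering_deterministic(tmp_path):
    rng = np.random.default_rng(0)
    img = BandImage(rng.uniform(0, 6, size=(8, 8)),
                    BandDefinition("b", 1000, 1100))
    scale = ColorScale(0.0, 6.0)
    render_false_color(img, scale, tmp_path / "a.png")
    render_false_color(img, scale, tmp_path / "b.png")
    assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()
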