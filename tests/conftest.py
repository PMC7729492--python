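import numpy as np
import pytest

from ftiri.hypermap import SpectralAxis
from ftiri.synthetic import (BandModel, CompartmentComposition,
                             SimulationConfig)


@pytest.fixture(scope="session")
def coarse_axis() -> SpectralAxis:
    """Acquisition-like axis: 800-4000 cm^-1 at 4 cm^-1."""
    return SpectralAxis(800.0 + 4.0 * np.arange(801))


def gaussian(w: np.ndarray, center: float, width: float,
             amplitude: float = 1.0) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((w - center) / width) ** 2)


def riemann_area(bands: list[tuple[float, float, float]], lo: float,
                 hi: float, step: float = 0.1) -> float:
    """Brute-force fine-grid Riemann integral of a Gaussian mixture."""
    grid = np.arange(lo, hi, step) + step / 2.0
    total = np.zeros_like(grid)
    for center, width, amplitude in bands:
        total += gaussian(grid, center, width, amplitude)
    return float(total.sum() * step)


def single_band_config(amplitude: float = 1.0, center: float = 1655.0,
                       width: float = 20.0, **overrides) -> SimulationConfig:
    """Minimal noise-free class III config with one cytoplasm band."""
    comp = CompartmentComposition(
        compartment="cytoplasm",
        bands=(BandModel("only", center, width, amplitude),),
    )
    defaults = dict(
        oocyte_class="III", cytoplasm=comp,
        map_height_um=81.92, map_width_um=81.92,
        thickness_cv=0.0, noise_sd=0.0, vapor_amplitude=0.0,
        n_droplets=0, seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
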