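"""Named spectral bands, trapezoidal band integration and false-color imaging.

Band intervals are stored ascending ``(lo, hi)`` with both ends closed; the
descending notation conventional in IR spectroscopy ("3002-2820 cm^-1") is
converted at construction.  Integration is a plain trapezoid on the (already
baseline-treated) spectrum; band edges falling between axis points are handled
by linear interpolation of the spectrum at the edge, which makes results
robust to the phase of the axis grid.  Negative absorbances integrate with
sign.  An optional local-baseline switch subtracts the chord between the band
endpoints before integrating (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import FormatError, RangeError
from .hypermap import HyperMap, SpectralAxis


@dataclass(frozen=True)
class BandDefinition:
    """A named wavenumber interval, ``800 <= lo < hi <= 4000`` cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        lo, hi = sorted((float(self.lo), float(self.hi)))
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if not (800.0 <= lo < hi <= 4000.0):
            raise FormatError(
                f"band {self.name!r} [{lo:g}, {hi:g}] must satisfy "
                "800 <= lo < hi <= 4000")

    @property
    def width(self) -> float:
        return self.hi - self.lo


# Imaging set: windows used for the false-color chemical maps.
IMAGING_BANDS: dict[str, BandDefinition] = {
    "lipids": BandDefinition("lipids", 2800, 3050),
    "proteins": BandDefinition("proteins", 1480, 1700),
    "glyco": BandDefinition("glyco", 1137, 1188),
    "cortisol": BandDefinition("cortisol", 1006, 1140),
}

# Ratio set: windows integrated on preprocessed point spectra.
LIP = BandDefinition("LIP", 2820, 3002)   # CH2/CH3 stretching, lipid chains
FA = BandDefinition("FA", 1717, 1763)     # ester C=O stretching, fatty acids
PRT = BandDefinition("PRT", 1486, 1717)   # amide I + II, proteins
CH2 = BandDefinition("CH2", 1429, 1486)   # CH2 bending, lipid chains
COH = BandDefinition("COH", 1137, 1188)   # COH stretching, glycosylated cpds
CRT = BandDefinition("CRT", 1000, 1137)   # C-O stretching, cortisol

RATIO_BANDS: tuple[BandDefinition, ...] = (LIP, FA, PRT, CH2, COH, CRT)

#: Fixed display ranges (absorbance*cm^-1) of the four chemical images.
DEFAULT_COLOR_SCALES: dict[str, tuple[float, float]] = {
    "lipids": (0.0, 6.0),
    "proteins": (0.0, 15.0),
    "glyco": (0.0, 1.0),
    "cortisol": (0.0, 8.0),
}


@dataclass(frozen=True)
class ColorScale:
    """Linear blue-to-white mapping with clamp bounds."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise FormatError("color scale requires lo < hi")


@dataclass
class BandImage:
    """Grid of integrated band areas (absorbance*cm^-1)."""

    values: np.ndarray
    band: BandDefinition

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("band image values must form a 2-D grid")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("band image contains non-finite values")


# ---------------------------------------------------------------------------
# Trapezoidal integration as a linear functional on the axis
# ---------------------------------------------------------------------------

def band_weights(axis: SpectralAxis, band: BandDefinition) -> np.ndarray:
    """Weights ``w`` such that ``w @ spectrum`` is the trapezoid integral of
    the piecewise-linear spectrum over ``[band.lo, band.hi]``.

    Fractional band edges contribute through linear interpolation of the
    spectrum at the edge, folded into the weights, so integration is exactly
    linear in the spectrum and exactly additive over adjacent bands.
    """
    x = axis.wavenumbers
    lo, hi = band.lo, band.hi
    if lo < x[0] or hi > x[-1]:
        raise RangeError(
            f"band {band.name!r} [{lo:g}, {hi:g}] outside spectrum range "
            f"[{x[0]:g}, {x[-1]:g}]")

    # knots: lo, interior axis points strictly inside (lo, hi), hi
    inner = np.nonzero((x > lo) & (x < hi))[0]
    knots = np.concatenate(([lo], x[inner], [hi]))
    # each knot value is a sparse linear combination of spectrum samples
    n = x.size
    coeffs = np.zeros((knots.size, n))
    for k, t in enumerate(knots):
        j = int(np.searchsorted(x, t))
        if j < n and x[j] == t:
            coeffs[k, j] = 1.0
        else:
            f = (t - x[j - 1]) / (x[j] - x[j - 1])
            coeffs[k, j - 1] = 1.0 - f
            coeffs[k, j] = f
    seg = np.diff(knots)
    trap = np.zeros(knots.size)
    trap[:-1] += seg / 2.0
    trap[1:] += seg / 2.0
    return trap @ coeffs


def integrate_band(values: np.ndarray, axis: SpectralAxis,
                   band: BandDefinition,
                   local_baseline: bool = False) -> float | np.ndarray:
    """Trapezoid integral of absorbance over the band; sign-preserving.

    ``values`` may be a single spectrum or a stack ``(..., n_wavenumbers)``.
    With ``local_baseline=True`` the chord between the band endpoints is
    subtracted before integrating.
    """
    w = band_weights(axis, band)
    values = np.asarray(values, dtype=float)
    area = values @ w
    if local_baseline:
        x = axis.wavenumbers
        y_lo = np.interp(band.lo, x, values) if values.ndim == 1 else \
            np.apply_along_axis(lambda v: np.interp(band.lo, x, v), -1, values)
        y_hi = np.interp(band.hi, x, values) if values.ndim == 1 else \
            np.apply_along_axis(lambda v: np.interp(band.hi, x, v), -1, values)
        area = area - (y_lo + y_hi) / 2.0 * band.width
    return float(area) if np.ndim(area) == 0 else area


def band_image(hmap: HyperMap, band: BandDefinition,
               local_baseline: bool = False) -> BandImage:
    """Per-pixel band integral of a (map-level preprocessed) map."""
    areas = integrate_band(hmap.cube, hmap.axis, band,
                           local_baseline=local_baseline)
    return BandImage(values=areas, band=band)


# ---------------------------------------------------------------------------
# False-color rendering
# ---------------------------------------------------------------------------

def false_color_rgb(image: BandImage, scale: ColorScale) -> np.ndarray:
    """Linear blue (scale.lo) to white (scale.hi) RGB array, values clamped."""
    t = (image.values - scale.lo) / (scale.hi - scale.lo)
    t = np.clip(t, 0.0, 1.0)
    rgb = np.empty(image.values.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.rint(255.0 * t)          # red ramps up
    rgb[..., 1] = np.rint(255.0 * t)          # green ramps up
    rgb[..., 2] = 255                         # blue stays saturated
    return rgb


def render_false_color(image: BandImage, scale: ColorScale,
                       path: str | Path) -> None:
    """Write the clamped blue-to-white rendering as a lossless PNG."""
    Image.fromarray(false_color_rgb(image, scale), mode="RGB").save(
        Path(path), format="PNG")
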