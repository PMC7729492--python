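"""Spectral preprocessing chains.

Two chains mirror how imaging and point-spectrum analyses treat the data:

* **map level** (before chemical imaging): water-vapor compensation followed
  by per-pixel vector normalization over the full acquired range, which
  cancels section-thickness differences;
* **analysis level** (before ratios and PCA): linear interpolation onto a
  uniform axis spanning exactly 3050-900 cm^-1, subtraction of the straight
  line through the two range endpoints (two-point baseline), then vector
  normalization over the cropped range.

Every applied step is appended to the object's provenance record.

Vapor compensation fits a single scale factor ``alpha`` to the reference
pattern by least squares on second differences within the 1900-1300 cm^-1
window.  High-pass matching keeps the fit selective for the narrow vapor
lines: broad biological bands (amide I/II) overlap the window but carry almost
no second-difference energy, so they do not bias ``alpha``.  The factor is
clamped at zero (vapor is an additive contaminant, never negative).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, DegenerateSpectrumError, RangeError
from .hypermap import HyperMap, SpectralAxis
from .vapor import VAPOR_WINDOW, vapor_reference

#: Analysis-level working range (cm^-1) and interpolation step.
ANALYSIS_RANGE = (900.0, 3050.0)
ANALYSIS_STEP = 2.0

#: Pixels whose spectral norm falls below this fraction of the map's median
#: tissue norm are treated as background and zeroed during map normalization.
BACKGROUND_NORM_FRACTION = 0.05


def analysis_axis(step: float = ANALYSIS_STEP) -> SpectralAxis:
    """The uniform 900-3050 cm^-1 axis used for all point-spectrum analysis."""
    lo, hi = ANALYSIS_RANGE
    n = int(round((hi - lo) / step))
    return SpectralAxis(lo + step * np.arange(n + 1))


# ---------------------------------------------------------------------------
# Water-vapor compensation
# ---------------------------------------------------------------------------

def fit_vapor_scale(values: np.ndarray, axis: SpectralAxis,
                    reference: np.ndarray,
                    window: tuple[float, float] = VAPOR_WINDOW) -> np.ndarray:
    """Least-squares vapor scale(s) for 1-D or ``(n, p)`` stacked spectra."""
    w = axis.wavenumbers
    sel = (w >= window[0]) & (w <= window[1])
    if sel.sum() < 5:
        raise RangeError("vapor fitting window covers fewer than 5 axis points")
    ref_d2 = np.diff(reference[sel], n=2)
    denom = float(ref_d2 @ ref_d2)
    if denom == 0.0:
        raise ConfigurationError("vapor reference is identically zero in the "
                                 "fitting window")
    vals = np.atleast_2d(values)[:, sel]
    d2 = np.diff(vals, n=2, axis=1)
    alpha = (d2 @ ref_d2) / denom
    return np.maximum(alpha, 0.0)


def compensate_water_vapor(obj: np.ndarray | HyperMap,
                           axis: SpectralAxis | None = None,
                           reference: np.ndarray | None = None,
                           window: tuple[float, float] = VAPOR_WINDOW):
    """Subtract the fitted vapor contribution from a spectrum or a map.

    For a spectrum, returns ``(corrected_values, alpha)``; for a
    :class:`HyperMap`, returns a new map with per-pixel alphas summarized in
    its provenance record.
    """
    if isinstance(obj, HyperMap):
        ref = vapor_reference(obj.axis.wavenumbers) if reference is None else \
            np.asarray(reference, dtype=float)
        if ref.shape != (len(obj.axis),):
            raise ConfigurationError("vapor reference length does not match axis")
        if not np.any(ref):
            raise ConfigurationError("vapor reference is identically zero")
        flat = obj.spectra()
        alpha = fit_vapor_scale(flat, obj.axis, ref, window)
        corrected = flat - alpha[:, None] * ref[None, :]
        out = HyperMap(axis=obj.axis,
                       cube=corrected.reshape(obj.cube.shape),
                       pixel_um=obj.pixel_um,
                       metadata=dict(obj.metadata))
        out.record_step("water_vapor_compensation",
                        window=list(window),
                        alpha_mean=float(alpha.mean()),
                        alpha_min=float(alpha.min()),
                        alpha_max=float(alpha.max()))
        return out

    values = np.asarray(obj, dtype=float)
    if axis is None:
        raise ConfigurationError("an axis is required for spectrum input")
    ref = vapor_reference(axis.wavenumbers) if reference is None else \
        np.asarray(reference, dtype=float)
    if not np.any(ref):
        raise ConfigurationError("vapor reference is identically zero")
    alpha = float(fit_vapor_scale(values, axis, ref, window)[0])
    return values - alpha * ref, alpha


# ---------------------------------------------------------------------------
# Vector normalization
# ---------------------------------------------------------------------------

def vector_normalize(values: np.ndarray, axis: SpectralAxis,
                     lo: float | None = None,
                     hi: float | None = None) -> tuple[np.ndarray, float]:
    """Scale a spectrum so its Euclidean norm over ``[lo, hi]`` equals 1.

    Points outside the range are scaled by the same factor.  Returns the
    scaled spectrum and the norm that was divided out.
    """
    values = np.asarray(values, dtype=float)
    w = axis.wavenumbers
    if lo is None and hi is None:
        sel = slice(None)
    else:
        lo = w[0] if lo is None else lo
        hi = w[-1] if hi is None else hi
        if not axis.covers(lo, hi):
            raise RangeError(f"normalization range [{lo:g}, {hi:g}] not covered "
                             f"by axis [{w[0]:g}, {w[-1]:g}]")
        sel = (w >= lo) & (w <= hi)
    norm = float(np.linalg.norm(values[sel]))
    if norm == 0.0:
        raise DegenerateSpectrumError(
            "spectrum is identically zero within the normalization range "
            "(background pixel?)")
    return values / norm, norm


def normalize_map(hmap: HyperMap,
                  background_fraction: float = BACKGROUND_NORM_FRACTION) -> HyperMap:
    """Per-pixel vector normalization over the full acquired range.

    Pixels whose norm is below ``background_fraction`` x the median pixel norm
    are background (no tissue): they are zeroed rather than blown up to unit
    norm.  The threshold is relative, so globally rescaled maps normalize to
    identical results.
    """
    flat = hmap.spectra()
    norms = np.linalg.norm(flat, axis=1)
    median = float(np.median(norms))
    threshold = background_fraction * median
    degenerate = norms <= threshold
    safe = np.where(degenerate, 1.0, norms)
    out_flat = np.where(degenerate[:, None], 0.0, flat / safe[:, None])
    out = HyperMap(axis=hmap.axis, cube=out_flat.reshape(hmap.cube.shape),
                   pixel_um=hmap.pixel_um, metadata=dict(hmap.metadata))
    out.record_step("vector_normalization", window="full",
                    background_fraction=background_fraction,
                    n_background=int(degenerate.sum()))
    return out


def preprocess_map(hmap: HyperMap,
                   reference: np.ndarray | None = None) -> HyperMap:
    """Map-level chain: vapor compensation, then per-pixel normalization."""
    return normalize_map(compensate_water_vapor(hmap, reference=reference))


# ---------------------------------------------------------------------------
# Analysis-level chain
# ---------------------------------------------------------------------------

def preprocess_for_analysis(values: np.ndarray, axis: SpectralAxis,
                            step: float = ANALYSIS_STEP,
                            ) -> tuple[np.ndarray, SpectralAxis, list[dict]]:
    """Interpolate to 3050-900, two-point-baseline, vector normalize.

    Returns ``(spectrum, new_axis, record)`` where ``record`` lists the steps
    applied.  The two range endpoints are exactly zero after the baseline
    step, and the chain is idempotent.
    """
    lo, hi = ANALYSIS_RANGE
    missing = []
    if axis.lo > lo:
        missing.append(f"low end reaches only {axis.lo:g} (need {lo:g})")
    if axis.hi < hi:
        missing.append(f"high end reaches only {axis.hi:g} (need {hi:g})")
    if missing:
        raise RangeError("input does not cover the 3050-900 cm^-1 analysis "
                         "range: " + "; ".join(missing))
    new_axis = analysis_axis(step)
    w = new_axis.wavenumbers
    values = np.interp(w, axis.wavenumbers, np.asarray(values, dtype=float))
    record = [{"step": "interpolate", "lo": lo, "hi": hi, "step_cm": step}]

    # straight line through the endpoint absorbances
    y0, y1 = values[0], values[-1]
    baseline = y0 + (y1 - y0) * (w - w[0]) / (w[-1] - w[0])
    scale = float(np.max(np.abs(values)))
    values = values - baseline
    values[0] = 0.0
    values[-1] = 0.0
    record.append({"step": "two_point_baseline",
                   "anchors": [float(w[0]), float(w[-1])]})
    # an input that was itself affine leaves only floating-point dust
    if np.max(np.abs(values)) <= 1e-12 * max(scale, 1e-30):
        raise DegenerateSpectrumError(
            "spectrum is identically zero after two-point baseline removal")

    values, norm = vector_normalize(values, new_axis)
    record.append({"step": "vector_normalization", "window": "full",
                   "norm": norm})
    return values, new_axis, record
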