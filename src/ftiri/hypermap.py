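"""In-memory data model for hyperspectral IR maps.

A hyperspectral map is a pixel grid in which every pixel holds a mid-infrared
absorbance spectrum on a shared wavenumber axis.  The axis is always stored in
ascending wavenumber order; files written with descending axes are normalized
on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import FormatError, SchemaError

#: Labels used in compartment masks.
BACKGROUND = 0
CYTOPLASM = 1
ZONA_RADIATA = 2

COMPARTMENT_CODES = {
    "background": BACKGROUND,
    "cytoplasm": CYTOPLASM,
    "zona_radiata": ZONA_RADIATA,
}


@dataclass(frozen=True)
class SpectralAxis:
    """Ascending wavenumber axis in cm^-1, approximately uniform."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        if w.ndim != 1 or w.size < 2:
            raise FormatError("spectral axis must be a 1-D sequence of >= 2 points")
        steps = np.diff(w)
        if not np.all(steps > 0):
            raise FormatError("spectral axis must be strictly ascending")
        if w[0] < 400.0 or w[-1] > 8000.0:
            raise FormatError(
                f"axis [{w[0]:g}, {w[-1]:g}] outside the supported 400-8000 cm^-1"
            )
        if steps.max() / steps.min() >= 1.5:
            raise FormatError("spectral axis spacing is not approximately uniform")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.wavenumbers.shape == other.wavenumbers.shape and bool(
            np.array_equal(self.wavenumbers, other.wavenumbers)
        )

    @property
    def lo(self) -> float:
        return float(self.wavenumbers[0])

    @property
    def hi(self) -> float:
        return float(self.wavenumbers[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.lo <= lo and hi <= self.hi


@dataclass
class HyperMap:
    """Absorbance cube indexed ``(row, column, wavenumber)`` with pixel size."""

    axis: SpectralAxis
    cube: np.ndarray
    pixel_um: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3:
            raise FormatError("cube must be 3-D (rows, cols, wavenumbers)")
        if self.cube.shape[2] != len(self.axis):
            raise FormatError(
                f"cube spectral dimension {self.cube.shape[2]} does not match "
                f"axis length {len(self.axis)}"
            )
        if self.cube.shape[0] < 1 or self.cube.shape[1] < 1:
            raise FormatError("maps must contain >= 1 pixel")
        if self.pixel_um <= 0:
            raise FormatError("pixel_um must be positive")
        if not np.all(np.isfinite(self.cube)):
            raise FormatError("cube contains non-finite absorbance values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[0], self.cube.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.cube.shape[0] * self.cube.shape[1]

    def spectra(self) -> np.ndarray:
        """Pixels flattened row-major into an ``(n_pixels, n_wavenumbers)`` view."""
        return self.cube.reshape(-1, self.cube.shape[2])

    def record_step(self, name: str, **params: Any) -> None:
        """Append a preprocessing step to the map's provenance record."""
        self.metadata.setdefault("steps", []).append({"step": name, **params})


@dataclass
class CompartmentMask:
    """Integer label grid aligned to a :class:`HyperMap`.

    0 = background, 1 = cytoplasm, 2 = zona radiata.
    """

    labels: np.ndarray
    pixel_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("mask labels must form a 2-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = self.labels.astype(np.int64)
            if not np.array_equal(lab, self.labels):
                raise FormatError("mask labels must be integers")
            self.labels = lab
        known = set(COMPARTMENT_CODES.values())
        if not set(np.unique(self.labels)).issubset(known):
            raise FormatError(f"mask labels must be within {sorted(known)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def check_aligned(self, hmap: HyperMap) -> None:
        if self.shape != hmap.shape:
            raise SchemaError(
                f"mask shape {self.shape} does not match map shape {hmap.shape}"
            )

    def pixels(self, compartment: str) -> np.ndarray:
        """Row-major sorted ``(row, col)`` coordinates of one compartment."""
        if compartment not in COMPARTMENT_CODES:
            raise SchemaError(f"unknown compartment {compartment!r}")
        rr, cc = np.nonzero(self.labels == COMPARTMENT_CODES[compartment])
        return np.column_stack([rr, cc])
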