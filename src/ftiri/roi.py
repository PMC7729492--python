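"""Compartment-resolved spectrum extraction.

From every mapped oocyte, a fixed number of pixel spectra is drawn uniformly
at random without replacement from one labeled compartment (40 from the
cytoplasm, ~10 from the class IV zona radiata by default) and passed through
the analysis-level preprocessing chain.  The draw depends only on the seed
and the set of eligible coordinates (row-major canonical order), never on
pixel storage order or spectral content beyond the all-zero exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SamplingError, SchemaError
from .hypermap import COMPARTMENT_CODES, CompartmentMask, HyperMap, SpectralAxis
from .preprocessing import preprocess_for_analysis

#: Default draw sizes.
N_CYTOPLASM = 40
N_ZONA_RADIATA = 10

LABEL_COLUMNS = ("group", "oocyte_class", "compartment", "map_id", "row", "col")


@dataclass
class SpectraSet:
    """Preprocessed spectra (rows) on a shared axis, with per-row labels."""

    axis: SpectralAxis
    spectra: np.ndarray               # (n_spectra, n_wavenumbers)
    labels: pd.DataFrame              # columns LABEL_COLUMNS

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[1] != len(self.axis):
            raise SchemaError("spectra array must be (n, len(axis))")
        missing = set(LABEL_COLUMNS) - set(self.labels.columns)
        if missing:
            raise SchemaError(f"labels lack columns {sorted(missing)}")
        if len(self.labels) != self.spectra.shape[0]:
            raise SchemaError("labels and spectra row counts differ")

    def __len__(self) -> int:
        return self.spectra.shape[0]


def concat_spectra_sets(sets: list[SpectraSet]) -> SpectraSet:
    if not sets:
        raise SchemaError("cannot concatenate zero spectra sets")
    axis = sets[0].axis
    for s in sets[1:]:
        if s.axis != axis:
            raise SchemaError("spectra sets are on different axes")
    return SpectraSet(
        axis=axis,
        spectra=np.vstack([s.spectra for s in sets]),
        labels=pd.concat([s.labels for s in sets], ignore_index=True),
    )


def sample_spectra(hmap: HyperMap, mask: CompartmentMask, compartment: str,
                   n: int, seed: int, *, group: str = "", oocyte_class: str = "",
                   map_id: str = "") -> SpectraSet:
    """Draw ``n`` distinct pixels from one compartment and preprocess them.

    All-zero pixels are excluded from eligibility before the draw.  Each
    sampled spectrum is run through :func:`preprocess_for_analysis`, so every
    returned row has unit norm and zero endpoints.
    """
    mask.check_aligned(hmap)
    if compartment not in COMPARTMENT_CODES:
        raise SchemaError(f"unknown compartment {compartment!r}")
    coords = mask.pixels(compartment)
    if coords.shape[0] == 0:
        raise SamplingError(
            f"compartment {compartment!r} is absent from the mask")
    nonzero = np.any(hmap.cube[coords[:, 0], coords[:, 1]] != 0.0, axis=1)
    coords = coords[nonzero]
    eligible = coords.shape[0]
    if n > eligible:
        raise SamplingError(
            f"requested {n} spectra but only {eligible} eligible pixels in "
            f"compartment {compartment!r}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n, replace=False)
    chosen.sort()
    picked = coords[chosen]

    spectra = []
    axis_out = None
    for r, c in picked:
        values, axis_out, _ = preprocess_for_analysis(hmap.cube[r, c], hmap.axis)
        spectra.append(values)
    labels = pd.DataFrame({
        "group": group, "oocyte_class": oocyte_class,
        "compartment": compartment, "map_id": map_id,
        "row": picked[:, 0], "col": picked[:, 1],
    })
    return SpectraSet(axis=axis_out, spectra=np.array(spectra), labels=labels)
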