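"""Reference water-vapor absorption pattern.

Atmospheric water vapor contaminates mid-IR spectra with a comb of narrow
rotational-vibrational lines riding on the amide region.  The reference used
for compensation here is a fixed, documented comb of Gaussian lines restricted
to 1900-1300 cm^-1 (the nu2 bending region), normalized to unit peak height.
Line positions are spaced irregularly, as in real vapor spectra; they are
package constants, not fits to any measured spectrum, and can be replaced by a
user-supplied reference at every call site.
"""

from __future__ import annotations

import numpy as np

#: (center cm^-1, relative amplitude) of each vapor line.
VAPOR_LINES: tuple[tuple[float, float], ...] = (
    (1844.0, 0.35), (1810.0, 0.50), (1772.0, 0.45), (1734.0, 0.30),
    (1718.0, 0.60), (1696.0, 0.50), (1670.0, 0.80), (1652.0, 0.55),
    (1636.0, 0.70), (1616.0, 1.00), (1576.0, 0.75), (1560.0, 0.50),
    (1540.0, 0.65), (1522.0, 0.40), (1508.0, 0.55), (1472.0, 0.70),
    (1456.0, 0.45), (1436.0, 0.60), (1418.0, 0.35), (1396.0, 0.50),
    (1374.0, 0.30), (1340.0, 0.40), (1320.0, 0.25),
)

#: Gaussian sigma of every line, cm^-1 (narrow relative to biological bands).
VAPOR_LINE_SIGMA = 1.6

#: Fitting window for the compensation scale factor, cm^-1.
VAPOR_WINDOW = (1300.0, 1900.0)


def vapor_reference(wavenumbers: np.ndarray) -> np.ndarray:
    """Evaluate the reference vapor pattern on ``wavenumbers`` (unit peak)."""
    w = np.asarray(wavenumbers, dtype=float)
    out = np.zeros_like(w)
    for center, amp in VAPOR_LINES:
        out += amp * np.exp(-0.5 * ((w - center) / VAPOR_LINE_SIGMA) ** 2)
    peak = out.max()
    if peak > 0:
        out /= peak
    return out
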