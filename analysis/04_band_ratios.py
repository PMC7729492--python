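#!/usr/bin/env python
"""Band-area ratio statistics: the semi-quantitative group comparison.

Computes LIP/FA/PRT/CH2/COH/CRT over the CYT denominator on every cytoplasm
spectrum (and the CRT-free panel over ZR for class IV envelopes), then
compares genotypes per ratio with pooled-variance Student's t-tests at
p < 0.05.  Writes the per-spectrum ratio tables, the comparison tables and
letter-annotated text reports under results/tables.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ftiri.hypermap import SpectralAxis
from ftiri.ratios import (CYT, CYT_RATIO_BANDS, ZR, ZR_RATIO_BANDS,
                          compare_groups, compute_ratios, format_report)
from ftiri.roi import SpectraSet

ROOT = Path(__file__).resolve().parent.parent
SPECTRA = ROOT / "scratch" / "spectra"
TABLES = ROOT / "results" / "tables"


def load(prefix: Path) -> SpectraSet:
    spec = pd.read_csv(f"{prefix}_spectra.csv")
    labels = pd.read_csv(f"{prefix}_labels.csv")
    axis = SpectralAxis(np.array([float(c) for c in spec.columns]))
    return SpectraSet(axis=axis, spectra=spec.to_numpy(), labels=labels)


def pooled_table(kind: str, class_name: str, group: str,
                 band_set, denominator) -> pd.DataFrame:
    prefixes = sorted(SPECTRA.glob(f"{kind}_{class_name}_{group}_*_spectra.csv"))
    frames = []
    for p in prefixes:
        sset = load(Path(str(p)[: -len("_spectra.csv")]))
        frames.append(compute_ratios(sset, band_set, denominator))
    return pd.concat(frames, ignore_index=True)


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    panels = [("cytoplasm", "III", CYT_RATIO_BANDS, CYT),
              ("cytoplasm", "IV", CYT_RATIO_BANDS, CYT),
              ("zr", "IV", ZR_RATIO_BANDS, ZR)]
    for kind, class_name, band_set, den in panels:
        tables = {g: pooled_table(kind, class_name, g, band_set, den)
                  for g in ("wt", "gr")}
        for g, t in tables.items():
            t.to_csv(TABLES / f"ratios_{kind}_{class_name}_{g}.csv",
                     index=False)
        comp = compare_groups(tables["wt"], tables["gr"])
        comp.to_csv(TABLES / f"comparison_{kind}_{class_name}.csv",
                    index=False)
        report = format_report(comp, "wt", "gr-/-")
        (TABLES / f"report_{kind}_{class_name}.txt").write_text(report + "\n")
        print(f"\n=== {kind}, class {class_name} "
              f"(n = {len(tables['wt'])} + {len(tables['gr'])} spectra) ===")
        print(report)
        up = comp[comp["significant"]
                  & (comp["mean_b"] > comp["mean_a"])]["ratio"].tolist()
        print(f"higher in mutant: {', '.join(up) if up else 'none'}")


if __name__ == "__main__":
    main()
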