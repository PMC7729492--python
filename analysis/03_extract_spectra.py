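#!/usr/bin/env python
"""Extract compartment spectra from the preprocessed maps.

Draws 40 cytoplasm spectra per oocyte (both classes) and 10 zona radiata
spectra per class IV oocyte, uniformly at random without replacement, each
passed through the analysis chain (3050-900 cm^-1 interpolation, two-point
baseline, vector normalization).  Spectra and labels go to scratch/spectra
as CSV pairs.
"""

from pathlib import Path

import pandas as pd

from ftiri.hypermap_io import read_map, read_mask
from ftiri.roi import sample_spectra
from ftiri.scenario import demo_scenario

ROOT = Path(__file__).resolve().parent.parent
MAPS = ROOT / "scratch" / "maps"
PRE = ROOT / "scratch" / "preprocessed"
SPECTRA = ROOT / "scratch" / "spectra"


def save(sset, prefix: Path) -> None:
    pd.DataFrame(sset.spectra,
                 columns=[f"{w:.6g}" for w in sset.axis.wavenumbers]
                 ).to_csv(f"{prefix}_spectra.csv", index=False)
    sset.labels.to_csv(f"{prefix}_labels.csv", index=False)


def main() -> None:
    SPECTRA.mkdir(parents=True, exist_ok=True)
    scenario = demo_scenario()
    roi_seed = scenario.seed * 10_000 + 1
    for map_path in sorted(PRE.glob("map_*.raw")):
        map_id = map_path.stem[4:]
        class_name, group, _ = map_id.split("_")
        pre = read_map(map_path)
        mask = read_mask(MAPS / f"mask_{map_id}.raw")
        cyto = sample_spectra(pre, mask, "cytoplasm", scenario.n_cytoplasm,
                              seed=roi_seed, group=group,
                              oocyte_class=class_name, map_id=map_id)
        save(cyto, SPECTRA / f"cytoplasm_{map_id}")
        roi_seed += 1
        msg = f"{map_id}: {len(cyto)} cytoplasm spectra"
        if class_name == "IV":
            zr = sample_spectra(pre, mask, "zona_radiata",
                                scenario.n_zona_radiata, seed=roi_seed,
                                group=group, oocyte_class=class_name,
                                map_id=map_id)
            save(zr, SPECTRA / f"zr_{map_id}")
            roi_seed += 1
            msg += f", {len(zr)} zona radiata spectra"
        print(msg)


if __name__ == "__main__":
    main()
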