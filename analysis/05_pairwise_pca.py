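#!/usr/bin/env python
"""Pairwise PCA of the cytoplasm spectra, per oocyte class.

Pools wild-type-like and mutant-like preprocessed cytoplasm spectra of one
maturation class, mean-centers over wavenumbers and decomposes by singular
values.  Writes score/loading/explained-variance tables and the score and
PC1-loading plots; prints PC1 explained variance and the point-biserial
correlation between PC1 score and genotype.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ftiri.bands import CH2, LIP, PRT
from ftiri.chemometrics import (explained_variance_table, group_separation,
                                loading_band_mass, loadings_table,
                                pairwise_pca, plot_loading, plot_scores,
                                scores_table)
from ftiri.hypermap import SpectralAxis
from ftiri.roi import SpectraSet, concat_spectra_sets

ROOT = Path(__file__).resolve().parent.parent
SPECTRA = ROOT / "scratch" / "spectra"
TABLES = ROOT / "results" / "tables"
FIGURES = ROOT / "results" / "figures"


def load_group(class_name: str, group: str) -> SpectraSet:
    sets = []
    for p in sorted(SPECTRA.glob(f"cytoplasm_{class_name}_{group}_*_spectra.csv")):
        prefix = str(p)[: -len("_spectra.csv")]
        spec = pd.read_csv(f"{prefix}_spectra.csv")
        labels = pd.read_csv(f"{prefix}_labels.csv")
        axis = SpectralAxis(np.array([float(c) for c in spec.columns]))
        sets.append(SpectraSet(axis=axis, spectra=spec.to_numpy(),
                               labels=labels))
    return concat_spectra_sets(sets)


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    FIGURES.mkdir(parents=True, exist_ok=True)
    for class_name in ("III", "IV"):
        res = pairwise_pca(load_group(class_name, "wt"),
                           load_group(class_name, "gr"))
        scores_table(res).to_csv(
            TABLES / f"pca_scores_{class_name}.csv", index=False)
        loadings_table(res).to_csv(
            TABLES / f"pca_loadings_{class_name}.csv", index=False)
        explained_variance_table(res).to_csv(
            TABLES / f"pca_explained_variance_{class_name}.csv", index=False)
        plot_scores(res, FIGURES / f"pca_scores_{class_name}.png")
        plot_loading(res, FIGURES / f"pca_pc1_loading_{class_name}.png")
        r = group_separation(res)
        lip_mass = loading_band_mass(res, LIP) + loading_band_mass(res, CH2)
        print(f"class {class_name}: PC1 explains "
              f"{100 * res.explained_variance[0]:.1f}% of variance; "
              f"|r(PC1, genotype)| = {abs(r):.2f}; "
              f"PC1 loading mass LIP+CH2 {lip_mass:.2f} vs PRT "
              f"{loading_band_mass(res, PRT):.2f}")


if __name__ == "__main__":
    main()
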