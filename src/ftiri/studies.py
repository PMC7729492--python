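"""Repeated-seed simulation studies over the full analysis chain.

These drive the pipeline end to end on reduced 32x32-pixel single-oocyte
maps — large enough to hold the 40-spectrum cytoplasm draw, small enough to
repeat across a hundred master seeds in well under two minutes each — and
summarize per-ratio test outcomes:

* a **null study** (identical wild-type and mutant configurations) estimates
  the type-I error rate of the per-spectrum pooled t-test;
* an **effect study** (lipid-family and cortisol amplitudes raised) estimates
  per-ratio rejection rates and directions, i.e. power.

Master seeds are spaced so that per-map derived seeds never collide between
repetitions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chemometrics import group_separation, loading_band_mass, pairwise_pca
from .preprocessing import preprocess_map
from .ratios import CYT, CYT_RATIO_BANDS, compare_groups, compute_ratios
from .roi import concat_spectra_sets, sample_spectra
from .synthetic import simulate_cohort, small_test_configs

#: Stride between consecutive master seeds (> number of maps per repetition).
SEED_STRIDE = 1000


def cohort_ratio_comparison(lipid_factor: float, cortisol_factor: float,
                            master_seed: int, *, n_maps: int = 3,
                            n_spectra: int = 40,
                            oocyte_class: str = "III",
                            return_sets: bool = False):
    """One full small-map cohort analysis; returns the group comparison."""
    wt_cfg, mut_cfg = small_test_configs(oocyte_class, lipid_factor,
                                         cortisol_factor)
    sets: dict[str, list] = {"wt": [], "gr": []}
    roi_seed = (master_seed * 101 + 17) % 2**31
    for member in simulate_cohort(wt_cfg, mut_cfg, n_maps, master_seed):
        pre = preprocess_map(member.hypermap)
        sets[member.group].append(sample_spectra(
            pre, member.truth.mask, "cytoplasm", n_spectra, seed=roi_seed,
            group=member.group, oocyte_class=oocyte_class,
            map_id=f"{member.group}{member.map_index}"))
        roi_seed += 1
    pooled = {g: concat_spectra_sets(s) for g, s in sets.items()}
    tables = {g: compute_ratios(pooled[g], CYT_RATIO_BANDS, CYT)
              for g in pooled}
    comparison = compare_groups(tables["wt"], tables["gr"])
    if return_sets:
        return comparison, pooled
    return comparison


def rejection_study(n_seeds: int, lipid_factor: float = 1.0,
                    cortisol_factor: float = 1.0, base_seed: int = 0,
                    *, n_maps: int = 3, n_spectra: int = 40) -> pd.DataFrame:
    """Per-ratio rejection counts over ``n_seeds`` master seeds.

    Returns one row per ratio with columns ``rejections`` (p < 0.05),
    ``rejections_up`` (significant with the mutant mean higher) and
    ``n_seeds``.
    """
    counts: dict[str, dict[str, int]] = {}
    for i in range(n_seeds):
        comparison = cohort_ratio_comparison(
            lipid_factor, cortisol_factor, base_seed + SEED_STRIDE * i,
            n_maps=n_maps, n_spectra=n_spectra)
        for _, row in comparison.iterrows():
            c = counts.setdefault(row["ratio"],
                                  {"rejections": 0, "rejections_up": 0})
            if row["significant"]:
                c["rejections"] += 1
                if row["mean_b"] > row["mean_a"]:
                    c["rejections_up"] += 1
    out = pd.DataFrame([
        {"ratio": r, **c, "n_seeds": n_seeds} for r, c in counts.items()])
    return out.set_index("ratio")


def pca_separation_study(master_seed: int, *, lipid_factor: float = 1.3,
                         cortisol_factor: float = 1.3, n_maps: int = 3,
                         n_spectra: int = 40) -> dict[str, float]:
    """PC1 group separation and loading placement on one effect cohort."""
    from .bands import CH2, LIP, PRT

    _, pooled = cohort_ratio_comparison(
        lipid_factor, cortisol_factor, master_seed, n_maps=n_maps,
        n_spectra=n_spectra, return_sets=True)
    result = pairwise_pca(pooled["wt"], pooled["gr"])
    return {
        "pc1_explained_variance": float(result.explained_variance[0]),
        "pc1_group_correlation": group_separation(result),
        "pc1_lipid_loading_mass": loading_band_mass(result, LIP)
        + loading_band_mass(result, CH2),
        "pc1_protein_loading_mass": loading_band_mass(result, PRT),
    }


def binomial_interval(p: float, n: int, z: float = 1.959964) -> tuple[float, float]:
    """Normal-approximation 95% interval for a proportion."""
    half = z * np.sqrt(p * (1.0 - p) / n)
    return p - half, p + half
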