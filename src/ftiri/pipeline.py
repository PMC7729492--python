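"""End-to-end orchestration of the imaging analysis.

``run_pipeline`` executes, per oocyte class: simulation (or ingestion),
map-level preprocessing, chemical imaging at the four fixed color scales,
compartment spectrum extraction, band-area ratio statistics, and pairwise
PCA, writing delimited tables, text reports, rendered images and a run
manifest under one output directory.  Every stage output is a pure function
of (scenario, master seed), so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .bands import (ColorScale, DEFAULT_COLOR_SCALES, IMAGING_BANDS,
                    band_image, render_false_color)
from .chemometrics import (explained_variance_table, group_separation,
                           loadings_table, pairwise_pca, plot_loading,
                           plot_scores, scores_table)
from .errors import ConfigurationError
from .hypermap_io import write_map, write_mask
from .preprocessing import preprocess_map
from .ratios import (CYT, CYT_RATIO_BANDS, ZR, ZR_RATIO_BANDS, compare_groups,
                     compute_ratios, format_report)
from .roi import concat_spectra_sets, sample_spectra
from .scenario import Scenario
from .synthetic import iter_scenario_maps

logger = logging.getLogger(__name__)

#: CSV float format shared by all tables, for byte-stable reruns.
FLOAT_FORMAT = "%.10g"


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT,
                 lineterminator="\n")


def run_pipeline(scenario: Scenario, outdir: str | Path,
                 seed: int | None = None, *, map_format: str = "envi_style",
                 write_maps: bool = True,
                 render_images: bool = True) -> dict:
    """Run every stage for every oocyte class; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = scenario.seed if seed is None else seed
    if scenario.n_maps_per_group < 1:
        raise ConfigurationError("scenario configures zero maps per group")

    manifest: dict = {
        "scenario": scenario.name,
        "master_seed": master_seed,
        "version": __version__,
        "n_maps_per_group": scenario.n_maps_per_group,
        "group_names": list(scenario.group_names),
        "stages": [],
        "outputs": [],
        "preprocess_records": {},
        "status": "running",
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))

    def note(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(outdir)))
        return path

    try:
        for class_name, (wt_cfg, mut_cfg) in scenario.classes.items():
            t0 = time.perf_counter()
            class_dir = outdir / f"class_{class_name}"
            class_dir.mkdir(exist_ok=True)

            cyto_sets: dict[str, list] = {g: [] for g in scenario.group_names}
            zr_sets: dict[str, list] = {g: [] for g in scenario.group_names}
            roi_seed = master_seed * 10_000 + 1

            for member in iter_scenario_maps(
                    wt_cfg, mut_cfg, scenario.n_maps_per_group, master_seed):
                map_id = f"{class_name}_{member.group}_{member.map_index}"
                if write_maps:
                    ext = ".raw" if map_format == "envi_style" else ".txt"
                    write_map(member.hypermap,
                              note(class_dir / f"map_{map_id}{ext}"),
                              map_format)
                    write_mask(member.truth.mask,
                               note(class_dir / f"mask_{map_id}{ext}"),
                               map_format)

                pre = preprocess_map(member.hypermap)
                manifest["preprocess_records"][map_id] = \
                    pre.metadata.get("steps", [])

                if render_images:
                    for name, band in IMAGING_BANDS.items():
                        img = band_image(pre, band)
                        scale = ColorScale(*DEFAULT_COLOR_SCALES[name])
                        render_false_color(
                            img, scale,
                            note(class_dir / f"img_{map_id}_{name}.png"))

                group = member.group
                cyto_sets[group].append(sample_spectra(
                    pre, member.truth.mask, "cytoplasm",
                    scenario.n_cytoplasm, seed=roi_seed,
                    group=group, oocyte_class=class_name, map_id=map_id))
                roi_seed += 1
                if class_name == "IV":
                    zr_sets[group].append(sample_spectra(
                        pre, member.truth.mask, "zona_radiata",
                        scenario.n_zona_radiata, seed=roi_seed,
                        group=group, oocyte_class=class_name, map_id=map_id))
                    roi_seed += 1

            g_a, g_b = scenario.group_names
            pooled = {g: concat_spectra_sets(cyto_sets[g])
                      for g in scenario.group_names}

            # ratio tables + group comparison (cytoplasm / CYT)
            tables = {g: compute_ratios(pooled[g], CYT_RATIO_BANDS, CYT)
                      for g in scenario.group_names}
            for g, tab in tables.items():
                _write_csv(tab, note(class_dir / f"ratios_cytoplasm_{g}.csv"))
            comparison = compare_groups(tables[g_a], tables[g_b])
            _write_csv(comparison,
                       note(class_dir / "comparison_cytoplasm.csv"))
            note(class_dir / "report_cytoplasm.txt").write_text(
                format_report(comparison, g_a, g_b) + "\n")

            if class_name == "IV":
                zr_pooled = {g: concat_spectra_sets(zr_sets[g])
                             for g in scenario.group_names}
                zr_tables = {g: compute_ratios(zr_pooled[g], ZR_RATIO_BANDS, ZR)
                             for g in scenario.group_names}
                for g, tab in zr_tables.items():
                    _write_csv(tab, note(class_dir / f"ratios_zr_{g}.csv"))
                zr_comparison = compare_groups(zr_tables[g_a], zr_tables[g_b])
                _write_csv(zr_comparison, note(class_dir / "comparison_zr.csv"))
                note(class_dir / "report_zr.txt").write_text(
                    format_report(zr_comparison, g_a, g_b) + "\n")

            # pairwise PCA on pooled cytoplasm spectra
            pca = pairwise_pca(pooled[g_a], pooled[g_b])
            _write_csv(scores_table(pca), note(class_dir / "pca_scores.csv"))
            _write_csv(loadings_table(pca),
                       note(class_dir / "pca_loadings.csv"))
            _write_csv(explained_variance_table(pca),
                       note(class_dir / "pca_explained_variance.csv"))
            if render_images:
                plot_scores(pca, note(class_dir / "pca_scores.png"))
                plot_loading(pca, note(class_dir / "pca_pc1_loading.png"))

            manifest["stages"].append({
                "oocyte_class": class_name,
                "n_maps": 2 * scenario.n_maps_per_group,
                "n_cytoplasm_spectra": sum(len(s) for s in pooled.values()),
                "pc1_explained_variance": float(pca.explained_variance[0]),
                "pc1_group_correlation": group_separation(pca),
                "seconds": round(time.perf_counter() - t0, 3),
            })
            logger.info("class %s done in %.1fs", class_name,
                        manifest["stages"][-1]["seconds"])

        manifest["status"] = "completed"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
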