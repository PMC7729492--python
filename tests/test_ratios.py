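"""Band-area ratios and the pooled-t group comparison."""

import numpy as np
import pandas as pd
import pytest

from conftest import gaussian, riemann_area
from ftiri.errors import ConfigurationError, SchemaError
from ftiri.hypermap import SpectralAxis
from ftiri.preprocessing import analysis_axis, preprocess_map
from ftiri.ratios import (CYT, CYT_RATIO_BANDS, ZR, ZR_RATIO_BANDS,
                          compare_groups, compute_ratios, format_report)
from ftiri.roi import LABEL_COLUMNS, SpectraSet, concat_spectra_sets, \
    sample_spectra
from ftiri.synthetic import simulate_cohort, small_test_configs


def make_set(spectra, axis=None):
    axis = axis or analysis_axis()
    spectra = np.atleast_2d(spectra)
    labels = pd.DataFrame({
        "group": "wt", "oocyte_class": "III", "compartment": "cytoplasm",
        "map_id": "m", "row": np.arange(len(spectra)), "col": 0})
    return SpectraSet(axis=axis, spectra=spectra, labels=labels)


def cohort_ratio_tables(lipid_factor, cortisol_factor=1.0, seed=0,
                        n_maps=3, n_spectra=40):
    wt_cfg, mut_cfg = small_test_configs("III", lipid_factor, cortisol_factor)
    tables = {"wt": [], "gr": []}
    roi_seed = seed * 1009 + 1
    for member in simulate_cohort(wt_cfg, mut_cfg, n_maps, seed):
        pre = preprocess_map(member.hypermap)
        sset = sample_spectra(pre, member.truth.mask, "cytoplasm", n_spectra,
                              seed=roi_seed, group=member.group,
                              oocyte_class="III",
                              map_id=f"{member.group}{member.map_index}")
        tables[member.group].append(sset)
        roi_seed += 1
    return {g: compute_ratios(concat_spectra_sets(s), CYT_RATIO_BANDS, CYT)
            for g, s in tables.items()}


# ---------------------------------------------------------------------------
# compute_ratios
# ---------------------------------------------------------------------------

def test_ratios_invariant_to_rescaling():
    axis = analysis_axis()
    w = axis.wavenumbers
    spectrum = gaussian(w, 2925, 14, 0.2) + gaussian(w, 1655, 22, 0.6)
    a = compute_ratios(make_set(spectrum))
    b = compute_ratios(make_set(417.0 * spectrum))
    for col in [c for c in a.columns if c.endswith("/CYT")]:
        np.testing.assert_allclose(a[col], b[col], rtol=1e-12)


def test_two_gaussian_closed_form():
    """One band inside LIP (area A1), one inside PRT (area A2), nothing else:
    LIP/CYT = A1/(A1+A2) and PRT/CYT = A2/(A1+A2)."""
    axis = analysis_axis()
    w = axis.wavenumbers
    lip = (2925.0, 14.0, 0.25)
    prt = (1600.0, 18.0, 0.7)
    spectrum = gaussian(w, *lip) + gaussian(w, *prt)
    a1 = riemann_area([lip], 2820, 3002)
    a2 = riemann_area([prt], 1486, 1717)
    table = compute_ratios(make_set(spectrum))
    assert table["LIP/CYT"][0] == pytest.approx(a1 / (a1 + a2), rel=2e-3)
    assert table["PRT/CYT"][0] == pytest.approx(a2 / (a1 + a2), rel=2e-3)


def test_noise_free_ratios_match_ground_truth_areas():
    """Single-compartment noise-free pixels: computed ratios equal analytic
    band-area ratios within 0.5%."""
    wt_cfg, _ = small_test_configs("III", thickness_cv=0.0, noise_sd=0.0,
                                   vapor_amplitude=0.0)
    comp = wt_cfg.cytoplasm
    models = [(b.center, b.width, b.amplitude) for b in comp.bands]
    den_truth = riemann_area(models, 2820, 3002) + riemann_area(models, 900, 1763)
    from ftiri.synthetic import simulate_map
    hmap, truth = simulate_map(wt_cfg)
    pre = preprocess_map(hmap)
    sset = sample_spectra(pre, truth.mask, "cytoplasm", 5, seed=1)
    table = compute_ratios(sset)
    for band in CYT_RATIO_BANDS:
        want = riemann_area(models, band.lo, band.hi) / den_truth
        got = table[f"{band.name}/CYT"].mean()
        assert got == pytest.approx(want, rel=5e-3), band.name


def test_denominator_nonpositive_rows_dropped():
    axis = analysis_axis()
    good = gaussian(axis.wavenumbers, 1655, 22, 0.6)
    bad = -good
    table = compute_ratios(make_set(np.vstack([good, bad])))
    assert len(table) == 1


def test_band_outside_preprocessed_range_rejected():
    from ftiri.bands import BandDefinition
    axis = analysis_axis()
    sset = make_set(gaussian(axis.wavenumbers, 1655, 22, 0.6))
    with pytest.raises(ConfigurationError, match="outside the preprocessed"):
        compute_ratios(sset, (BandDefinition("hi", 3050, 3500),), CYT)


def test_zr_panel_has_no_crt():
    assert [b.name for b in ZR_RATIO_BANDS] == ["LIP", "FA", "PRT", "CH2", "COH"]
    assert CYT.components == ZR.components == ((2820.0, 3002.0), (900.0, 1763.0))


# ---------------------------------------------------------------------------
# compare_groups
# ---------------------------------------------------------------------------

def test_identical_tables_give_t0_p1_same_letter():
    tables = cohort_ratio_tables(1.0, n_maps=1, n_spectra=10)
    comp = compare_groups(tables["wt"], tables["wt"])
    assert np.allclose(comp["t"], 0.0)
    assert np.allclose(comp["p"], 1.0)
    assert (comp["letter_a"] == comp["letter_b"]).all()


def test_pooled_t_hand_computation():
    """{1,2,3} vs {4,5,6}: pooled t = -3.674, p = 0.0214, letters differ."""
    a = pd.DataFrame({"X": [1.0, 2.0, 3.0]})
    b = pd.DataFrame({"X": [4.0, 5.0, 6.0]})
    comp = compare_groups(a, b)
    assert comp["t"][0] == pytest.approx(-3.674, abs=1e-3)
    assert comp["p"][0] == pytest.approx(0.0214, abs=1e-3)
    assert comp["letter_a"][0] != comp["letter_b"][0]


def test_comparison_symmetric_under_group_swap():
    tables = cohort_ratio_tables(1.3, seed=2)
    ab = compare_groups(tables["wt"], tables["gr"])
    ba = compare_groups(tables["gr"], tables["wt"])
    np.testing.assert_allclose(ab["t"], -ba["t"], rtol=1e-12)
    np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-12)
    assert (ab["significant"] == ba["significant"]).all()


def test_missing_ratio_column_rejected():
    a = pd.DataFrame({"X": [1.0, 2.0], "Y": [1.0, 2.0]})
    b = pd.DataFrame({"X": [1.0, 2.0]})
    with pytest.raises(SchemaError, match="columns differ"):
        compare_groups(a, b)


def test_effect_scenario_directionality():
    """Raised lipid amplitudes push the lipid-family ratios up strongly while
    the protein and glyco ratios stay near unity fold change."""
    tables = cohort_ratio_tables(1.3, cortisol_factor=1.3, seed=4)
    comp = compare_groups(tables["wt"], tables["gr"]).set_index("ratio")
    fold = comp["mean_b"] / comp["mean_a"]
    for name in ("LIP/CYT", "CH2/CYT", "FA/CYT"):
        assert fold[name] > 1.2, name
        assert comp.loc[name, "significant"]
    # the unchanged COH tail leaks into the 1000-1137 window, diluting CRT
    assert fold["CRT/CYT"] > 1.1
    assert comp.loc["CRT/CYT", "significant"]
    for name in ("PRT/CYT", "COH/CYT"):
        assert 0.90 < fold[name] < 1.10, name


def test_per_oocyte_aggregation_reduces_n():
    tables = cohort_ratio_tables(1.0, seed=5)
    comp = compare_groups(tables["wt"], tables["gr"], aggregate_by="map_id")
    assert (comp["n_a"] == 3).all() and (comp["n_b"] == 3).all()


def test_holm_adjustment_is_monotone_and_conservative():
    tables = cohort_ratio_tables(1.3, seed=6)
    plain = compare_groups(tables["wt"], tables["gr"])
    holm = compare_groups(tables["wt"], tables["gr"], holm=True)
    assert np.all(holm["p_holm"] >= holm["p"] - 1e-15)
    assert holm["significant"].sum() <= plain["significant"].sum()


def test_report_layout_mentions_letters():
    tables = cohort_ratio_tables(1.3, seed=7, n_maps=1, n_spectra=10)
    comp = compare_groups(tables["wt"], tables["gr"])
    text = format_report(comp, "wt", "gr-/-")
    assert "LIP/CYT" in text and "±" in text
    assert "Different letters" in text
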