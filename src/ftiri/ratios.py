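"""Semi-quantitative band-area ratios and group statistics.

Each marker band's integrated area is divided by a total-biomass denominator:
CYT (cytoplasm) and ZR (zona radiata) are both defined as the sum of the
integrated areas over 3002-2820 and 1763-900 cm^-1.  Ratios are computed per
extracted spectrum; groups are compared per ratio with a classical
pooled-variance two-sample Student's t-test (Welch available behind a flag),
and compact-letter codes mark significance at p < 0.05, mirroring how such
tables are conventionally reported.  No multiple-testing correction is
applied by default; Holm adjustment is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BandDefinition, RATIO_BANDS, band_weights
from .errors import ConfigurationError, SchemaError
from .roi import LABEL_COLUMNS, SpectraSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DenominatorDefinition:
    """Total-biomass denominator: a sum of non-overlapping intervals."""

    name: str
    components: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple(tuple(sorted(c)) for c in self.components)
        object.__setattr__(self, "components", comps)
        for (a_lo, a_hi) in comps:
            for (b_lo, b_hi) in comps:
                if (a_lo, a_hi) < (b_lo, b_hi) and a_hi > b_lo:
                    raise ConfigurationError(
                        f"denominator {self.name}: overlapping components")

    def bands(self) -> list[BandDefinition]:
        return [BandDefinition(f"{self.name}_{i}", lo, hi)
                for i, (lo, hi) in enumerate(self.components)]


#: Both compartment denominators share the same spectral definition.
CYT = DenominatorDefinition("CYT", ((2820.0, 3002.0), (900.0, 1763.0)))
ZR = DenominatorDefinition("ZR", ((2820.0, 3002.0), (900.0, 1763.0)))

#: Ratio panels as reported per compartment (CRT is cytoplasm-only).
CYT_RATIO_BANDS = RATIO_BANDS
ZR_RATIO_BANDS = tuple(b for b in RATIO_BANDS if b.name != "CRT")


def compute_ratios(sset: SpectraSet,
                   band_set: tuple[BandDefinition, ...] = CYT_RATIO_BANDS,
                   denominator: DenominatorDefinition = CYT) -> pd.DataFrame:
    """Band-area ratio table: one row per spectrum, one column per ratio.

    Rows whose denominator is <= 0 are dropped (and counted in a log line).
    """
    axis = sset.axis
    for band in band_set:
        if band.lo < axis.lo or band.hi > axis.hi:
            raise ConfigurationError(
                f"band {band.name!r} [{band.lo:g}, {band.hi:g}] outside the "
                f"preprocessed range [{axis.lo:g}, {axis.hi:g}]")
    den_w = np.sum([band_weights(axis, b) for b in denominator.bands()], axis=0)
    den = sset.spectra @ den_w
    table = sset.labels.copy()
    for band in band_set:
        areas = sset.spectra @ band_weights(axis, band)
        with np.errstate(divide="ignore", invalid="ignore"):
            table[f"{band.name}/{denominator.name}"] = areas / den
    keep = den > 0
    if not np.all(keep):
        logger.warning("dropping %d spectra with non-positive %s denominator",
                       int((~keep).sum()), denominator.name)
        table = table[keep].reset_index(drop=True)
    return table


def ratio_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in LABEL_COLUMNS]


def _letters(p: float, alpha: float) -> tuple[str, str]:
    return ("a", "b") if p < alpha else ("a", "a")


def compare_groups(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   *, equal_var: bool = True, alpha: float = 0.05,
                   aggregate_by: str | None = None,
                   holm: bool = False) -> pd.DataFrame:
    """Per-ratio Student's t comparison of two ratio tables.

    ``aggregate_by`` (e.g. ``"map_id"``) averages spectra within that label
    before testing, the conservative per-oocyte alternative to per-spectrum
    pooling.  Letters differ exactly when (adjusted) p < ``alpha``.
    """
    cols_a, cols_b = ratio_columns(table_a), ratio_columns(table_b)
    if cols_a != cols_b:
        raise SchemaError(
            f"ratio columns differ between groups: {cols_a} vs {cols_b}")
    if aggregate_by is not None:
        table_a = table_a.groupby(aggregate_by, sort=True)[cols_a].mean()
        table_b = table_b.groupby(aggregate_by, sort=True)[cols_b].mean()
    rows = []
    for col in cols_a:
        a = np.asarray(table_a[col], dtype=float)
        b = np.asarray(table_b[col], dtype=float)
        if a.size < 2 or b.size < 2:
            raise SchemaError(f"ratio {col!r}: each group needs >= 2 rows")
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "ratio": col,
            "mean_a": a.mean(), "sd_a": a.std(ddof=1), "n_a": a.size,
            "mean_b": b.mean(), "sd_b": b.std(ddof=1), "n_b": b.size,
            "t": float(t), "p": float(p),
        })
    out = pd.DataFrame(rows)
    p_eff = out["p"].to_numpy().copy()
    if holm:
        order = np.argsort(p_eff)
        m = p_eff.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_eff[idx])
            adj[idx] = min(1.0, running)
        p_eff = adj
        out["p_holm"] = p_eff
    letters = [_letters(p, alpha) for p in p_eff]
    out["letter_a"] = [la for la, _ in letters]
    out["letter_b"] = [lb for _, lb in letters]
    out["significant"] = p_eff < alpha
    return out


def format_report(comparison: pd.DataFrame, name_a: str = "wt",
                  name_b: str = "gr-/-") -> str:
    """Plain-text table: mean +/- SD with significance letters per group."""
    width = max(len(r) for r in comparison["ratio"])
    lines = [f"{'ratio':<{width}}  {name_a:>24}  {name_b:>24}  {'p':>10}"]
    for _, row in comparison.iterrows():
        a = f"{row['mean_a']:.4g} ± {row['sd_a']:.3g} ^{row['letter_a']}"
        b = f"{row['mean_b']:.4g} ± {row['sd_b']:.3g} ^{row['letter_b']}"
        lines.append(f"{row['ratio']:<{width}}  {a:>24}  {b:>24}  "
                     f"{row['p']:>10.3g}")
    lines.append("Different letters indicate statistically significant "
                 "differences (p < 0.05).")
    return "\n".join(lines)
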