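"""Synthetic hyperspectral oocyte-section maps with known ground truth.

The simulator emulates mid-IR absorbance maps of zebrafish ovarian follicle
sections of two maturation classes:

* **class III** (maturing): a roughly circular oocyte filling most of a
  square map, with optional droplet-like lipid-enriched inclusions in the
  cytoplasm;
* **class IV** (fully grown): an elliptical oocyte in an elongated map,
  surrounded by a zona radiata (ZR) ring of configurable thickness, a
  glycoprotein-rich envelope.

Each compartment carries a mixture of Gaussian absorption bands (lipid CH
stretches, fatty-acid ester C=O, amide I/II, CH2 bend, COH of glycosylated
compounds, cortisol C-O) plus a linear baseline.  A pixel's spectrum is

    thickness * (sum of compartment bands + baseline)
    + vapor_amplitude * vapor_pattern + white noise,

where ``thickness`` is a per-pixel multiplicative log-normal scale (section
thickness variation, CV configurable) and the vapor pattern is the packaged
reference comb.  Band shape is Gaussian, so every true band area has the
closed form ``amplitude * width * sqrt(2*pi)`` used by the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import ConfigurationError
from .hypermap import (BACKGROUND, CYTOPLASM, ZONA_RADIATA, CompartmentMask,
                       HyperMap, SpectralAxis)
from .vapor import vapor_reference

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band: peak position, sigma, peak height."""

    name: str
    center: float          # cm^-1
    width: float           # Gaussian sigma, cm^-1
    amplitude: float       # peak absorbance
    family: str = ""       # 'lipid', 'protein', 'glyco', 'cortisol', ...

    def __post_init__(self) -> None:
        if not (800.0 <= self.center <= 4000.0):
            raise ConfigurationError(
                f"band {self.name!r}: center {self.center:g} outside 4000-800")
        if self.width <= 0:
            raise ConfigurationError(f"band {self.name!r}: width must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError(f"band {self.name!r}: amplitude must be >= 0")

    @property
    def area(self) -> float:
        """Analytic full-line area, absorbance*cm^-1."""
        return self.amplitude * self.width * SQRT_2PI

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -0.5 * ((wavenumbers - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class CompartmentComposition:
    """Band mixture plus linear baseline of one tissue compartment."""

    compartment: str       # 'cytoplasm' or 'zona_radiata'
    bands: tuple[BandModel, ...]
    baseline_slope: float = 0.0    # absorbance per cm^-1
    baseline_offset: float = 0.0   # absorbance

    def __post_init__(self) -> None:
        if self.compartment not in ("cytoplasm", "zona_radiata"):
            raise ConfigurationError(
                f"unknown compartment {self.compartment!r}")
        if len(self.bands) < 1:
            raise ConfigurationError(
                f"{self.compartment}: at least one band is required")
        for b in self.bands:
            if b.center - 3 * b.width < 800.0 or b.center + 3 * b.width > 4000.0:
                raise ConfigurationError(
                    f"band {b.name!r}: center +/- 3 widths leaves 4000-800")
        object.__setattr__(self, "bands", tuple(self.bands))

    def spectrum(self, wavenumbers: np.ndarray,
                 lipid_boost: float = 1.0) -> np.ndarray:
        """Noise-free compartment spectrum; ``lipid_boost`` scales the
        amplitude of every band of family ``'lipid'`` (droplet rendering)."""
        out = self.baseline_offset + self.baseline_slope * (
            wavenumbers - wavenumbers[0])
        for b in self.bands:
            factor = lipid_boost if b.family == "lipid" else 1.0
            out = out + factor * b.evaluate(wavenumbers)
        return out

    def band_areas(self) -> dict[str, float]:
        return {b.name: b.area for b in self.bands}

    def scaled(self, factors: dict[str, float]) -> "CompartmentComposition":
        """New composition with per-family amplitude factors applied."""
        bands = tuple(
            replace(b, amplitude=b.amplitude * factors.get(b.family, 1.0))
            for b in self.bands)
        return replace(self, bands=bands)


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, spectral axis, compositions and nuisance levels of one map."""

    oocyte_class: str                       # 'III' or 'IV'
    cytoplasm: CompartmentComposition
    zona_radiata: CompartmentComposition | None = None
    map_height_um: float = 328.0
    map_width_um: float = 328.0
    pixel_um: float = 2.56
    axis_lo: float = 800.0
    axis_hi: float = 4000.0
    axis_step: float = 4.0
    thickness_cv: float = 0.10
    noise_sd: float = 0.002
    vapor_amplitude: float = 0.03
    zr_thickness_um: float = 7.68           # class IV only
    n_droplets: int = 0                     # class III only
    droplet_radius_um: tuple[float, float] = (5.0, 10.0)
    droplet_lipid_boost: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oocyte_class not in ("III", "IV"):
            raise ConfigurationError(
                f"oocyte_class must be 'III' or 'IV', got {self.oocyte_class!r}")
        if not self.axis_lo < self.axis_hi:
            raise ConfigurationError(
                f"axis_lo {self.axis_lo:g} must be < axis_hi {self.axis_hi:g}")
        if self.axis_step <= 0:
            raise ConfigurationError("axis_step must be > 0")
        if self.pixel_um <= 0:
            raise ConfigurationError("pixel_um must be > 0")
        for name in ("thickness_cv", "noise_sd", "vapor_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for dim, name in ((self.map_height_um, "map_height_um"),
                          (self.map_width_um, "map_width_um")):
            n = math.floor(dim / self.pixel_um)
            if n < 8:
                raise ConfigurationError(f"{name} spans fewer than 8 pixels")
            if abs(dim - round(dim / self.pixel_um) * self.pixel_um) > self.pixel_um:
                raise ConfigurationError(
                    f"{name} is not divisible by pixel_um within one pixel")
        if self.oocyte_class == "IV":
            if self.zona_radiata is None:
                raise ConfigurationError(
                    "class IV maps require a zona_radiata composition")
            if self.zr_thickness_um < self.pixel_um:
                raise ConfigurationError(
                    f"zr_thickness_um = {self.zr_thickness_um:g} um is below "
                    f"one pixel ({self.pixel_um:g} um)")

    @property
    def n_rows(self) -> int:
        return math.floor(self.map_height_um / self.pixel_um)

    @property
    def n_cols(self) -> int:
        return math.floor(self.map_width_um / self.pixel_um)

    def axis(self) -> SpectralAxis:
        n = int(round((self.axis_hi - self.axis_lo) / self.axis_step))
        return SpectralAxis(self.axis_lo + self.axis_step * np.arange(n + 1))

    def same_geometry(self, other: "SimulationConfig") -> bool:
        return (self.axis() == other.axis()
                and self.pixel_um == other.pixel_um
                and self.n_rows == other.n_rows
                and self.n_cols == other.n_cols)


@dataclass
class GroundTruth:
    """What the simulator knows that the pipeline must recover."""

    mask: CompartmentMask
    band_areas: dict[str, dict[str, float]]   # compartment -> band -> area
    thickness: np.ndarray                      # per-pixel multiplicative scale
    droplet_mask: np.ndarray = field(default_factory=lambda: np.zeros((1, 1), bool))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _class_iii_mask(cfg: SimulationConfig) -> np.ndarray:
    nr, nc = cfg.n_rows, cfg.n_cols
    rr, cc = np.mgrid[0:nr, 0:nc]
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    radius = 0.45 * min(nr, nc)
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    labels = np.where(inside, CYTOPLASM, BACKGROUND)
    return labels.astype(np.int64)


def _class_iv_mask(cfg: SimulationConfig) -> np.ndarray:
    nr, nc = cfg.n_rows, cfg.n_cols
    rr, cc = np.mgrid[0:nr, 0:nc]
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    zr_px = cfg.zr_thickness_um / cfg.pixel_um
    a = 0.45 * nr - zr_px          # inner (cytoplasm) semi-axes
    b = 0.45 * nc - zr_px
    if a < 2 or b < 2:
        raise ConfigurationError(
            "zr_thickness_um leaves no room for cytoplasm in the map")
    inner = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    outer = ((rr - r0) / (a + zr_px)) ** 2 + ((cc - c0) / (b + zr_px)) ** 2 <= 1.0
    labels = np.full((nr, nc), BACKGROUND, dtype=np.int64)
    labels[outer] = ZONA_RADIATA
    labels[inner] = CYTOPLASM
    return labels


def _droplet_mask(cfg: SimulationConfig, labels: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    droplets = np.zeros_like(labels, dtype=bool)
    if cfg.n_droplets <= 0:
        return droplets
    nr, nc = labels.shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    inner_radius = 0.36 * min(nr, nc)   # keep droplets well inside the disc
    lo_px = cfg.droplet_radius_um[0] / cfg.pixel_um
    hi_px = cfg.droplet_radius_um[1] / cfg.pixel_um
    for _ in range(cfg.n_droplets):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = inner_radius * math.sqrt(rng.uniform())
        dr0 = r0 + rad * math.sin(ang)
        dc0 = c0 + rad * math.cos(ang)
        drad = rng.uniform(lo_px, hi_px)
        droplets |= (rr - dr0) ** 2 + (cc - dc0) ** 2 <= drad ** 2
    droplets &= labels == CYTOPLASM
    return droplets


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_map(config: SimulationConfig) -> tuple[HyperMap, GroundTruth]:
    """Render one synthetic section map plus its ground truth."""
    axis = config.axis()
    w = axis.wavenumbers
    rng = np.random.default_rng(config.seed)

    if config.oocyte_class == "III":
        labels = _class_iii_mask(config)
    else:
        labels = _class_iv_mask(config)
    droplets = _droplet_mask(config, labels, rng)

    base = {CYTOPLASM: config.cytoplasm.spectrum(w)}
    if config.zona_radiata is not None:
        base[ZONA_RADIATA] = config.zona_radiata.spectrum(w)
    droplet_spec = config.cytoplasm.spectrum(
        w, lipid_boost=config.droplet_lipid_boost)

    nr, nc = labels.shape
    cube = np.zeros((nr, nc, w.size))
    for code, spec in base.items():
        cube[labels == code] = spec
    cube[droplets] = droplet_spec

    # per-pixel multiplicative thickness scale, log-normal with mean 1
    if config.thickness_cv > 0:
        sigma2 = math.log1p(config.thickness_cv ** 2)
        thickness = rng.lognormal(mean=-sigma2 / 2.0,
                                  sigma=math.sqrt(sigma2), size=(nr, nc))
    else:
        thickness = np.ones((nr, nc))
    thickness = np.where(labels == BACKGROUND, 0.0, thickness)
    cube *= thickness[:, :, None]

    if config.vapor_amplitude > 0:
        cube += config.vapor_amplitude * vapor_reference(w)[None, None, :]
    if config.noise_sd > 0:
        cube += rng.normal(0.0, config.noise_sd, size=cube.shape)

    hmap = HyperMap(axis=axis, cube=cube, pixel_um=config.pixel_um,
                    metadata={"source": "ftiri.synthetic",
                              "oocyte_class": config.oocyte_class,
                              "seed": config.seed})
    areas = {"cytoplasm": config.cytoplasm.band_areas()}
    if config.zona_radiata is not None:
        areas["zona_radiata"] = config.zona_radiata.band_areas()
    truth = GroundTruth(
        mask=CompartmentMask(labels=labels, pixel_um=config.pixel_um),
        band_areas=areas, thickness=thickness, droplet_mask=droplets)
    return hmap, truth


@dataclass(frozen=True)
class CohortMember:
    group: str
    map_index: int
    hypermap: HyperMap
    truth: GroundTruth


def simulate_cohort(wt_config: SimulationConfig,
                    mut_config: SimulationConfig,
                    n_maps_per_group: int,
                    seed: int) -> list[CohortMember]:
    """Simulate matched cohorts; per-map seeds = master seed + map index."""
    if not wt_config.same_geometry(mut_config):
        raise ConfigurationError(
            "wt and mutant configs must share axis and pixel geometry")
    members: list[CohortMember] = []
    index = 0
    for group, cfg in (("wt", wt_config), ("gr", mut_config)):
        for i in range(n_maps_per_group):
            per_map = replace(cfg, seed=seed + index)
            hmap, truth = simulate_map(per_map)
            members.append(CohortMember(group=group, map_index=i,
                                        hypermap=hmap, truth=truth))
            index += 1
    return members


# ---------------------------------------------------------------------------
# Default study compositions
# ---------------------------------------------------------------------------

def cytoplasm_composition(lipid_factor: float = 1.0,
                          cortisol_factor: float = 1.0,
                          oocyte_class: str = "III") -> CompartmentComposition:
    """Yolk-protein-dominated cytoplasm of a vitellogenic oocyte.

    Amplitudes put the lipid CH-stretch area near 8% of the CYT denominator,
    with amide I/II carrying most of the biomass signal.  ``lipid_factor``
    scales the lipid-family bands and ``cortisol_factor`` the cortisol band
    (the mutant-like contrast).
    """
    amide_i = 0.70 if oocyte_class == "IV" else 0.60
    bands = (
        BandModel("lip_2925", 2925.0, 14.0, 0.10, family="lipid"),
        BandModel("lip_2852", 2852.0, 12.0, 0.06, family="lipid"),
        BandModel("fa_1740", 1740.0, 12.0, 0.08, family="lipid"),
        BandModel("amide_i_1655", 1655.0, 22.0, amide_i, family="protein"),
        BandModel("amide_ii_1545", 1545.0, 20.0, 0.35, family="protein"),
        BandModel("ch2_1455", 1455.0, 12.0, 0.08, family="lipid"),
        BandModel("coh_1160", 1160.0, 14.0, 0.12, family="glyco"),
        BandModel("crt_1060", 1060.0, 12.0, 0.06, family="cortisol"),
    )
    comp = CompartmentComposition(compartment="cytoplasm", bands=bands,
                                  baseline_slope=1.0e-5, baseline_offset=0.02)
    return comp.scaled({"lipid": lipid_factor, "cortisol": cortisol_factor})


def zona_radiata_composition(lipid_factor: float = 1.0) -> CompartmentComposition:
    """Glycoprotein-rich zona radiata envelope (class IV)."""
    bands = (
        BandModel("lip_2925", 2925.0, 14.0, 0.02, family="lipid"),
        BandModel("fa_1740", 1740.0, 12.0, 0.02, family="lipid"),
        BandModel("amide_i_1655", 1655.0, 22.0, 0.50, family="protein"),
        BandModel("amide_ii_1545", 1545.0, 20.0, 0.30, family="protein"),
        BandModel("ch2_1455", 1455.0, 12.0, 0.03, family="lipid"),
        BandModel("coh_1160", 1160.0, 14.0, 0.35, family="glyco"),
    )
    comp = CompartmentComposition(compartment="zona_radiata", bands=bands,
                                  baseline_slope=1.0e-5, baseline_offset=0.02)
    return comp.scaled({"lipid": lipid_factor})


def class_config(oocyte_class: str,
                 lipid_factor: float = 1.0,
                 cortisol_factor: float = 1.0,
                 seed: int = 0,
                 **overrides) -> SimulationConfig:
    """Study-condition config for one oocyte class and one genotype contrast."""
    cyt = cytoplasm_composition(lipid_factor, cortisol_factor, oocyte_class)
    if oocyte_class == "III":
        defaults = dict(map_height_um=328.0, map_width_um=328.0,
                        n_droplets=10)
        zr = None
    else:
        defaults = dict(map_height_um=164.0, map_width_um=492.0,
                        zr_thickness_um=7.68)
        zr = zona_radiata_composition(lipid_factor)
    defaults.update(overrides)
    return SimulationConfig(oocyte_class=oocyte_class, cytoplasm=cyt,
                            zona_radiata=zr, seed=seed, **defaults)


def effect_configs(oocyte_class: str = "III",
                   lipid_factor: float = 1.3,
                   cortisol_factor: float = 1.3,
                   **overrides) -> tuple[SimulationConfig, SimulationConfig]:
    """(wt-like, mutant-like) config pair differing only in band amplitudes."""
    wt = class_config(oocyte_class, 1.0, 1.0, **overrides)
    mut = class_config(oocyte_class, lipid_factor, cortisol_factor, **overrides)
    return wt, mut


def small_test_configs(oocyte_class: str = "III",
                       lipid_factor: float = 1.0,
                       cortisol_factor: float = 1.0,
                       **overrides) -> tuple[SimulationConfig, SimulationConfig]:
    """Reduced 32x32-pixel geometry for simulation studies (null / power)."""
    small = dict(map_height_um=81.92, map_width_um=81.92, n_droplets=0)
    if oocyte_class == "IV":
        small = dict(map_height_um=81.92, map_width_um=163.84,
                     zr_thickness_um=7.68)
    small.update(overrides)
    wt = class_config(oocyte_class, 1.0, 1.0, **small)
    mut = class_config(oocyte_class, lipid_factor, cortisol_factor, **small)
    return wt, mut


def iter_scenario_maps(wt_config: SimulationConfig,
                       mut_config: SimulationConfig,
                       n_maps_per_group: int,
                       seed: int) -> Iterator[CohortMember]:
    """Memory-light generator form of :func:`simulate_cohort`."""
    if not wt_config.same_geometry(mut_config):
        raise ConfigurationError(
            "wt and mutant configs must share axis and pixel geometry")
    index = 0
    for group, cfg in (("wt", wt_config), ("gr", mut_config)):
        for i in range(n_maps_per_group):
            per_map = replace(cfg, seed=seed + index)
            hmap, truth = simulate_map(per_map)
            yield CohortMember(group=group, map_index=i,
                               hypermap=hmap, truth=truth)
            index += 1
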