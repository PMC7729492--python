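"""Human-readable scenario files describing a two-group simulation study.

A scenario YAML names the shared geometry/axis/nuisance settings, the oocyte
classes to map, and the per-group band-amplitude factors (the genotype
contrast).  The shipped demo scenario mirrors the study layout: a wild-type
group and a mutant-like group with lipid-family and cortisol amplitudes
raised by 30%, three oocytes per group in each of classes III and IV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthetic import SimulationConfig, class_config


@dataclass(frozen=True)
class Scenario:
    """Parsed scenario: per-class (wt-like, mutant-like) config pairs."""

    name: str
    n_maps_per_group: int
    seed: int
    classes: dict[str, tuple[SimulationConfig, SimulationConfig]]
    group_names: tuple[str, str]
    n_cytoplasm: int = 40
    n_zona_radiata: int = 10

    def __post_init__(self) -> None:
        if self.n_maps_per_group < 1:
            raise ConfigurationError(
                "scenario requires n_maps_per_group >= 1 (zero maps configured)")
        if not self.classes:
            raise ConfigurationError("scenario names no oocyte classes")


def _build_class_configs(class_name: str, class_spec: dict, shared: dict,
                         groups: dict) -> tuple[SimulationConfig, SimulationConfig]:
    overrides = dict(shared)
    overrides.update({k: v for k, v in class_spec.items()
                      if k not in ("droplets",)})
    droplets = class_spec.get("droplets")
    if droplets:
        overrides["n_droplets"] = int(droplets.get("n", 0))
        if "radius_um" in droplets:
            overrides["droplet_radius_um"] = tuple(droplets["radius_um"])
        if "lipid_boost" in droplets:
            overrides["droplet_lipid_boost"] = float(droplets["lipid_boost"])
    (wt_name, wt_spec), (mut_name, mut_spec) = list(groups.items())
    cfgs = []
    for spec in (wt_spec, mut_spec):
        cfgs.append(class_config(
            class_name,
            lipid_factor=float(spec.get("lipid_factor", 1.0)),
            cortisol_factor=float(spec.get("cortisol_factor", 1.0)),
            **overrides))
    return cfgs[0], cfgs[1]


def load_scenario(path: str | Path) -> Scenario:
    """Parse a scenario YAML into per-class simulation config pairs.

    Groups are taken in file order: the first entry is the reference
    (wild-type-like) group, the second the comparison group.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"scenario file {path} is not a mapping")
    for key in ("classes", "groups"):
        if key not in raw:
            raise ConfigurationError(f"scenario lacks required key {key!r}")
    groups = raw["groups"]
    if len(groups) != 2:
        raise ConfigurationError(
            f"scenario must define exactly 2 groups, found {len(groups)}")
    axis = raw.get("axis", {})
    shared = {
        "axis_lo": float(axis.get("lo", 800.0)),
        "axis_hi": float(axis.get("hi", 4000.0)),
        "axis_step": float(axis.get("step", 4.0)),
        "pixel_um": float(raw.get("pixel_um", 2.56)),
        "thickness_cv": float(raw.get("thickness_cv", 0.10)),
        "noise_sd": float(raw.get("noise_sd", 0.002)),
        "vapor_amplitude": float(raw.get("vapor_amplitude", 0.03)),
    }
    classes = {}
    for class_name, class_spec in raw["classes"].items():
        if class_name not in ("III", "IV"):
            raise ConfigurationError(
                f"unknown oocyte class {class_name!r} in scenario")
        classes[class_name] = _build_class_configs(
            class_name, class_spec or {}, shared, groups)
    return Scenario(
        name=str(raw.get("name", Path(path).stem)),
        n_maps_per_group=int(raw.get("n_maps_per_group", 3)),
        seed=int(raw.get("seed", 0)),
        classes=classes,
        group_names=tuple(groups.keys()),
        n_cytoplasm=int(raw.get("n_cytoplasm", 40)),
        n_zona_radiata=int(raw.get("n_zona_radiata", 10)),
    )


def demo_scenario_path() -> Path:
    """Path of the packaged demo scenario YAML."""
    with resources.as_file(
            resources.files("ftiri").joinpath("data/demo_scenario.yaml")) as p:
        return Path(p)


def demo_scenario() -> Scenario:
    return load_scenario(demo_scenario_path())
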