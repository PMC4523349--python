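"""Structured-config I/O: species models and factor spaces as YAML.

A species file holds the species name, the breakpoint list of each
suitability curve, the optional second ADBL curve with its salinity
threshold, and the surface light transmission.  A ``factors`` section, when
present, overrides the default factor space.  Read/write round-trips are
lossless (floats are serialised exactly).

Two example species files ship with the package — approximate
reconstructions of published look-up graphs for *Halodule wrightii* (shoal
grass) and *Vallisneria americana* (tape grass); see each file's header.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .factors import FactorSpec, FactorSpace, default_factor_space
from .hsi import SpeciesModel, SuitabilityCurve

__all__ = [
    "load_species",
    "save_species",
    "species_from_dict",
    "species_to_dict",
    "factor_space_from_list",
    "factor_space_to_list",
    "example_species_path",
    "example_species",
    "EXAMPLE_SPECIES",
]

EXAMPLE_SPECIES = ("halodule_wrightii", "vallisneria_americana")


def _curve(name: str, data) -> SuitabilityCurve:
    return SuitabilityCurve(name, tuple((float(x), float(s)) for x, s in data))


def species_from_dict(doc: dict) -> SpeciesModel:
    spec = doc["species"]
    curves = spec["curves"]
    if "adbl" in curves:
        adbl = (_curve("adbl", curves["adbl"]),)
        threshold = None
    else:
        adbl = (
            _curve("adbl", curves["adbl_low_salinity"]),
            _curve("adbl", curves["adbl_high_salinity"]),
        )
        threshold = float(spec["adbl_salinity_threshold"])
    return SpeciesModel(
        name=spec["name"],
        salinity_curve=_curve("salinity", curves["salinity"]),
        temperature_curve=_curve("temperature", curves["temperature"]),
        adbl_curves=adbl,
        adbl_salinity_threshold=threshold,
        surface_transmission=float(spec.get("surface_transmission", 0.9)),
    )


def species_to_dict(model: SpeciesModel) -> dict:
    def pts(curve: SuitabilityCurve):
        return [[float(x), float(s)] for x, s in curve.breakpoints]

    curves: dict = {
        "salinity": pts(model.salinity_curve),
        "temperature": pts(model.temperature_curve),
    }
    spec: dict = {"name": model.name, "surface_transmission": model.surface_transmission}
    if len(model.adbl_curves) == 1:
        curves["adbl"] = pts(model.adbl_curves[0])
    else:
        curves["adbl_low_salinity"] = pts(model.adbl_curves[0])
        curves["adbl_high_salinity"] = pts(model.adbl_curves[1])
        spec["adbl_salinity_threshold"] = model.adbl_salinity_threshold
    spec["curves"] = curves
    return {"species": spec}


def factor_space_from_list(items) -> FactorSpace:
    factors = []
    for it in items:
        factors.append(
            FactorSpec(
                name=it["name"],
                kind=it["kind"],
                low=float(it.get("low", 0.8)),
                high=float(it.get("high", 1.2)),
                levels=tuple(it.get("levels", ())),
            )
        )
    return FactorSpace(tuple(factors))


def factor_space_to_list(space: FactorSpace) -> list:
    out = []
    for f in space.factors:
        item: dict = {"name": f.name, "kind": f.kind}
        if f.kind == "discrete":
            item["levels"] = list(f.levels)
        else:
            item["low"] = f.low
            item["high"] = f.high
        out.append(item)
    return out


def load_species(path) -> tuple[SpeciesModel, FactorSpace]:
    """Load a species config; the factor space defaults when not specified."""
    doc = yaml.safe_load(Path(path).read_text())
    model = species_from_dict(doc)
    if "factors" in doc:
        space = factor_space_from_list(doc["factors"])
    else:
        space = default_factor_space(model)
    return model, space


def save_species(model: SpeciesModel, path, space: FactorSpace | None = None) -> None:
    doc = species_to_dict(model)
    if space is not None:
        doc["factors"] = factor_space_to_list(space)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def example_species_path(name: str) -> Path:
    """Filesystem path of a shipped example species config."""
    if name not in EXAMPLE_SPECIES:
        raise ValueError(f"unknown example species {name!r}; choose from {EXAMPLE_SPECIES}")
    return Path(resources.files("savgsa").joinpath("species", f"{name}.yaml"))


def example_species(name: str) -> tuple[SpeciesModel, FactorSpace]:
    """Load one of the shipped example species models."""
    return load_species(example_species_path(name))
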