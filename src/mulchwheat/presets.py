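"""Shipped parameter sets: the two Ludhiana soils, the PBW343 cultivar
presets (bare and mulched) and the Ludhiana monthly climate normals."""

from __future__ import annotations

from importlib import resources

import yaml

from .crop import CropParams
from .soil import SoilLayer, SoilProfile
from .weather import ClimateNormals, MonthNormal

__all__ = ["load_soil", "load_cultivar", "ludhiana_normals", "SOIL_NAMES"]

SOIL_NAMES = ("sandy_loam", "clay_loam")


def _read_yaml(name: str) -> dict:
    path = resources.files("mulchwheat.data").joinpath(name)
    return yaml.safe_load(path.read_text())


def load_soil(name: str) -> SoilProfile:
    """Load a shipped soil profile (``sandy_loam`` or ``clay_loam``)."""
    if name not in SOIL_NAMES:
        raise ValueError(f"unknown soil {name!r}; choose from {SOIL_NAMES}")
    raw = _read_yaml(f"soil_{name}.yaml")
    layers = [
        SoilLayer(
            thickness_mm=(d["bottom_cm"] - d["top_cm"]) * 10.0,
            ll=d["ll"], dul=d["dul"], sat=d["sat"], bd=d["bd"],
            swcon=d["swcon"], kl=d["kl"],
        )
        for d in raw["layers"]
    ]
    return SoilProfile(layers=layers, u_mm=raw["u_mm"], cona=raw["cona"],
                       bund_mm=raw["bund_mm"], name=raw["name"])


def load_cultivar(name: str) -> CropParams:
    """Load a cultivar preset (``pbw343_bare`` or ``pbw343_mulch``)."""
    raw = _read_yaml("cultivars.yaml")
    if name not in raw:
        raise ValueError(f"unknown cultivar {name!r}; choose from {sorted(raw)}")
    entry = dict(raw[name])
    parent = entry.pop("inherits", None)
    if parent:
        merged = dict(raw[parent])
        merged.pop("inherits", None)
        merged.update(entry)
        entry = merged
    entry["trap_x"] = tuple(entry["trap_x"])
    entry["trap_y"] = tuple(entry["trap_y"])
    return CropParams(**entry)


def ludhiana_normals() -> ClimateNormals:
    """Monthly climate normals for Ludhiana (wheat-season months observed;
    off-season months are documented assumptions)."""
    raw = _read_yaml("ludhiana_normals.yaml")
    months = {
        int(m): MonthNormal(
            tmax=d["tmax"], tmin=d["tmin"], radn=d["radn"],
            rain_mean=d["rain_mean"], rain_min=d["rain_min"],
            rain_max=d["rain_max"], observed=d["observed"],
        )
        for m, d in raw["months"].items()
    }
    return ClimateNormals(months=months, latitude=raw["latitude"])
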