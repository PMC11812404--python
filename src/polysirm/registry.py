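"""Loading and validation of the metabolite registry.

The registry maps metabolite names to their base formula, Fmoc tag count and
measurement metadata. A default registry covering the polyamine pathway
(SPD, PUT, ornithine, citrulline, arginine, agmatine, carbamoylputrescine,
acetylputrescine, diacetylspermidine, glutamate, SAM, MTA) ships with the
package; user registries are YAML files with the same schema.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .constants import SCAN_WINDOW_MZ
from .formulas import DerivatizedSpecies, FormulaError, parse_formula

__all__ = ["load_registry", "default_registry", "RegistryError"]


class RegistryError(ValueError):
    """Invalid registry file or registry entry."""


def _entry_to_species(entry: dict) -> DerivatizedSpecies:
    try:
        name = entry["name"]
        formula = parse_formula(entry["formula"])
    except KeyError as exc:
        raise RegistryError(f"registry entry missing field {exc}") from exc
    except FormulaError as exc:
        raise RegistryError(str(exc)) from exc
    rt = entry.get("rt_window")
    sp = DerivatizedSpecies(
        metabolite_name=name,
        base_formula=formula,
        n_tags=int(entry.get("n_tags", 0)),
        reactive_amines=entry.get("reactive_amines"),
        rt_window=tuple(rt) if rt else None,
        polarity=entry.get("polarity", "positive"),
    )
    lo, hi = SCAN_WINDOW_MZ
    mz = sp.mz_monoisotopic
    if not lo <= mz <= hi:
        raise RegistryError(
            f"{name}: monoisotopic [M+H]+ {mz:.4f} outside scan window {lo}-{hi}"
        )
    return sp


def load_registry(path: str | Path | None = None) -> dict[str, DerivatizedSpecies]:
    """Load a registry YAML; with no path, load the packaged default.

    Every species is validated on load: tag count vs reactive amines, and
    the derivatized [M+H]+ falling inside the 75-1000 m/z scan window.
    """
    if path is None:
        text = (
            resources.files("polysirm").joinpath("data/registry.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    entries = yaml.safe_load(text)
    if not isinstance(entries, list):
        raise RegistryError("registry YAML must be a list of entries")
    registry: dict[str, DerivatizedSpecies] = {}
    for entry in entries:
        sp = _entry_to_species(entry)
        if sp.metabolite_name in registry:
            raise RegistryError(f"duplicate registry entry: {sp.metabolite_name}")
        registry[sp.metabolite_name] = sp
    return registry


def default_registry() -> dict[str, DerivatizedSpecies]:
    """The packaged polyamine-pathway registry."""
    return load_registry(None)
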