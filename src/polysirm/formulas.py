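"""Molecular-formula arithmetic and Fmoc-derivatization accounting.

Polyamines are derivatized with Fmoc-OSu before LC-HRMS: each reacted
primary/secondary amine net-gains C15H10O2. The carbons introduced by the
tag can never carry tracer label, so every derivatized species keeps an
explicit split between *labelable* carbons (the metabolite backbone) and
*tag* carbons (15 per Fmoc group). That split drives both the isotopologue
m/z ladder and the natural-abundance correction matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .constants import (
    C13_C12_MASS_DIFF,
    FMOC_NET_ADDITION,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
)

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "parse_formula",
    "DerivatizedSpecies",
    "derivatize",
    "isotopologue_mz",
]


class FormulaError(ValueError):
    """Malformed formula text or invalid formula arithmetic."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> atom-count map for a neutral species.

    Supports element-wise ``+`` and ``-`` (subtraction that would produce a
    negative count raises) and integer scaling with ``*``.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int,)) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n!r}")
            if n > 0:
                clean[el] = int(n)
        object.__setattr__(self, "counts", MappingProxyType(clean))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count ({left})"
                )
            merged[el] = left
        return MolecularFormula(merged)

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula scaling requires a non-negative int, got {k!r}")
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    @property
    def carbons(self) -> int:
        return self["C"]

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass (all-lightest-isotope), Da."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts.items())

    def hill(self) -> str:
        """Hill notation: C, then H, then remaining elements alphabetically."""
        parts = []
        for el in ["C", "H"] + sorted(set(self.counts) - {"C", "H"}):
            n = self[el]
            if n:
                parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C7H19N3"``.

    Round-trips through :meth:`MolecularFormula.hill`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


FMOC_FORMULA = MolecularFormula(FMOC_NET_ADDITION)


@dataclass(frozen=True)
class DerivatizedSpecies:
    """A metabolite together with its Fmoc tag count and adduct.

    ``labelable_carbons`` are the carbons of the underivatized metabolite
    (eligible for 13C tracer); ``tag_carbons`` (= 15 per Fmoc) come from the
    derivatization reagent and only ever carry natural-abundance 13C.
    """

    metabolite_name: str
    base_formula: MolecularFormula
    n_tags: int = 0
    adduct: str = "[M+H]+"
    charge: int = 1
    reactive_amines: int | None = None
    rt_window: tuple[float, float] | None = None
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.n_tags < 0:
            raise FormulaError("n_tags must be >= 0")
        if self.charge < 1:
            raise FormulaError("charge must be >= 1")
        if self.reactive_amines is not None and self.n_tags > self.reactive_amines:
            raise FormulaError(
                f"{self.metabolite_name}: n_tags={self.n_tags} exceeds "
                f"declared reactive amines ({self.reactive_amines})"
            )

    @property
    def labelable_carbons(self) -> int:
        return self.base_formula.carbons

    @property
    def tag_carbons(self) -> int:
        return 15 * self.n_tags

    @property
    def formula(self) -> MolecularFormula:
        """Full formula of the derivatized (neutral) species."""
        return self.base_formula + self.n_tags * FMOC_FORMULA

    @property
    def mz_monoisotopic(self) -> float:
        return isotopologue_mz(self, 0)


def derivatize(
    base: MolecularFormula,
    n_tags: int,
    *,
    metabolite_name: str = "",
    reactive_amines: int | None = None,
    **kwargs,
) -> DerivatizedSpecies:
    """Attach ``n_tags`` Fmoc groups to ``base`` (net +C15H10O2 each)."""
    return DerivatizedSpecies(
        metabolite_name=metabolite_name or base.hill(),
        base_formula=base,
        n_tags=n_tags,
        reactive_amines=reactive_amines,
        **kwargs,
    )


def isotopologue_mz(sp: DerivatizedSpecies, i: int) -> float:
    """m/z of the i-th tracer isotopologue (i 13C atoms in the backbone).

    Spacing between consecutive isotopologues is exactly the 13C-12C mass
    difference divided by charge.
    """
    if not 0 <= i <= sp.labelable_carbons:
        raise ValueError(
            f"isotopologue index {i} out of range 0..{sp.labelable_carbons} "
            f"for {sp.metabolite_name}"
        )
    neutral = sp.formula.monoisotopic_mass + i * C13_C12_MASS_DIFF
    return (neutral + sp.charge * PROTON_MASS) / sp.charge
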