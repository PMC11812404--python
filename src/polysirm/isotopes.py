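"""Natural-abundance isotope patterns, correction matrices, and stripping.

The measured isotopologue pattern of a derivatized metabolite mixes three
signals: tracer-derived 13C in the metabolite backbone, natural heavy
isotopes in the (unlabeled) backbone positions, and natural heavy isotopes
in the atoms added by the Fmoc tag. Stripping deconvolves the first from the
other two by solving a non-negative least-squares problem

    min ||A x - m||^2   s.t. x >= 0,

where column i of the correction matrix A is the distribution of *observed*
mass shifts produced by a molecule carrying exactly i tracer 13C atoms.
The solution, normalized to molar fractions f_0..f_n, yields the
per-isotopologue fractional enrichments and the total labeled fraction
sigma13C = sum_{i>=1} f_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .constants import ISOTOPES
from .formulas import DerivatizedSpecies, MolecularFormula

__all__ = [
    "natural_pattern",
    "CorrectionMatrix",
    "build_correction_matrix",
    "IsotopologueVector",
    "CorrectedDistribution",
    "strip",
    "enrichment_summary",
]

ARMS = ("tracer_13C", "control_12C")
COMPARTMENTS = ("cell", "medium")


def _single_atom_pmf(element: str, abundances: dict[str, list[tuple[float, float]]]):
    """Probability over integer mass shifts for one atom of ``element``."""
    isotopes = abundances[element]
    m0 = isotopes[0][0]
    max_shift = int(round(isotopes[-1][0] - m0))
    pmf = np.zeros(max_shift + 1)
    for mass, ab in isotopes:
        pmf[int(round(mass - m0))] += ab
    return pmf / pmf.sum()


def _pmf_power(pmf: np.ndarray, n: int) -> np.ndarray:
    """Distribution of the shift sum over n i.i.d. atoms (n-fold convolution)."""
    out = np.array([1.0])
    base = pmf
    # exponentiation by squaring keeps this cheap even for C50+ tags
    while n > 0:
        if n & 1:
            out = np.convolve(out, base)
        base = np.convolve(base, base)
        n >>= 1
    return out


def natural_pattern(
    formula: MolecularFormula,
    elements: Sequence[str] = ("C",),
    abundances: dict | None = None,
) -> np.ndarray:
    """Natural-abundance mass-shift distribution of ``formula``.

    Only heavy isotopes of ``elements`` contribute; all other atoms are
    treated as monoisotopic. Returns a probability vector over integer mass
    shifts (index 0 = all-light), summing to 1. An empty formula gives
    ``[1.0]``.
    """
    abundances = abundances if abundances is not None else ISOTOPES
    pattern = np.array([1.0])
    for el in elements:
        n = formula[el]
        if n == 0:
            continue
        if el not in abundances:
            raise KeyError(f"no abundance table for element {el!r}")
        pattern = np.convolve(pattern, _pmf_power(_single_atom_pmf(el, abundances), n))
    return pattern


@dataclass(frozen=True)
class CorrectionMatrix:
    """(n+1)x(n+1) natural-abundance correction matrix for one species.

    Column i is the pmf of observed mass shifts given i tracer 13C atoms,
    truncated to shifts 0..n. With no purity correction the matrix is lower
    triangular; with tracer purity p < 1 labeled positions may revert to 12C
    and mass can shift below i.
    """

    A: np.ndarray
    species: DerivatizedSpecies
    elements: tuple[str, ...] = ("C",)
    purity: float = 1.0

    @property
    def n(self) -> int:
        return self.A.shape[0] - 1


def build_correction_matrix(
    sp: DerivatizedSpecies,
    elements: Sequence[str] = ("C",),
    purity: float = 1.0,
    abundances: dict | None = None,
) -> CorrectionMatrix:
    """Build the stripping matrix for ``sp``.

    Column i combines (a) natural 13C in the n-i unlabeled backbone carbons,
    (b) natural heavy isotopes of all tag atoms — the Fmoc carbons plus, if
    non-carbon elements are being corrected, those elements over the whole
    derivatized formula — and (c), when ``purity`` < 1, reversion of labeled
    positions to 12C with probability 1-p (a downward shift).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"tracer purity must be in (0, 1], got {purity}")
    elements = tuple(elements)
    if "C" not in elements:
        raise ValueError("carbon must always be among the corrected elements")
    abund = abundances if abundances is not None else ISOTOPES
    n = sp.labelable_carbons

    # atoms whose natural isotopes contribute identically in every column:
    # the tag carbons, plus all atoms of any corrected non-C element
    tag_counts: dict[str, int] = {}
    if sp.tag_carbons:
        tag_counts["C"] = sp.tag_carbons
    full = sp.formula
    for el in elements:
        if el != "C" and full[el]:
            tag_counts[el] = full[el]
    tag_pattern = natural_pattern(MolecularFormula(tag_counts), elements, abund)

    c_pmf = _single_atom_pmf("C", abund)
    A = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        backbone = _pmf_power(c_pmf, n - i)  # natural 13C in unlabeled positions
        col = np.convolve(backbone, tag_pattern)  # shifts >= 0 relative to i
        offsets = np.arange(col.size)
        if purity < 1.0 and i > 0:
            from scipy.stats import binom

            down = binom.pmf(np.arange(i + 1), i, 1.0 - purity)  # k 12C reversions
            col = np.convolve(col, down)
            offsets = np.arange(col.size) - i
        rows = i + offsets
        ok = (rows >= 0) & (rows <= n)
        np.add.at(A[:, i], rows[ok], col[ok])
    return CorrectionMatrix(A=A, species=sp, elements=elements, purity=purity)


@dataclass
class IsotopologueVector:
    """Raw isotopologue peak areas for one sample x metabolite."""

    species: DerivatizedSpecies
    areas: np.ndarray
    sample_id: str = ""
    compartment: str = "cell"
    arm: str = "tracer_13C"

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        n = self.species.labelable_carbons
        if self.areas.shape != (n + 1,):
            raise ValueError(
                f"{self.species.metabolite_name}: expected {n + 1} areas "
                f"(shifts 0..{n}), got {self.areas.shape}"
            )
        if np.any(self.areas < 0):
            raise ValueError("peak areas must be >= 0")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")


@dataclass
class CorrectedDistribution:
    """Molar isotopologue fractions after natural-abundance stripping.

    ``fractions[i]`` is the molar fraction of the i-labeled isotopologue
    (the per-isotopologue "% of the total carbon pool"); ``sigma13C`` their
    sum over i >= 1 (the total 13C-labeled fraction); ``atom_enrichment``
    the mean labeled-carbon fraction sum(i f_i)/n. ``residual`` is the
    stripping fit residual norm relative to the input area norm.
    """

    species: DerivatizedSpecies
    fractions: np.ndarray
    residual: float
    sample_id: str = ""
    compartment: str = "cell"
    arm: str = "tracer_13C"

    @property
    def sigma13C(self) -> float:
        return float(self.fractions[1:].sum())

    @property
    def atom_enrichment(self) -> float:
        n = self.fractions.size - 1
        if n == 0:
            return 0.0
        return float(np.arange(n + 1) @ self.fractions / n)


def strip(raw: IsotopologueVector, cm: CorrectionMatrix) -> CorrectedDistribution:
    """Natural-abundance stripping by non-negative least squares.

    NNLS (rather than triangular back-substitution with clipping) keeps all
    fractions physical when noise would otherwise drive small isotopologues
    negative; on noise-free data the two coincide.
    """
    m = raw.areas
    if cm.A.shape[0] != m.size:
        raise ValueError(
            f"area vector length {m.size} does not match correction matrix "
            f"dimension {cm.A.shape[0]}"
        )
    total = m.sum()
    if total <= 0:
        raise ValueError("all-zero area vector cannot be stripped")
    # diagonal >= product of light-isotope abundances > 0: always solvable
    assert np.all(np.diag(cm.A) > 0), "degenerate correction matrix"
    x, rnorm = nnls(cm.A, m)
    s = x.sum()
    if s <= 0:
        raise ValueError("stripping produced an all-zero solution")
    return CorrectedDistribution(
        species=raw.species,
        fractions=x / s,
        residual=float(rnorm / np.linalg.norm(m)),
        sample_id=raw.sample_id,
        compartment=raw.compartment,
        arm=raw.arm,
    )


def enrichment_summary(d: CorrectedDistribution) -> pd.DataFrame:
    """Per-isotopologue enrichment table (i, fraction, sigma13C)."""
    n = d.fractions.size - 1
    return pd.DataFrame(
        {
            "metabolite": d.species.metabolite_name,
            "sample_id": d.sample_id,
            "isotopologue_index": np.arange(n + 1),
            "fraction": d.fractions,
            "sigma13C": d.sigma13C,
            "atom_enrichment": d.atom_enrichment,
            "residual": d.residual,
        }
    )
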