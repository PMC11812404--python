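"""Peak-table in, enrichment table out: the canonical analysis path.

Consumes the long-format peak table (sample_id, arm, compartment,
metabolite, isotopologue_index, area), applies natural-abundance stripping
per sample x metabolite with the registry's derivatization bookkeeping, and
emits a tidy per-isotopologue enrichment table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formulas import DerivatizedSpecies
from .isotopes import IsotopologueVector, build_correction_matrix, strip
from .registry import default_registry

__all__ = ["read_peak_table", "enrich_table", "summarize_enrichment"]

log = logging.getLogger(__name__)

PEAK_TABLE_COLUMNS = [
    "sample_id", "arm", "compartment", "metabolite", "isotopologue_index", "area",
]


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format peak-area CSV."""
    df = pd.read_csv(path)
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def enrich_table(
    peaks: pd.DataFrame,
    registry: dict[str, DerivatizedSpecies] | None = None,
    elements: Sequence[str] = ("C",),
    purity: float = 1.0,
) -> pd.DataFrame:
    """Strip natural abundance from every sample x metabolite in a table.

    Missing isotopologue rows are zero-filled (and logged), never imputed;
    metabolites absent from the registry are skipped with a log message.
    Returns one row per sample x metabolite x isotopologue with the molar
    fraction, sigma13C, atom enrichment and fit residual.
    """
    registry = registry or default_registry()
    matrices = {}
    out = []
    for (sample_id, metabolite), grp in peaks.groupby(
        ["sample_id", "metabolite"], sort=True
    ):
        sp = registry.get(metabolite)
        if sp is None:
            log.info("metabolite %r not in registry; skipped", metabolite)
            continue
        n = sp.labelable_carbons
        areas = np.zeros(n + 1)
        idx = grp["isotopologue_index"].to_numpy(dtype=int)
        if np.any((idx < 0) | (idx > n)):
            raise ValueError(
                f"{metabolite}: isotopologue index outside 0..{n}"
            )
        areas[idx] = grp["area"].to_numpy(dtype=float)
        if len(idx) < n + 1:
            log.info(
                "%s/%s: %d of %d isotopologues present; missing zero-filled",
                sample_id, metabolite, len(idx), n + 1,
            )
        if areas.sum() <= 0:
            log.warning("%s/%s: all-zero areas; skipped", sample_id, metabolite)
            continue
        key = (metabolite, tuple(elements), purity)
        if key not in matrices:
            matrices[key] = build_correction_matrix(sp, elements, purity)
        arm = str(grp["arm"].iloc[0])
        compartment = str(grp["compartment"].iloc[0])
        vec = IsotopologueVector(
            species=sp, areas=areas, sample_id=str(sample_id),
            compartment=compartment, arm=arm,
        )
        d = strip(vec, matrices[key])
        for i in range(n + 1):
            out.append(
                (
                    sample_id, arm, compartment, metabolite, i,
                    float(d.fractions[i]), d.sigma13C, d.atom_enrichment,
                    d.residual,
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "sample_id", "arm", "compartment", "metabolite",
            "isotopologue_index", "fraction", "sigma13C", "atom_enrichment",
            "residual",
        ],
    )


def summarize_enrichment(enriched: pd.DataFrame) -> pd.DataFrame:
    """Mean per-isotopologue fractions by arm x compartment x metabolite."""
    return (
        enriched.groupby(["arm", "compartment", "metabolite", "isotopologue_index"])
        .agg(fraction_mean=("fraction", "mean"), fraction_sem=("fraction", "sem"),
             sigma13C_mean=("sigma13C", "mean"))
        .reset_index()
    )
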