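"""Isotopologue peak-area extraction from centroided mzML runs.

This is the optional front end of the pipeline: given a derivatized species
and a retention-time window, it sums centroid intensities within a ppm
tolerance of each isotopologue m/z per scan and trapezoid-integrates over
retention time, producing the same :class:`IsotopologueVector` a vendor
peak table would supply. No smoothing, baseline subtraction or peak picking
is applied — areas are deterministic functions of the centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formulas import DerivatizedSpecies, isotopologue_mz
from .isotopes import IsotopologueVector
from .mzmlio import read_centroided_scans

__all__ = ["XicRequest", "extract_isotopologue_areas"]

DEFAULT_MZ_TOLERANCE_PPM = 5.0


@dataclass(frozen=True)
class XicRequest:
    """Extraction request: species, RT window (minutes), ppm tolerance."""

    species: DerivatizedSpecies
    rt_window: tuple[float, float]
    mz_tolerance_ppm: float = DEFAULT_MZ_TOLERANCE_PPM
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.mz_tolerance_ppm <= 0:
            raise ValueError("mz tolerance must be > 0")
        if not self.rt_window[0] < self.rt_window[1]:
            raise ValueError("rt window start must precede end")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def extract_isotopologue_areas(
    run: str | Path,
    req: XicRequest,
    sample_id: str = "",
    compartment: str = "cell",
    arm: str = "tracer_13C",
) -> IsotopologueVector:
    """XIC areas for every isotopologue of ``req.species`` in one mzML run.

    Areas are trapezoid integrals of summed in-tolerance centroid intensity
    over retention time (minutes). An empty RT window yields a zero vector
    with a warning; profile-mode spectra raise.
    """
    sp = req.species
    n = sp.labelable_carbons
    targets = np.array([isotopologue_mz(sp, i) for i in range(n + 1)])
    tol = targets * req.mz_tolerance_ppm * 1e-6

    rts: list[float] = []
    intensities: list[np.ndarray] = []
    for scan in read_centroided_scans(run):
        if scan.polarity != req.polarity:
            continue
        rt = scan.rt_minutes
        if not req.rt_window[0] <= rt <= req.rt_window[1]:
            continue
        mz, inten = scan.mz, scan.intensity
        row = np.array(
            [
                inten[np.abs(mz - t) <= d].sum() if mz.size else 0.0
                for t, d in zip(targets, tol)
            ]
        )
        rts.append(rt)
        intensities.append(row)

    if not rts:
        warnings.warn(
            f"no scans in RT window {req.rt_window} for {sp.metabolite_name}; "
            "returning zero areas",
            stacklevel=2,
        )
        areas = np.zeros(n + 1)
    else:
        order = np.argsort(rts)
        rt_arr = np.asarray(rts)[order]
        mat = np.vstack(intensities)[order]
        if rt_arr.size == 1:
            areas = np.zeros(n + 1)
        else:
            areas = np.trapezoid(mat, rt_arr, axis=0)
    return IsotopologueVector(
        species=sp, areas=areas, sample_id=sample_id,
        compartment=compartment, arm=arm,
    )
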