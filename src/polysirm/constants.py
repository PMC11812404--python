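"""Embedded isotope constants.

A single IUPAC-derived table is used everywhere (masses in Da, abundances as
mole fractions) so that masses, natural-abundance patterns and correction
matrices are bit-stable across platforms and never depend on an external
package's (possibly updated) constants.
"""

from __future__ import annotations

# element -> list of (isotope mass, natural abundance), lightest isotope first.
# Only elements occurring in the shipped metabolite registry are included.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.0033548, 0.0107)],
    "H": [(1.00782503, 0.999885), (2.01410178, 0.000115)],
    "N": [(14.00307401, 0.99636), (15.00010890, 0.00364)],
    "O": [(15.99491462, 0.99757), (16.99913176, 0.00038), (17.99915961, 0.00205)],
    "S": [
        (31.97207117, 0.9499),
        (32.97145891, 0.0075),
        (33.96786701, 0.0425),
        (35.96708071, 0.0001),
    ],
    "P": [(30.97376200, 1.0)],
}

#: monoisotopic (lightest-isotope) mass per element, Da
MONOISOTOPIC_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: 13C - 12C mass difference, Da — the isotopologue spacing for singly
#: charged ions
C13_C12_MASS_DIFF = 1.0033548

#: proton mass, Da — added per charge for [M+H]+ style adducts
PROTON_MASS = 1.0072765

#: net atoms added by one Fmoc (fluorenylmethoxycarbonyl) tag on an amine:
#: the amine loses one H, the carbamate C15H11O2 group is gained
FMOC_NET_ADDITION = {"C": 15, "H": 10, "O": 2}

#: instrument scan window (m/z) for the polyamine LC-HRMS method; every
#: registry species' [M+H]+ must land inside it
SCAN_WINDOW_MZ = (75.0, 1000.0)
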