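"""Extract isotopologue areas from a (synthetic) centroided mzML run.

Writes a small mzML file with Gaussian chromatographic peaks at the
putrescine and spermidine isotopologue m/z values, then recovers the
areas by ppm-tolerance XIC integration and compares them to the planted
ground truth.
"""

import tempfile
from pathlib import Path

import numpy as np

from polysirm import (
    XicRequest,
    default_registry,
    extract_isotopologue_areas,
    generate_scenario,
    simulate_mzml,
)

registry = default_registry()
sc = generate_scenario("human", seed=21)

with tempfile.TemporaryDirectory() as tmp:
    path, planted = simulate_mzml(
        sc, ["putrescine", "spermidine"], Path(tmp) / "run.mzML"
    )
    for met in ["putrescine", "spermidine"]:
        sp = registry[met]
        lo, hi = sp.rt_window
        vec = extract_isotopologue_areas(
            path, XicRequest(species=sp, rt_window=(lo - 0.5, hi + 0.5))
        )
        truth = (
            planted[planted["metabolite"] == met]
            .sort_values("isotopologue_index")["area"]
            .to_numpy()
        )
        print(f"\n{met}: monoisotopic [M+H]+ m/z {sp.mz_monoisotopic:.4f}")
        for i, (got, want) in enumerate(zip(vec.areas, truth)):
            if want > truth.max() * 1e-3:
                print(f"  M+{i}: extracted {got:12.0f}  planted {want:12.0f} "
                      f"({100 * got / want - 100:+.2f} %)")

print("\nAreas are trapezoid integrals of in-tolerance centroid intensity"
      "\nover retention time; sub-1% recovery validates the XIC front end.")
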