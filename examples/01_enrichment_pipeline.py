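"""Simulate a tracer-incubation study and compute fractional enrichments.

Generates the 'human' scenario (3 subjects per arm, cell + medium
compartments, 5% area CV), strips natural abundance from the peak table,
and prints the subject-mean per-isotopologue enrichments for spermidine
(SPD) and putrescine (PUT) in the cell fraction.
"""

import numpy as np

from polysirm import enrich_table, generate_scenario, simulate_peak_table

sc = generate_scenario("human", seed=1)
peaks, truth = simulate_peak_table(sc)
enriched = enrich_table(peaks)

cell = enriched[
    (enriched["arm"] == "tracer_13C") & (enriched["compartment"] == "cell")
]
for met in ["spermidine", "putrescine"]:
    sub = cell[cell["metabolite"] == met]
    means = sub.groupby("isotopologue_index")["fraction"].mean()
    sigma = sub.groupby("sample_id")["sigma13C"].first().mean()
    print(f"\n{met} (cell fraction, mean of n = 3 subjects)")
    for i, f in means.items():
        if f > 0.002:
            print(f"  13C{i}: {100 * f:5.1f} % of pool")
    print(f"  total 13C-labeled (sigma13C): {100 * sigma:.1f} %")

print(
    "\nThe dominant 13C2-SPD vs 13C4-PUT contrast is the signature of the"
    "\narginine-agmatine route contributing to spermidine biosynthesis."
)
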