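"""Estimate biosynthetic route contributions for spermidine.

Plants a known route mixture (80% arginine-agmatine route, 20% putrescine
aminopropylation) in a synthetic study, runs the pipeline, and deconvolves
the recovered spermidine isotopologue distribution back into route weights.
"""

from polysirm import (
    RouteSpec,
    deconvolve_routes,
    enrich_table,
    generate_scenario,
    simulate_peak_table,
    spd_route_model,
)

planted = {"put_aminopropylation": 0.2, "agmatine_route": 0.8}
sc = generate_scenario(
    "human", seed=11, route_spec=RouteSpec(weights=planted), noise_cv=0.02,
    compartments=("cell",),
)
peaks, _ = simulate_peak_table(sc)
enriched = enrich_table(peaks[peaks["metabolite"] == "spermidine"])

model = spd_route_model(
    put_dist=sc.truths["putrescine"]["cell"],
    agmatine_dist=sc.truths["agmatine"]["cell"],
)
spd = enriched[enriched["arm"] == "tracer_13C"]
f = spd.groupby("isotopologue_index")["fraction"].mean().sort_index().to_numpy()
mix = deconvolve_routes(f, model)

print("planted route weights :", planted)
print("recovered route weights:",
      {k: round(v, 3) for k, v in mix.weights.items()})
print(f"fit residual: {mix.fit_residual:.4f}   identifiable: {mix.identifiable}")
print(
    "\nWeights are molar shares of the spermidine pool attributable to each"
    "\nroute, assuming an unlabeled 3-carbon aminopropyl unit from SAM."
)
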