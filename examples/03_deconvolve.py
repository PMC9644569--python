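"""Hierarchically deconvolve bulk samples down to 17 cell classes.

Layer 1 is the tumor-purity density mode; layers 2-6 cascade the
constrained projections down the lineage tree, so children always sum
exactly to their parent's mass.
"""
from tmedecon import (
    SimulationConfig,
    build_bundle,
    deconvolve,
    simulate_mixtures,
    simulate_reference_panel,
    simulate_tumor_normal,
)

cfg = SimulationConfig(seed=17)
panel, _ = simulate_reference_panel(cfg)
tumor, normal, _ = simulate_tumor_normal(cfg)
bundle = build_bundle(tumor, normal, panel, tumor_type="SYN")
mixtures, truth = simulate_mixtures(cfg)

res = deconvolve(mixtures, bundle, h=6)

first = mixtures.sample_ids[0]
print("layer 1 (tumor vs rest):")
print(res.tables[1].loc[first].round(3).to_string())
print("\nlayer 6 (17 terminal classes), first sample vs truth:")
cmp = res.tables[6].loc[first].to_frame("predicted")
cmp["truth"] = truth.proportions.loc[first]
print(cmp.round(3).to_string())
print(f"\nlayer-6 row sum: {res.tables[6].loc[first].sum():.6f}")
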