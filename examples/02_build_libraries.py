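"""Build the 12-library deconvolution bundle for one tumor type.

Layer 1 selects the top-1000 informative differentially methylated CpGs
(iDMCs) between tumor and normal training samples; layers 2-6 carry
100 cell-type-specific hyper/hypo markers per class, fitted with the
empirical-Bayes moderated model. The bundle is serialized to a
diff-able directory of CSV tables.
"""
from pathlib import Path

from tmedecon import (
    SimulationConfig,
    build_bundle,
    save_library_bundle,
    simulate_reference_panel,
    simulate_tumor_normal,
)

cfg = SimulationConfig(seed=17)
panel, _ = simulate_reference_panel(cfg)
tumor, normal, _ = simulate_tumor_normal(cfg)

bundle = build_bundle(tumor, normal, panel, tumor_type="SYN")

print(f"bundle for tumor type {bundle.tumor_type!r}: {bundle.n_libraries} libraries")
print(f"L1 iDMC library: {len(bundle.l1)} CpGs "
      f"({(bundle.l1.entries['direction'] == 'hyper').sum()} hyper, "
      f"{(bundle.l1.entries['direction'] == 'hypo').sum()} hypo)")
for tag, lib in bundle.layers.items():
    print(f"  {tag}: classes {', '.join(lib.classes)} | {len(lib.probes)} probes")

out = Path("scratch_bundle")
save_library_bundle(bundle, out)
print(f"\nserialized to {out}/ ({len(list(out.iterdir()))} files)")
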