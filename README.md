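# tmedecon

Hierarchical reference-based deconvolution of the tumor microenvironment
(TME) from DNA methylation beta values.

Bulk tumor methylation profiles mix signal from tumor cells, angiogenic /
non-immune cells (epithelial, endothelial, stromal) and a deep hierarchy
of immune cells. `tmedecon` resolves that mixture layer by layer:

1. **Tumor purity** from informative differentially methylated CpGs
   (iDMCs): the top 1000 tumor-vs-normal CpGs (rank-sum ranked, tumor
   beta variance > 0.005), hypomethylated ones flipped to 1−β, and the
   purity taken as the mode of a Gaussian-kernel density of the
   transformed values.
2. **Constrained projection** for every deeper split: per library, the
   bulk profile y is projected onto class-mean reference profiles X by
   solving min‖y − Xw‖² subject to w ≥ 0, Σw = 1 (solved exactly by
   support-set enumeration).
3. **A hierarchical cascade** over 12 libraries in 6 layers: each node's
   focal weights are renormalized and multiplied by the parent's absolute
   mass, resolving up to 17 cell classes with exact parent/child mass
   conservation.

Reference libraries are built from labelled purified-cell panels with
empirical-Bayes moderated t-statistics (limma-style variance shrinkage,
implemented here), keeping the top 50 hyper- + 50 hypomethylated CpGs per
class. A seeded synthetic-data module generates reference panels,
tumor/normal training sets and mixture cohorts with known ground truth,
so the entire pipeline is testable without downloading array data.

Audience: methylation/epigenomics researchers who have preprocessed
Infinium beta matrices (450K/EPIC-style, probes × samples) and want
absolute TME cell proportions per sample.

## Worked example

```python
from tmedecon import (SimulationConfig, simulate_reference_panel,
                      simulate_tumor_normal, simulate_mixtures,
                      build_bundle, deconvolve)

cfg = SimulationConfig(seed=17)
panel, _ = simulate_reference_panel(cfg)          # 16 purified cell classes
tumor, normal, _ = simulate_tumor_normal(cfg)     # L1 training data
bundle = build_bundle(tumor, normal, panel, tumor_type="SYN")
mixtures, truth = simulate_mixtures(cfg)          # 24 bulk samples, known truth
res = deconvolve(mixtures, bundle, h=6)
print(res.tables[1].iloc[0].round(3))             # layer 1
print(res.tables[6].iloc[0].round(3).head())      # layer 6 (17 classes)
```

prints (seed 17, first sample):

```
Tumor       0.505
Nontumor    0.495

Tumor          0.505
Epithelial     0.008
Endothelial    0.247
Stromal        0.198
Neutrophil     0.001
```

i.e. the sample is estimated as 50.5% tumor (true value 50.3%), with the
non-tumor mass split across the angiogenic and immune classes
(endothelial 24.7% vs 24.8% true, stromal 19.8% vs 19.6% true); every
layer's row sums to 1 and children always sum exactly to their parent.
On 50 synthetic mixtures at measurement noise sd 0.03 the pipeline
recovers composition with ~0.6 percentage points pooled mean absolute
error (per-class RMSE < 1.5 points); `examples/04_evaluate_recovery.py`
prints the full per-class table.

The `examples/` directory holds one short script per capability
(simulation, library construction, deconvolution, evaluation); each
prints what it computes and what the numbers mean. A thin CLI mirrors the
API:

```bash
tmedecon simulate --out-dir fixtures/
tmedecon build-library bundle --tumor fixtures/tumor.csv --normal fixtures/normal.csv \
    --panel fixtures/panel.csv --labels fixtures/labels.csv --tumor-type SYN --out bundle/
tmedecon deconvolve --betas fixtures/mixtures.csv --bundle bundle/ --layer 6 --out props.csv
tmedecon evaluate --pred props.csv --truth fixtures/truth.csv --out report.csv
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.

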