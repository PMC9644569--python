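# Methods

## Model

`tmedecon` estimates the cell composition of bulk tumor methylation
profiles by hierarchical reference-based deconvolution. The quantity
measured per CpG is the beta value β ∈ [0, 1] (methylated fraction of an
Infinium array probe). A bulk profile is modelled as a convex combination
of cell-class reference profiles, and the composition is resolved along a
six-layer lineage tree with 17 terminal classes (tumor; epithelial,
endothelial, stromal; neutrophil, basophil, eosinophil, monocyte,
dendritic; NK; naïve/memory B; naïve/memory CD4 T, Treg; naïve/memory
CD8 T). Macrophages are deliberately outside the model.

### Layer 1 — tumor purity

The tumor fraction is not obtained by projection but from the density of
informative differentially methylated CpGs (iDMCs):

* candidate CpGs must have unbiased tumor-sample beta variance > 0.005;
* candidates are ranked by two-sided rank-sum (Mann–Whitney) p-value of
  tumor vs normal training samples and the top 1000 kept;
* each iDMC is hyper (mean tumor β > mean normal β) or hypo;
* for a bulk sample, hyper iDMC betas are kept and hypo betas flipped to
  1−β, so every transformed value rises with tumor content;
* a Gaussian KDE is fitted to the transformed values and evaluated on the
  closed grid [0, 1] with step 0.001; purity = the grid mode.

Rank-sum p-values use exact enumeration when the smaller group has ≤ 10
samples and a probe has no cross-group ties, otherwise the normal
approximation with continuity and tie corrections. Ranking ties are broken
by larger |mean tumor − mean normal|, then probe ID, so library
construction is fully deterministic. The KDE bandwidth is Silverman's rule
(the upstream convention is unspecified; this is a documented choice, not
an asserted equivalence). Mode ties resolve to the lowest grid value, and
a multimodality flag is set when a secondary local maximum reaches 95% of
the global one (bimodal purity densities occur in histologically mixed
tumor series). Degenerate inputs (all transformed values identical) snap
the common value to the grid instead of fitting a KDE. Transformed values
are clipped to [0, 1] before density estimation.

### Layers 2–6 — marker libraries and constrained projection

Each of the 11 deeper libraries (L2, L3A/B, L4A/B, L5A–D, L6A/B) refines
one tree node. Its classes are the node's focal children plus collapsed
classes absorbing the same-branch siblings (e.g. L3A separates
epithelial/endothelial/stromal with all immune cells collapsed; L5C
separates naïve/memory B with NK+T collapsed). Collapsed classes receive
ranked markers exactly like focal classes so that off-branch signal has
somewhere to go. Every library additionally carries the tumor reference
profile as a non-focal class: bulk profiles always contain tumor signal,
and without a tumor column the sum-to-one constraint would force that
mass onto cell classes — measured on the synthetic study this costs
~2.5 percentage points of bias at the upper layers even without noise.
The tumor weight is discarded at every layer; tumor mass comes only from
layer 1.

Markers are selected one-vs-rest with an empirical-Bayes moderated t:
per CpG an OLS fit of β on an intercept, the class indicator and optional
covariates; residual variances are shrunk toward a scaled-F prior whose
hyperparameters (d0, s0²) come from the method-of-moments equations on log
variances (digamma/trigamma inversion, Newton iteration, tolerance 1e-8).
One deviation from the common implementation: when the excess spread of
log variances is non-positive (no evidence of variance mixing), the prior
variance is the geometric mean of the observed variances with no
finite-df bias correction, which makes exactly-equal variances a fixed
point — moderated t then equals ordinary t. Residual variances below
1e-25 are treated as true zeros (exact fits leave O(ε²) residue); a zero
posterior variance with a nonzero coefficient yields t = ±∞, p = 0, and
an all-zero-variance fit is flagged.

Per class the top 50 hypermethylated plus top 50 hypomethylated CpGs are
kept (p ascending; ties by |coefficient| then probe ID; a short side is
back-filled from the other with a warning). "100 markers per class" is
read as 50 + 50; the count is configurable. The library stores per-class
mean betas over the deduplicated marker union.

Projection solves the constrained least-squares problem
min‖y − Xw‖² s.t. w ≥ 0, Σw = 1 on the probes shared by sample and
library. For ≤ 10 classes (every shipped library has ≤ 4) the solver
enumerates support sets and solves each equality-constrained KKT system —
exact and deterministic; above 10 classes SLSQP is used. A brute-force
simplex grid search (step 0.01) is retained as an independent oracle and
alternative solver. Collinear library columns (Gram condition > 1e10)
emit a warning and fall back to least-norm KKT solves. Tiny negative
round-off weights are clipped at 0 and the vector renormalized.

### The cascade

Layer 1 fixes tumor mass m_T; non-tumor mass is 1 − m_T. Layer 2 projects
onto {Tumor, Angiogenic, Immune} but discards the Tumor weight — tumor
mass comes exclusively from layer 1 — and renormalizes the focal weights
over the non-tumor mass. Every deeper node renormalizes its focal
children's projection weights and multiplies by the parent's absolute
mass, so children sum to their parent exactly (float rounding only, ≤ 1
ulp) and roll-up consistency across layers holds by construction. Each
layer is weighted by its immediate parent's output, not directly by the
layer-1 masses. Classes with no sub-library (NK below layer 4; leaves
generally) are carried forward unchanged. If a projection assigns zero
weight to every focal child, the parent mass is split equally with a
warning — conservation is preserved without inventing signal. A sample
must cover at least max(10, #classes + 5) library probes; coverage below
50% of a library warns.

The tumor reference class is built from the tumor training samples whose
layer-1 purity lies in the top tertile (at least two samples), each
purity-adjusted before use: x ↦ clip((x − (1−p)·mean normal)/p, 0, 1)
with p the sample's purity estimate floored at 0.25. Raw training tumors
average well below purity 1, so an unadjusted tumor mean is deflated at
iDMC probes and biases the L2 split (~2.5 points on the immune/angiogenic
masses in the noise-free study); the adjustment removes the estimated
normal-tissue fraction, which is the standard reference-cleaning step for
contaminated references.

## Synthetic data

The generator emulates the structure the model assumes, with one latent
archetype set shared by the reference panel, the tumor/normal training
matrices and the mixture cohorts (distinct child seed streams of one
seed, so the three generators are individually deterministic and mutually
consistent):

* baseline betas uniform in [0.1, 0.9];
* a private marker block per terminal class *and per internal lineage
  node* (the lineage blocks are displaced in every leaf beneath the node)
  — real methylomes carry lineage-shared signatures, and without them
  collapsed library classes would be incoherent mixtures; block baselines
  are stratified so each block yields equal hyper and hypo halves;
* displacement is ±delta (default 0.5) toward the far side of [0, 1];
* tumor-vs-normal differential CpGs with near-saturated contrast (normal
  side ~U(0.002, 0.01) or mirrored near 1, tumor side flipped). In the
  noise-free limit the purity mode equals the iDMC contrast level, so
  this choice is what makes pure-profile recovery meaningful; the beta
  compression of real arrays is represented by the noise term instead;
* tumor training samples are purity-mixtures of the tumor archetype and
  the normal background (purity ~ U(0.5, 0.95)), which gives differential
  probes large between-tumor variance (the 0.005 filter passes them)
  while background probes carry only measurement noise (it rejects them);
* mixture proportions are drawn hierarchically — a symmetric Dirichlet
  (concentration 2.0) split at every tree node — so the parent/child mass
  structure the cascade assumes is real in the data; rows are nudged to
  sum to exactly 1.0 in floating point;
* noise is additive Gaussian truncated (clipped) to [0, 1], default sd
  0.05 (typical purified-array replicate noise); a Beta-noise option
  exists for realism studies. Noise draws are paired across noise levels
  under a fixed seed, so noise sweeps are paired comparisons.

Default sizes (6000 CpGs, 6 replicates per class, 12 tumor + 12 normal,
24 mixtures; recovery studies use 50 mixtures at noise sd 0.03) keep a
full build-deconvolve-score cycle in seconds while leaving every filter
and ranking step discriminating.

What the generator does **not** emulate: Type I/II probe chemistry, batch
effects, copy-number-driven beta shifts, cross-reactive probes, or
tumor-reprogrammed immune phenotypes. Passing recovery tests therefore
demonstrates correctness of the algorithmic pipeline under its own model
assumptions, not field performance on arrays.

## Evaluation

Errors are reported on the percent scale: error = predicted% − true%,
absolute error its magnitude, per-class RMSE and Pearson R across
samples (R flagged undefined, not zeroed, for constant vectors; p-values
are descriptive only), plus the pooled mean absolute error. A
leaf-level truth table is rolled up the tree to score any layer.

One property worth noting: with strong subtype markers the deep splits
are accurate and errors concentrate in the upper-layer mass estimates, so
aggregating subtypes (e.g. T subsets to total T) does *not* necessarily
reduce RMSE below the worst subset — the signed subset errors share the
parent's error rather than cancelling. The guaranteed bound is the
triangle inequality: parent RMSE ≤ sum of subset RMSEs.

## Known limitations

* The L2 collapsed-class means average the panel's class composition;
  mixtures whose immune/angiogenic composition differs from the panel mix
  incur a small bias at the upper layers (visible as the nonzero RMSE
  floor in the noise → 0 sweep).
* Purity carries a small bias equal to the iDMC contrast offset
  (≲ 0.01 under defaults; real iDMC pools are less saturated and the bias
  correspondingly larger).
* Probe sets are taken as given: no manifest handling, normalization or
  detection-p filtering — upstream pipelines own those steps, and
  user-supplied probe masks stand in for curated cross-reactive/SNP/sex
  lists.
* No confidence intervals on proportions.
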