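"""Seeded synthetic methylation cohorts with known ground truth.

The generator emulates the statistical structure the deconvolution model
assumes, so every stage of the pipeline is testable without external
array downloads:

* a shared per-probe baseline beta drawn uniformly in [0.1, 0.9];
* per cell class, a private block of discriminative CpGs displaced from
  the baseline by ``delta`` toward the far side of [0, 1] (hyper or hypo
  depending on where the baseline sits) — the analogue of cell-type
  marker CpGs. Internal lineage nodes (Lymphoid, Myeloid, Bcell, ...)
  get blocks of their own, displaced in *every* leaf beneath them, the
  way real methylomes carry lineage-shared signatures; this is what
  makes collapsed library classes coherent;
* a block of tumor-vs-normal differential CpGs with near-saturated
  contrast (normal side drawn close to 0 or 1, tumor side mirrored) —
  the analogue of the iDMC pool used for purity;
* tumor training samples simulated as purity-mixtures of the tumor
  archetype and the normal background (purity uniform in a configurable
  range), which is what gives differential probes the large
  between-tumor variance the 0.005 filter keys on;
* mixture cohorts with hierarchical Dirichlet proportions: mass is split
  top-down at every node of the lineage tree, so the parent/child
  structure the cascade assumes is real in the data;
* additive Gaussian measurement noise truncated (clipped) to [0, 1],
  with a Beta-noise option for realism studies.

Everything is deterministic per seed; the three public generators draw
their noise from distinct child streams of the same seed, so panels,
tumor/normal sets and mixtures generated from one config are mutually
consistent (same probes, same archetypes).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hierarchy import HierarchyTree, default_tree
from .matrix import BetaMatrix, ReferencePanel, ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_reference_panel",
    "simulate_tumor_normal",
    "simulate_mixtures",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the stock study
    conditions used throughout the test-suite and recovery reports."""

    n_probes: int = 6000
    markers_per_class: int = 100   # private discriminative CpGs per class
    delta: float = 0.5             # beta-scale marker separation
    idmc_margin: tuple[float, float] = (0.002, 0.01)  # normal-side iDMC betas
    n_differential: int = 1500     # tumor-vs-normal differential CpGs
    noise_sd: float = 0.05         # beta-scale measurement noise
    noise_model: str = "gaussian"  # "gaussian" (truncated) or "beta"
    n_per_class: int = 6           # reference replicates per cell class
    n_tumor: int = 12
    n_normal: int = 12
    n_mixtures: int = 24
    concentration: float = 2.0     # symmetric per-node Dirichlet parameter
    tumor_purity_range: tuple[float, float] = (0.5, 0.95)
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValidationError("delta must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for name in ("n_probes", "markers_per_class", "n_differential",
                     "n_per_class", "n_tumor", "n_normal", "n_mixtures"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    def tree(self) -> HierarchyTree:
        return default_tree()


@dataclass
class SyntheticTruth:
    """Ground-truth leaf proportions per mixture sample."""

    proportions: pd.DataFrame  # samples x terminal classes, rows sum to 1
    config: dict = field(default_factory=dict)


# --------------------------------------------------------------- archetypes
def _child_rng(cfg: SimulationConfig, role: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), role]))


def _study_archetypes(cfg: SimulationConfig):
    """Deterministic latent structure shared by all three generators.

    Returns (probe_ids, archetypes DataFrame probes x [cell classes +
    Tumor + Normal background], differential probe list, marker blocks).
    """
    tree = cfg.tree()
    cell_classes = [c for c in tree.leaves() if c != "Tumor"]
    # marker blocks: one per terminal class plus one per internal lineage
    # node below Nontumor (lineage-shared signatures)
    lineage_nodes = [
        n
        for n in tree.node_order()
        if n not in (tree.root, "Tumor", "Nontumor") and not tree.is_leaf(n)
    ]
    block_owners = cell_classes + lineage_nodes
    need = len(block_owners) * cfg.markers_per_class + cfg.n_differential
    if cfg.n_probes < need:
        raise ValidationError(
            f"n_probes={cfg.n_probes} < markers + differential blocks ({need})"
        )

    rng = _child_rng(cfg, 0)
    probes = [f"cg{i:07d}" for i in range(cfg.n_probes)]
    baseline = rng.uniform(0.1, 0.9, cfg.n_probes)

    # differential (iDMC-like) block: near-saturated tumor/normal contrast
    lo, hi = cfg.idmc_margin
    diff_idx = np.arange(cfg.n_differential)
    half = cfg.n_differential // 2
    normal_side = np.empty(cfg.n_differential)
    tumor_side = np.empty(cfg.n_differential)
    normal_side[:half] = rng.uniform(lo, hi, half)              # hyper in tumor
    tumor_side[:half] = 1.0 - rng.uniform(lo, hi, half)
    normal_side[half:] = 1.0 - rng.uniform(lo, hi, cfg.n_differential - half)
    tumor_side[half:] = rng.uniform(lo, hi, cfg.n_differential - half)  # hypo
    baseline[diff_idx] = normal_side

    # marker blocks, after the differential block; the block baseline is
    # stratified so half of each block is displaced upward (hyper in the
    # owner) and half downward — real cell-type signatures carry both
    # directions and the selection step takes equal halves
    marker_blocks: dict[str, np.ndarray] = {}
    start = cfg.n_differential
    for c in block_owners:
        blk = np.arange(start, start + cfg.markers_per_class)
        half = cfg.markers_per_class // 2
        baseline[blk[:half]] = rng.uniform(0.1, 0.45, half)
        baseline[blk[half:]] = rng.uniform(0.55, 0.9, cfg.markers_per_class - half)
        marker_blocks[c] = blk
        start += cfg.markers_per_class

    # a leaf is displaced at its own block and at every ancestor's block
    arch = {}
    for c in cell_classes:
        prof = baseline.copy()
        blocks = [c] + [n for n in lineage_nodes if c in tree.leaves_under(n)]
        for owner in blocks:
            blk = marker_blocks[owner]
            toward = np.where(baseline[blk] < 0.5, 1.0, -1.0)
            prof[blk] = np.clip(baseline[blk] + toward * cfg.delta, 0.0, 1.0)
        arch[c] = prof
    tumor_prof = baseline.copy()
    tumor_prof[diff_idx] = tumor_side
    arch["Tumor"] = tumor_prof
    arch["__normal__"] = baseline

    archetypes = pd.DataFrame(arch, index=pd.Index(probes, name="probe_id"))
    differential = [probes[i] for i in diff_idx]
    return probes, archetypes, differential, marker_blocks


def _add_noise(
    profiles: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.noise_sd == 0:
        return profiles.copy()
    if cfg.noise_model == "gaussian":
        noisy = profiles + rng.standard_normal(profiles.shape) * cfg.noise_sd
        return np.clip(noisy, 0.0, 1.0)
    if cfg.noise_model == "beta":
        # Beta draws with mean = archetype and sd ~ noise_sd (precision from
        # the beta-variance identity), clipped away from degenerate 0/1 means
        mu = np.clip(profiles, 1e-3, 1.0 - 1e-3)
        nu = np.maximum(mu * (1.0 - mu) / cfg.noise_sd**2 - 1.0, 1.0)
        return rng.beta(mu * nu, (1.0 - mu) * nu)
    raise ValidationError(f"unknown noise model {cfg.noise_model!r}")


# ------------------------------------------------------------------ panels
def simulate_reference_panel(
    cfg: SimulationConfig,
) -> tuple[ReferencePanel, pd.DataFrame]:
    """Purified-cell reference panel plus the latent class archetypes.

    Each of the 16 non-tumor terminal classes contributes
    ``cfg.n_per_class`` replicate samples = archetype + truncated noise.
    """
    probes, archetypes, _, _ = _study_archetypes(cfg)
    rng = _child_rng(cfg, 1)
    cell_classes = [c for c in archetypes.columns if c not in ("Tumor", "__normal__")]

    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for c in cell_classes:
        prof = archetypes[c].to_numpy()
        reps = _add_noise(np.tile(prof[:, None], (1, cfg.n_per_class)), cfg, rng)
        for j in range(cfg.n_per_class):
            sid = f"{c}_{j + 1:02d}"
            cols[sid] = reps[:, j]
            labels[sid] = c
    betas = BetaMatrix(pd.DataFrame(cols, index=probes), validate=False)
    panel = ReferencePanel(betas, pd.Series(labels))
    return panel, archetypes[cell_classes]


def simulate_tumor_normal(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, BetaMatrix, list[str]]:
    """Tumor and matched-normal training matrices plus the list of truly
    differential probes.

    Normal samples are background + noise. Each tumor sample is a
    purity-mixture of the tumor archetype and the background, purity
    uniform in ``cfg.tumor_purity_range`` — differential probes therefore
    carry purity-driven between-sample variance (passing the 0.005
    filter) while background probes carry only measurement noise.
    """
    probes, archetypes, differential, _ = _study_archetypes(cfg)
    rng = _child_rng(cfg, 2)
    baseline = archetypes["__normal__"].to_numpy()
    tumor_arch = archetypes["Tumor"].to_numpy()

    if cfg.delta == 0 or cfg.n_differential == 0:
        differential = []

    purities = rng.uniform(*cfg.tumor_purity_range, cfg.n_tumor)
    tumor_profiles = (
        purities[None, :] * tumor_arch[:, None]
        + (1.0 - purities)[None, :] * baseline[:, None]
    )
    tumor_vals = _add_noise(tumor_profiles, cfg, rng)
    normal_vals = _add_noise(np.tile(baseline[:, None], (1, cfg.n_normal)), cfg, rng)

    tumor = BetaMatrix(
        pd.DataFrame(
            tumor_vals, index=probes,
            columns=[f"tumor_{i + 1:02d}" for i in range(cfg.n_tumor)],
        ),
        validate=False,
    )
    normal = BetaMatrix(
        pd.DataFrame(
            normal_vals, index=probes,
            columns=[f"normal_{i + 1:02d}" for i in range(cfg.n_normal)],
        ),
        validate=False,
    )
    return tumor, normal, differential


# ---------------------------------------------------------------- mixtures
def _hierarchical_proportions(
    tree: HierarchyTree, cfg: SimulationConfig, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    """Top-down Dirichlet split of unit mass at every tree node."""
    leaves = tree.leaves()
    out = np.zeros((n, len(leaves)))
    leaf_pos = {c: i for i, c in enumerate(leaves)}
    for i in range(n):
        mass = {tree.root: 1.0}
        for node in tree.node_order():
            kids = tree.children.get(node, ())
            if not kids:
                continue
            split = rng.dirichlet([cfg.concentration] * len(kids))
            for c, frac in zip(kids, split):
                mass[c] = mass[node] * float(frac)
        for c in leaves:
            out[i, leaf_pos[c]] = mass[c]
    out = out / out.sum(axis=1, keepdims=True)
    for i in range(n):
        _force_unit_sum(out[i])
    return pd.DataFrame(
        out, index=[f"mix_{i + 1:03d}" for i in range(n)], columns=list(leaves)
    )


def _force_unit_sum(row: np.ndarray) -> None:
    """Nudge one entry so the row sums to exactly 1.0 in floating point.

    Rounding can leave the normalized row 1 ulp off; compensating a single
    entry does not always land exactly, so try each entry (largest first)
    and keep the first adjustment whose resulting sum is exactly 1."""
    order = np.argsort(row)[::-1]
    for _ in range(4):
        r = 1.0 - row.sum()
        if r == 0.0:
            return
        for j in order:
            trial = row[j] + r
            if trial < 0:
                continue
            old = row[j]
            row[j] = trial
            if 1.0 - row.sum() == 0.0:
                return
            row[j] = old
        row[order[0]] += r  # shrink the residual and retry
    return


def simulate_mixtures(
    cfg: SimulationConfig,
    fixed_proportions: pd.DataFrame | None = None,
    archetypes: pd.DataFrame | None = None,
) -> tuple[BetaMatrix, SyntheticTruth]:
    """Bulk mixture cohort with exact ground truth.

    Leaf proportions are drawn hierarchically (Dirichlet at every tree
    node) unless ``fixed_proportions`` (samples x terminal classes) is
    given; each mixture beta is the proportion-weighted combination of
    the leaf archetypes plus truncated noise.
    """
    probes, arch_all, _, _ = _study_archetypes(cfg)
    tree = cfg.tree()
    leaves = list(tree.leaves())
    arch = arch_all[leaves]  # includes Tumor
    rng = _child_rng(cfg, 3)

    if fixed_proportions is not None:
        props = fixed_proportions.astype(float)
        missing = [c for c in leaves if c not in props.columns]
        if missing:
            raise ValidationError(f"fixed proportions missing classes: {missing}")
        props = props[leaves]
        sums = props.to_numpy().sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValidationError("fixed proportion rows must sum to 1")
        # keep the rng stream aligned with the default path
        _ = _hierarchical_proportions(tree, cfg, rng, len(props))
    else:
        props = _hierarchical_proportions(tree, cfg, rng, cfg.n_mixtures)

    clean = arch.to_numpy() @ props.to_numpy().T  # probes x samples
    vals = _add_noise(clean, cfg, rng)
    mix = BetaMatrix(
        pd.DataFrame(vals, index=probes, columns=list(props.index)), validate=False
    )
    truth = SyntheticTruth(proportions=props, config=asdict(cfg))
    return mix, truth
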