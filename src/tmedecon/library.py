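"""Build the 12-library bundle: L1 iDMCs plus the 11 layer libraries.

Each layer library carries, per class, the top cell-type-specific markers:
a one-vs-rest moderated model ranks CpGs and the best hyper- and
hypomethylated halves are kept (default 50 + 50 = 100 per class). The
library stores per-class mean beta profiles over the union of selected
markers; those means are the reference matrix X of the constrained
projection at deconvolution time.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import HierarchyTree, LibrarySpec, default_tree, LAYER_TAGS
from .matrix import BetaMatrix, ReferencePanel, ValidationError
from .moderated import fit_moderated_model
from .purity import IDMCLibrary, select_idmc, estimate_purity_matrix

__all__ = [
    "LayerLibrary",
    "LibraryBundle",
    "rank_class_markers",
    "build_layer_library",
    "build_bundle",
]


@dataclass
class LayerLibrary:
    """One layer's reference: selected probes and per-class mean betas."""

    tag: str
    classes: tuple[str, ...]
    means: pd.DataFrame          # probes (union, deduplicated) x classes
    markers: pd.DataFrame        # columns: class, rank, probe_id, direction
    focal_children: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.means.index.has_duplicates:
            raise ValidationError(f"{self.tag}: duplicate probes in library")
        vals = self.means.to_numpy(dtype=float)
        if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
            raise ValidationError(f"{self.tag}: mean betas outside [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.means.index

    def attributed(self, class_name: str) -> pd.DataFrame:
        return self.markers[self.markers["class"] == class_name]


@dataclass
class LibraryBundle:
    """Everything needed to deconvolve one tumor type: the L1 iDMC library,
    the 11 layer libraries, the lineage tree and construction parameters."""

    tumor_type: str
    l1: IDMCLibrary
    layers: dict[str, LayerLibrary]
    tree: HierarchyTree
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [t for t in LAYER_TAGS if t not in self.layers]
        if missing:
            raise ValidationError(f"bundle missing layer libraries: {missing}")
        extra = [t for t in self.layers if t not in LAYER_TAGS]
        if extra:
            raise ValidationError(f"unknown layer library tags: {extra}")

    @property
    def n_libraries(self) -> int:
        return 1 + len(self.layers)


def _rank_markers_from_fit(fit_table: pd.DataFrame, n_markers: int) -> pd.DataFrame:
    """Split a moderated fit into hyper (coef > 0) / hypo (coef < 0) sides,
    rank each by p ascending (ties: |coef| desc, then probe ID) and take
    n_markers//2 from each side, back-filling a short side from the other."""
    tbl = fit_table.copy()
    tbl["abs_coef"] = tbl["coef"].abs()
    tbl = tbl.sort_values(
        ["p", "abs_coef", "probe"], ascending=[True, False, True], kind="mergesort"
    )
    hyper = tbl[tbl["coef"] > 0]
    hypo = tbl[tbl["coef"] < 0]
    n_hyper = n_markers - n_markers // 2
    n_hypo = n_markers // 2
    take_hyper = hyper.head(n_hyper)
    take_hypo = hypo.head(n_hypo)
    short_hyper = n_hyper - len(take_hyper)
    short_hypo = n_hypo - len(take_hypo)
    if short_hyper > 0:
        take_hypo = hypo.head(n_hypo + short_hyper)
        warnings.warn(
            f"hyper-marker shortage; back-filled {short_hyper} from the hypo side",
            stacklevel=3,
        )
    elif short_hypo > 0:
        take_hyper = hyper.head(n_hyper + short_hypo)
        warnings.warn(
            f"hypo-marker shortage; back-filled {short_hypo} from the hyper side",
            stacklevel=3,
        )
    out = pd.concat([take_hyper.assign(direction="hyper"), take_hypo.assign(direction="hypo")])
    if len(out) < n_markers:
        raise ValidationError(
            f"cannot assemble {n_markers} markers (only {len(out)} discriminative probes)"
        )
    return out[["probe", "direction", "p", "coef"]].reset_index(drop=True)


def rank_class_markers(
    panel: ReferencePanel, class_name: str, n_markers: int = 100
) -> pd.DataFrame:
    """Top cell-type-specific markers for one class (one-vs-rest).

    Returns an ordered DataFrame with columns probe, direction (hyper =
    more methylated in the class), p, coef; hyper markers first.
    """
    if class_name not in set(panel.labels):
        raise ValidationError(f"class {class_name!r} absent from panel")
    if len(panel.classes) < 2:
        raise ValidationError("panel needs >= 2 classes")
    n_in = int((panel.labels == class_name).sum())
    if n_in < 2 or len(panel.labels) - n_in < 2:
        raise ValidationError(f"class {class_name!r} needs >= 2 samples on each side")
    if n_markers > panel.betas.shape[0]:
        raise ValidationError("n_markers exceeds available probes")

    # categorical (rest, focal) fixes the contrast sign: coef = focal - rest
    group = pd.Series(
        pd.Categorical(
            np.where(panel.labels == class_name, "focal", "rest"),
            categories=["rest", "focal"],
        ),
        index=panel.labels.index,
    )
    fit = fit_moderated_model(panel.betas, group)
    tbl = fit.table.reset_index(names="probe")
    return _rank_markers_from_fit(tbl, n_markers)


def build_layer_library(
    panel: ReferencePanel,
    tag: str,
    focal_children: Sequence[str],
    collapse_map: Mapping[str, str],
    n_markers: int = 100,
) -> LayerLibrary:
    """Assemble one layer library.

    ``collapse_map`` sends each original panel class to its library class
    (focal child or collapsed group name); panel classes absent from the
    map are dropped. Every library class — collapsed groups included —
    receives its own ranked marker set, so the projection can attribute
    off-branch signal. Means are per-class averages over the deduplicated
    probe union.
    """
    relabeled = panel.relabel(collapse_map)
    lib_classes = list(dict.fromkeys(collapse_map.values()))
    if len(lib_classes) != len(set(lib_classes)):
        raise ValidationError("duplicate class names after collapse")
    present = set(relabeled.labels)
    missing = [c for c in lib_classes if c not in present]
    if missing:
        raise ValidationError(f"{tag}: no samples for classes {missing}")
    for c in lib_classes:
        if (relabeled.labels == c).sum() < 2:
            raise ValidationError(f"{tag}: class {c!r} has < 2 samples after collapse")

    marker_rows = []
    for c in lib_classes:
        ranked = rank_class_markers(relabeled, c, n_markers=n_markers)
        ranked.insert(0, "class", c)
        ranked.insert(1, "rank", np.arange(1, len(ranked) + 1))
        marker_rows.append(ranked)
    markers = pd.concat(marker_rows, ignore_index=True)

    probe_union = list(dict.fromkeys(markers["probe"]))
    sub = relabeled.betas.data.loc[probe_union]
    means = sub.T.groupby(relabeled.labels).mean().T[lib_classes]
    means.index.name = "probe_id"

    return LayerLibrary(
        tag=tag,
        classes=tuple(lib_classes),
        means=means,
        markers=markers[["class", "rank", "probe", "direction", "p", "coef"]].rename(
            columns={"probe": "probe_id"}
        ),
        focal_children=tuple(focal_children),
    )


def _collapse_map_for(spec: LibrarySpec) -> dict[str, str]:
    cmap: dict[str, str] = {}
    for lib_class, members in spec.roster.items():
        for m in members:
            cmap[m] = lib_class
    return cmap


def build_bundle(
    tumor: BetaMatrix,
    normal: BetaMatrix,
    cell_panel: ReferencePanel,
    tumor_type: str,
    n_top: int = 1000,
    var_threshold: float = 0.005,
    n_markers: int = 100,
    tree: HierarchyTree | None = None,
) -> LibraryBundle:
    """Construct the full 12-library bundle for one tumor type.

    The tumor reference class is formed from the tumor training samples
    whose layer-1 purity lies in the top tertile (least contaminated by
    non-tumor cells); those samples are injected into the panel as class
    "Tumor" before the layer libraries are built. All operations are
    deterministic, so two runs on the same inputs are bit-identical.
    """
    tree = tree or default_tree()
    terminal_needed = [c for c in tree.leaves() if c != "Tumor"]
    have = set(cell_panel.labels)
    missing = [c for c in terminal_needed if c not in have]
    if missing:
        raise ValidationError(f"reference panel missing terminal classes: {missing}")

    # restrict everything to the probes shared by all inputs
    tumor_probes, normal_probes = set(tumor.probe_ids), set(normal.probe_ids)
    shared = [
        p
        for p in cell_panel.betas.probe_ids
        if p in tumor_probes and p in normal_probes
    ]
    if not shared:
        raise ValidationError("no probes shared by tumor, normal and panel matrices")
    tumor = tumor.select_probes(shared)
    normal = normal.select_probes(shared)
    panel = ReferencePanel(cell_panel.betas.select_probes(shared), cell_panel.labels)

    l1 = select_idmc(tumor, normal, n_top=n_top, var_threshold=var_threshold)

    purities = estimate_purity_matrix(tumor, l1)
    cut = purities["purity"].quantile(2.0 / 3.0)
    top_ids = list(purities.index[purities["purity"] >= cut])
    if len(top_ids) < 2:  # always keep at least two samples for variance
        top_ids = list(purities["purity"].sort_values(ascending=False).index[:2])

    # purity-adjust the tumor reference: remove each training sample's
    # estimated normal-tissue fraction so the Tumor class approximates the
    # pure tumor methylome rather than a purity-diluted average
    normal_mean = normal.data.mean(axis=1)
    corrected = {}
    for sid in top_ids:
        p = max(float(purities.loc[sid, "purity"]), 0.25)
        corrected[sid] = np.clip(
            (tumor.data[sid] - (1.0 - p) * normal_mean) / p, 0.0, 1.0
        )
    tumor_ref = pd.DataFrame(corrected)
    merged = pd.concat([panel.betas.data, tumor_ref], axis=1)
    labels = pd.concat(
        [panel.labels, pd.Series("Tumor", index=tumor_ref.columns)]
    )
    full_panel = ReferencePanel(BetaMatrix(merged, validate=False), labels)

    layers: dict[str, LayerLibrary] = {}
    for tag, spec in tree.library_specs().items():
        layers[tag] = build_layer_library(
            full_panel,
            tag,
            focal_children=spec.focal_children,
            collapse_map=_collapse_map_for(spec),
            n_markers=n_markers,
        )

    params = {
        "n_top": n_top,
        "var_threshold": var_threshold,
        "n_markers": n_markers,
        "tumor_reference": "purity-adjusted top-tertile tumor training samples",
        "n_tumor_reference_samples": len(top_ids),
    }
    return LibraryBundle(
        tumor_type=tumor_type, l1=l1, layers=layers, tree=tree, params=params
    )
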