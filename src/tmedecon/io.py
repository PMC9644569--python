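"""Readers and writers: beta matrices, probe masks, labels, proportion
tables and serialized library bundles.

Beta matrices travel as delimited text with probes in rows (first column)
and samples in columns (header row) — the array-community convention.
Empty cells are missing values. A library bundle is one diff-able
directory: ``meta.json`` (tumor tag, parameters, format version, rosters),
``L1.csv`` (probe, direction), per-layer ``<tag>_means.csv`` and
``<tag>_markers.csv`` tables, and ``hierarchy.csv`` (parent-child edge
list).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import HierarchyTree, LAYER_TAGS
from .library import LayerLibrary, LibraryBundle
from .matrix import (
    BetaMatrix,
    ProbeMask,
    ProportionTable,
    ReferencePanel,
    ValidationError,
)
from .purity import IDMCLibrary

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_mask",
    "read_labels",
    "read_reference_panel",
    "write_proportions",
    "read_proportions",
    "save_library_bundle",
    "load_library_bundle",
    "BundleFormatError",
]

BUNDLE_FORMAT_VERSION = "1.0"

#: float format preserving round-trips to better than 1e-12
_FLOAT_FMT = "%.17g"


class BundleFormatError(ValidationError):
    """A bundle directory is missing components or has the wrong version."""


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_beta_matrix(
    path, dialect: str | None = None, transpose: bool = False
) -> BetaMatrix:
    """Read and validate a delimited beta matrix.

    First column = probe IDs, header row = sample IDs; empty cells become
    missing. ``transpose`` accepts samples-in-rows files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found (malformed header?)")
    non_numeric = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(non_numeric):
        raise ValidationError(f"{path}: non-numeric cells in columns {list(non_numeric)[:3]}")
    if transpose:
        df = df.T
    return BetaMatrix(df)


def write_beta_matrix(m: BetaMatrix, path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = m.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def read_probe_mask(path) -> ProbeMask:
    """One probe ID per line; ``#`` starts a comment; blank lines ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ProbeMask(frozenset(ids))


def read_labels(path) -> pd.Series:
    """Two-column CSV (sample_id, class) -> label Series."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: labels file needs two columns (sample_id, class)")
    s = pd.Series(df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str))
    if s.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample IDs in labels file")
    return s


def read_reference_panel(betas_path, labels_path, dialect: str | None = None) -> ReferencePanel:
    return ReferencePanel(read_beta_matrix(betas_path, dialect), read_labels(labels_path))


def write_proportions(tables: dict[int, pd.DataFrame], path) -> None:
    """Write per-layer proportion tables as long CSV with a ``layer``
    column (sample_id, layer, class, proportion). Row sums are enforced
    before writing — an invalid table raises instead of being silently
    renormalized."""
    frames = []
    for layer in sorted(tables):
        tbl = tables[layer]
        ProportionTable(tbl)  # enforce invariants on write
        long = tbl.reset_index().melt(
            id_vars="sample_id", var_name="class", value_name="proportion"
        )
        long.insert(1, "layer", layer)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_proportions(path) -> dict[int, pd.DataFrame]:
    long = pd.read_csv(path, float_precision="round_trip")
    out: dict[int, pd.DataFrame] = {}
    for layer, sub in long.groupby("layer"):
        wide = sub.pivot(index="sample_id", columns="class", values="proportion")
        # preserve first-appearance class order within the layer
        order = list(dict.fromkeys(sub["class"]))
        out[int(layer)] = wide[order]
    return out


# ----------------------------------------------------------------- bundles
def save_library_bundle(bundle: LibraryBundle, dir_path) -> None:
    """Serialize a bundle to one directory (see module docstring)."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)

    l1 = bundle.l1.entries.copy()
    l1.index.name = "probe_id"
    l1.to_csv(d / "L1.csv", float_format=_FLOAT_FMT)

    for tag, lib in bundle.layers.items():
        means = lib.means.copy()
        means.index.name = "probe_id"
        means.to_csv(d / f"{tag}_means.csv", float_format=_FLOAT_FMT)
        lib.markers.to_csv(d / f"{tag}_markers.csv", index=False, float_format=_FLOAT_FMT)

    edges = [
        {"parent": parent, "child": child}
        for parent, kids in bundle.tree.children.items()
        for child in kids
    ]
    pd.DataFrame(edges).to_csv(d / "hierarchy.csv", index=False)

    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "tumor_type": bundle.tumor_type,
        "params": {
            **bundle.params,
            "l1_n_top": bundle.l1.n_top,
            "l1_var_threshold": bundle.l1.var_threshold,
        },
        "layer_tags": list(bundle.layers),
        "focal_children": {tag: list(lib.focal_children) for tag, lib in bundle.layers.items()},
        "classes": {tag: list(lib.classes) for tag, lib in bundle.layers.items()},
        "tree_root": bundle.tree.root,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_library_bundle(dir_path) -> LibraryBundle:
    d = Path(dir_path)
    if not d.is_dir():
        raise BundleFormatError(f"bundle directory not found: {d}")
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise BundleFormatError("bundle missing components: ['meta.json']")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleFormatError(
            f"bundle format version {version!r} != supported {BUNDLE_FORMAT_VERSION!r}"
        )

    missing = []
    expected = ["L1.csv", "hierarchy.csv"]
    for tag in LAYER_TAGS:
        expected += [f"{tag}_means.csv", f"{tag}_markers.csv"]
    for name in expected:
        if not (d / name).exists():
            missing.append(name)
    if missing:
        raise BundleFormatError(f"bundle missing components: {missing}")

    l1_df = pd.read_csv(d / "L1.csv", index_col=0, float_precision="round_trip")
    params = meta.get("params", {})
    l1 = IDMCLibrary(
        entries=l1_df,
        n_top=int(params.get("l1_n_top", len(l1_df))),
        var_threshold=float(params.get("l1_var_threshold", 0.005)),
    )

    edges = pd.read_csv(d / "hierarchy.csv")
    children: dict[str, tuple[str, ...]] = {}
    for parent, sub in edges.groupby("parent", sort=False):
        children[str(parent)] = tuple(sub["child"].astype(str))
    tree = HierarchyTree(children=children, root=str(meta.get("tree_root", "root")))

    layers: dict[str, LayerLibrary] = {}
    for tag in LAYER_TAGS:
        means = pd.read_csv(d / f"{tag}_means.csv", index_col=0, float_precision="round_trip")
        markers = pd.read_csv(d / f"{tag}_markers.csv", float_precision="round_trip")
        layers[tag] = LayerLibrary(
            tag=tag,
            classes=tuple(meta["classes"][tag]),
            means=means[meta["classes"][tag]],
            markers=markers,
            focal_children=tuple(meta["focal_children"][tag]),
        )

    return LibraryBundle(
        tumor_type=str(meta.get("tumor_type", "")),
        l1=l1,
        layers=layers,
        tree=tree,
        params=params,
    )
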