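"""The six-layer cell-lineage hierarchy and the twelve library slots.

The deconvolution model is a rooted tree over 17 terminal cell classes.
Layer 1 splits a bulk tumor sample into tumor and non-tumor mass; each
deeper layer re-partitions one parent's mass among its children using a
dedicated reference library:

    root
    |-- Tumor                                   (L1: purity density)
    `-- Nontumor                                (L2)
        |-- Angiogenic                          (L3A)
        |   |-- Epithelial / Endothelial / Stromal
        `-- Immune                              (L3B)
            |-- Myeloid                         (L4A)
            |   |-- Granulocyte                 (L5A)
            |   |   `-- Neutrophil / Basophil / Eosinophil
            |   `-- Mononuclear                 (L5B)
            |       `-- Monocyte / DC
            `-- Lymphoid                        (L4B)
                |-- NK
                |-- Bcell                       (L5C)
                |   `-- Bnv / Bmem
                `-- Tcell                       (L5D)
                    |-- CD4T                    (L6A)
                    |   `-- CD4nv / CD4mem / Treg
                    `-- CD8T                    (L6B)
                        `-- CD8nv / CD8mem

Each library separates its *focal children* and absorbs the same-branch
siblings as one collapsed class (e.g. L3A separates epithelial, endothelial
and stromal cells while all immune cells are collapsed into one group).
Every library also carries the tumor reference profile as a non-focal
class — bulk profiles always contain tumor signal, and without a tumor
column the sum-to-one projection would have to smear that mass across
cell classes. The tumor weight itself is always discarded: tumor mass
comes exclusively from the layer-1 purity estimate. Macrophages are
deliberately not modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "HierarchyTree",
    "LibrarySpec",
    "default_tree",
    "LIBRARY_TAGS",
    "LAYER_TAGS",
    "TERMINAL_CLASSES",
]

#: the 11 projection-library tags (L1 is the purity library, handled apart)
LAYER_TAGS = ("L2", "L3A", "L3B", "L4A", "L4B", "L5A", "L5B", "L5C", "L5D", "L6A", "L6B")
LIBRARY_TAGS = ("L1",) + LAYER_TAGS

TERMINAL_CLASSES = (
    "Tumor", "Epithelial", "Endothelial", "Stromal",
    "Neutrophil", "Basophil", "Eosinophil", "Monocyte", "DC",
    "NK", "Bnv", "Bmem", "CD4nv", "CD4mem", "Treg", "CD8nv", "CD8mem",
)

ROOT = "root"

_DEFAULT_CHILDREN: dict[str, tuple[str, ...]] = {
    ROOT: ("Tumor", "Nontumor"),
    "Nontumor": ("Angiogenic", "Immune"),
    "Angiogenic": ("Epithelial", "Endothelial", "Stromal"),
    "Immune": ("Myeloid", "Lymphoid"),
    "Myeloid": ("Granulocyte", "Mononuclear"),
    "Lymphoid": ("NK", "Bcell", "Tcell"),
    "Granulocyte": ("Neutrophil", "Basophil", "Eosinophil"),
    "Mononuclear": ("Monocyte", "DC"),
    "Bcell": ("Bnv", "Bmem"),
    "Tcell": ("CD4T", "CD8T"),
    "CD4T": ("CD4nv", "CD4mem", "Treg"),
    "CD8T": ("CD8nv", "CD8mem"),
}

#: node whose children each projection library separates
_TAG_TO_NODE: dict[str, str] = {
    "L2": "Nontumor",
    "L3A": "Angiogenic",
    "L3B": "Immune",
    "L4A": "Myeloid",
    "L4B": "Lymphoid",
    "L5A": "Granulocyte",
    "L5B": "Mononuclear",
    "L5C": "Bcell",
    "L5D": "Tcell",
    "L6A": "CD4T",
    "L6B": "CD8T",
}

#: non-focal classes each library carries so the projection can attribute
#: off-branch signal somewhere: (class name, subtree roots it collapses).
#: Every library also carries the tumor profile — without a tumor column
#: the sum-to-one projection would have to smear the tumor mass across
#: cell classes; its weight is always discarded in favour of the layer-1
#: purity mass.
_TAG_TO_COLLAPSED: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = {
    "L2": (("Tumor", ("Tumor",)),),
    "L3A": (("Immune", ("Immune",)), ("Tumor", ("Tumor",))),
    "L3B": (("Angiogenic", ("Angiogenic",)), ("Tumor", ("Tumor",))),
    "L4A": (("Lymphoid", ("Lymphoid",)), ("Tumor", ("Tumor",))),
    "L4B": (("Myeloid", ("Myeloid",)), ("Tumor", ("Tumor",))),
    "L5A": (("Mononuclear", ("Mononuclear",)), ("Tumor", ("Tumor",))),
    "L5B": (("Granulocyte", ("Granulocyte",)), ("Tumor", ("Tumor",))),
    "L5C": (("NK_T", ("NK", "Tcell")), ("Tumor", ("Tumor",))),
    "L5D": (("NK_B", ("NK", "Bcell")), ("Tumor", ("Tumor",))),
    "L6A": (("CD8T", ("CD8T",)), ("Tumor", ("Tumor",))),
    "L6B": (("CD4T", ("CD4T",)), ("Tumor", ("Tumor",))),
}


@dataclass(frozen=True)
class LibrarySpec:
    """One library slot: which node it refines and what its classes are.

    ``roster`` maps every library class (focal children first, collapsed
    groups after) to the terminal classes whose reference samples represent
    it.
    """

    tag: str
    node: str
    focal_children: tuple[str, ...]
    roster: Mapping[str, tuple[str, ...]]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.roster)


@dataclass
class HierarchyTree:
    """Rooted cell-lineage tree with per-node library assignments."""

    children: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CHILDREN)
    )
    root: str = ROOT

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------ structure
    def validate(self) -> None:
        seen: set[str] = set()
        order = self.node_order()
        for node in order:
            if node in seen:
                raise ValueError(f"node {node!r} reachable twice: not a tree")
            seen.add(node)
        child_set = {c for kids in self.children.values() for c in kids}
        if self.root in child_set:
            raise ValueError("root must not be a child")

    def node_order(self) -> list[str]:
        """Deterministic depth-first preorder of all nodes."""
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children.get(node, ())))
        return out

    def is_leaf(self, node: str) -> bool:
        return node not in self.children or not self.children[node]

    def leaves(self) -> tuple[str, ...]:
        """Terminal classes in depth-first order (fixed output column order)."""
        return tuple(n for n in self.node_order() if self.is_leaf(n))

    def leaves_under(self, node: str) -> tuple[str, ...]:
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                out.append(n)
            else:
                stack.extend(reversed(self.children[n]))
        return tuple(out)

    def depth(self, node: str) -> int:
        d = {self.root: 0}
        for parent in self.node_order():
            for c in self.children.get(parent, ()):
                d[c] = d[parent] + 1
        return d[node]

    def parent_of(self, node: str) -> str | None:
        for parent, kids in self.children.items():
            if node in kids:
                return parent
        return None

    def max_depth(self) -> int:
        return max(self.depth(n) for n in self.node_order())

    def classes_at_layer(self, h: int) -> tuple[str, ...]:
        """The cut of the tree at depth ``h``: nodes at depth h plus leaves
        shallower than h, in depth-first order."""
        if not 1 <= h <= self.max_depth():
            raise ValueError(f"layer must be in 1..{self.max_depth()}, got {h}")
        out: list[str] = []
        depths = {self.root: 0}
        stack = [self.root]
        # preorder walk truncated at depth h
        order: list[str] = []
        while stack:
            n = stack.pop()
            order.append(n)
            for c in reversed(self.children.get(n, ())):
                depths[c] = depths[n] + 1
                stack.append(c)
        for n in order:
            d = depths[n]
            if d == h or (d < h and self.is_leaf(n)):
                out.append(n)
        return tuple(out)

    def ancestor_at_depth(self, leaf: str, h: int) -> str:
        """The depth-h cut class a terminal class rolls up into."""
        path = [leaf]
        node = leaf
        while node != self.root:
            node = self.parent_of(node)
            if node is None:
                raise ValueError(f"{leaf!r} not in tree")
            path.append(node)
        path.reverse()  # root ... leaf
        return path[min(h, len(path) - 1)]

    # ------------------------------------------------------------ libraries
    def library_specs(self) -> dict[str, LibrarySpec]:
        """The 11 projection-library slots (tags L2..L6B) for this tree."""
        specs: dict[str, LibrarySpec] = {}
        for tag in LAYER_TAGS:
            node = _TAG_TO_NODE[tag]
            focal = self.children[node]
            roster: dict[str, tuple[str, ...]] = {}
            for child in focal:
                roster[child] = self.leaves_under(child)
            for name, roots in _TAG_TO_COLLAPSED.get(tag, ()):
                members: list[str] = []
                for r in roots:
                    members.extend(self.leaves_under(r))
                roster[name] = tuple(members)
            specs[tag] = LibrarySpec(tag=tag, node=node, focal_children=focal, roster=roster)
        return specs

    def library_for_node(self) -> dict[str, str]:
        """node -> library tag for every refined node."""
        return {node: tag for tag, node in _TAG_TO_NODE.items()}


def default_tree() -> HierarchyTree:
    """The stock 17-class carcinoma TME hierarchy."""
    return HierarchyTree()
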