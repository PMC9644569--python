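"""Constrained projection and the hierarchical deconvolution cascade.

Each layer solves the Houseman-style constrained projection: given a bulk
methylation vector y and the library's class-mean matrix X,

    minimize ||y - X w||^2   subject to   w >= 0,  sum(w) = 1,

on the probes shared by sample and library. The cascade then converts the
per-layer *relative* weights into *absolute* proportions: layer 1 fixes
the tumor mass as the purity-density mode; layer 2 splits the non-tumor
mass between immune and angiogenic components (the library's own Tumor
weight is discarded); every deeper layer renormalizes its focal children's
weights and multiplies by the parent's absolute mass, so children always
sum exactly to their parent.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .hierarchy import HierarchyTree
from .library import LayerLibrary, LibraryBundle
from .matrix import BetaMatrix, ProportionTable, ValidationError
from .purity import estimate_purity

__all__ = [
    "ProjectionResult",
    "DeconvolutionResult",
    "constrained_projection",
    "deconvolve_layer",
    "deconvolve",
    "aggregate_to_layer",
    "simplex_grid_search",
]

#: KKT feasibility slack for the exact active-set enumeration
_QP_TOL = 1e-10


@dataclass
class ProjectionResult:
    weights: pd.Series           # class -> fraction, >= 0, sums to 1
    residual_norm: float
    n_probes_used: int
    warnings: list[str] = field(default_factory=list)


def _simplex_lsq_exact(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Exact simplex-constrained least squares by support-set enumeration.

    The optimum's support set S satisfies the equality-constrained KKT
    system restricted to S, so scanning every non-empty support set and
    keeping the feasible solution with the smallest objective is exact.
    Intended for small class counts (every shipped library has <= 4).
    """
    k = X.shape[1]
    G = X.T @ X
    c = X.T @ y
    warns: list[str] = []
    if k > 1 and np.linalg.cond(G) > 1e10:
        warns.append("collinear library columns; projection may be non-unique")
    best_obj = np.inf
    best_w: np.ndarray | None = None
    for size in range(1, k + 1):
        for S in itertools.combinations(range(k), size):
            idx = np.array(S)
            m = len(idx)
            KKT = np.zeros((m + 1, m + 1))
            KKT[:m, :m] = 2.0 * G[np.ix_(idx, idx)]
            KKT[:m, m] = 1.0
            KKT[m, :m] = 1.0
            rhs = np.concatenate([2.0 * c[idx], [1.0]])
            try:
                sol = np.linalg.solve(KKT, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
            w_S = sol[:m]
            if w_S.min() < -_QP_TOL:
                continue
            w = np.zeros(k)
            w[idx] = np.clip(w_S, 0.0, None)
            obj = float(w @ G @ w - 2.0 * c @ w)
            if obj < best_obj - 1e-14:
                best_obj = obj
                best_w = w
    assert best_w is not None  # size-1 supports are always feasible
    return best_w, warns


def _simplex_lsq_slsqp(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, list[str]]:
    k = X.shape[1]
    G, c = X.T @ X, X.T @ y

    def f(w):
        return float(w @ G @ w - 2.0 * c @ w)

    def grad(w):
        return 2.0 * (G @ w - c)

    res = optimize.minimize(
        f,
        np.full(k, 1.0 / k),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, None), []


def simplex_grid_search(X: np.ndarray, y: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Brute-force minimizer of ||y - Xw||^2 over the simplex grid with the
    given step. Independent of the QP path; used as a cross-check oracle
    and as an alternative solver in recovery studies."""
    k = X.shape[1]
    n_steps = int(round(1.0 / step))
    W = _simplex_grid(k, n_steps) * step
    G, c = X.T @ X, X.T @ y
    obj = np.einsum("ij,jk,ik->i", W, G, W) - 2.0 * W @ c
    return W[int(np.argmin(obj))]


_GRID_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _simplex_grid(k: int, n_steps: int) -> np.ndarray:
    """All integer compositions of n_steps into k parts (stars and bars)."""
    key = (k, n_steps)
    if key not in _GRID_CACHE:
        grids = []
        for dividers in itertools.combinations(range(n_steps + k - 1), k - 1):
            prev = -1
            parts = []
            for d in dividers:
                parts.append(d - prev - 1)
                prev = d
            parts.append(n_steps + k - 2 - prev)
            grids.append(parts)
        _GRID_CACHE[key] = np.asarray(grids, dtype=float)
    return _GRID_CACHE[key]


def constrained_projection(
    y: pd.Series | dict,
    lib: LayerLibrary,
    solver: str = "exact",
    sum_constraint: str = "eq",
) -> ProjectionResult:
    """Project one sample onto a layer library's class means.

    ``solver``: "exact" (support-set enumeration, default; SLSQP above 10
    classes), "slsqp", or "grid" (0.01-step brute force, for oracle runs).

    ``sum_constraint``: "eq" (Σw = 1, the default — weights are fractions
    of a separately fixed parent mass) or "le" (Σw ≤ 1, for comparison:
    plain non-negative least squares unless the cap binds). The returned
    weights are renormalized to the simplex either way.
    """
    s = pd.Series(y, dtype=float)
    avail = lib.means.index.intersection(s.index)
    vals = s.loc[avail]
    avail = avail[vals.notna().to_numpy()]
    k = len(lib.classes)
    min_probes = max(10, k + 5)
    if len(avail) < min_probes:
        raise ValidationError(
            f"{lib.tag}: only {len(avail)} usable probes (< {min_probes})"
        )
    warns: list[str] = []
    if len(avail) < 0.5 * len(lib.means):
        warns.append(f"{lib.tag}: < 50% probe coverage ({len(avail)}/{len(lib.means)})")

    X = lib.means.loc[avail].to_numpy(dtype=float)
    yv = s.loc[avail].to_numpy(dtype=float)

    if sum_constraint not in ("eq", "le"):
        raise ValueError(f"sum_constraint must be 'eq' or 'le', got {sum_constraint!r}")
    if sum_constraint == "le":
        w_nnls, _ = optimize.nnls(X, yv)
        if w_nnls.sum() <= 1.0 + 1e-12:
            w = w_nnls  # the cap is slack: plain NNLS is the optimum
        else:
            w, extra = _simplex_lsq_exact(X, yv)
            warns.extend(extra)
    elif solver == "grid":
        w = simplex_grid_search(X, yv)
    elif solver == "slsqp" or (solver == "exact" and k > 10):
        w, extra = _simplex_lsq_slsqp(X, yv)
        warns.extend(extra)
    elif solver == "exact":
        w, extra = _simplex_lsq_exact(X, yv)
        warns.extend(extra)
    else:
        raise ValueError(f"unknown solver {solver!r}")

    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total > 0:
        w = w / total
    resid = float(np.linalg.norm(yv - X @ w))
    return ProjectionResult(
        weights=pd.Series(w, index=list(lib.classes)),
        residual_norm=resid,
        n_probes_used=int(len(avail)),
        warnings=warns,
    )


def deconvolve_layer(
    y: pd.Series | dict,
    lib: LayerLibrary,
    focal_children: tuple[str, ...] | None = None,
    parent_mass: float = 1.0,
    solver: str = "exact",
) -> tuple[dict[str, float], list[str]]:
    """Split a parent's absolute mass among its focal children.

    Runs the constrained projection, renormalizes the focal children's
    weights among themselves, multiplies by ``parent_mass`` and discards
    non-focal (collapsed) weights. If every focal weight is zero the
    parent mass is split equally with a warning, preserving conservation.
    """
    if not 0.0 <= parent_mass <= 1.0 + 1e-9:
        raise ValidationError(f"parent_mass must be in [0, 1], got {parent_mass}")
    focal = tuple(focal_children) if focal_children is not None else lib.focal_children
    proj = constrained_projection(y, lib, solver=solver)
    warns = list(proj.warnings)
    w_focal = proj.weights.loc[list(focal)].to_numpy()
    total = w_focal.sum()
    if total <= 0:
        warns.append(f"{lib.tag}: all focal weights zero; equal split of parent mass")
        rel = np.full(len(focal), 1.0 / len(focal))
    else:
        rel = w_focal / total
    return {c: float(r * parent_mass) for c, r in zip(focal, rel)}, warns


@dataclass
class DeconvolutionResult:
    """Per-layer absolute proportion tables plus provenance."""

    tables: dict[int, pd.DataFrame]   # layer -> samples x classes
    provenance: dict = field(default_factory=dict)

    def proportions(self, h: int) -> ProportionTable:
        if h not in self.tables:
            raise ValidationError(f"layer {h} was not computed")
        return ProportionTable(self.tables[h])


def deconvolve(
    mix: BetaMatrix,
    bundle: LibraryBundle,
    h: int = 6,
    solver: str = "exact",
    grid_step: float = 0.001,
) -> DeconvolutionResult:
    """Hierarchical deconvolution of bulk samples down to layer ``h``.

    Layer 1 is the purity-density estimate (tumor vs non-tumor); layers
    2..h cascade the constrained projections down the lineage tree.
    Classes with no sub-library at a given layer (e.g. NK below layer 4)
    are carried forward unchanged. Roll-up consistency across layers holds
    by construction.
    """
    tree = bundle.tree
    if not 1 <= h <= tree.max_depth():
        raise ValidationError(f"h must be in 1..{tree.max_depth()}, got {h}")
    node_lib = tree.library_for_node()

    all_warns: dict[str, list[str]] = {}
    per_layer_rows: dict[int, list[pd.Series]] = {k: [] for k in range(1, h + 1)}

    for sid in mix.sample_ids:
        y = mix.sample(sid)
        warns: list[str] = []
        est = estimate_purity(y, bundle.l1, grid_step=grid_step, sample_id=sid)
        warns.extend(est.warnings)
        mass: dict[str, float] = {"Tumor": est.purity, "Nontumor": 1.0 - est.purity}

        for layer in range(2, h + 1):
            parents = [
                n
                for n in tree.classes_at_layer(layer - 1)
                if not tree.is_leaf(n) and n in node_lib
            ]
            for node in parents:
                lib = bundle.layers[node_lib[node]]
                children_mass, w = deconvolve_layer(
                    y,
                    lib,
                    focal_children=tree.children[node],
                    parent_mass=mass[node],
                    solver=solver,
                )
                warns.extend(w)
                mass.update(children_mass)

        for layer in range(1, h + 1):
            classes = tree.classes_at_layer(layer)
            per_layer_rows[layer].append(
                pd.Series({c: mass[c] for c in classes}, name=sid)
            )
        if warns:
            all_warns[sid] = warns

    tables = {
        layer: pd.DataFrame(rows)[list(tree.classes_at_layer(layer))]
        for layer, rows in per_layer_rows.items()
    }
    for t in tables.values():
        t.index.name = "sample_id"
    provenance = {
        "tumor_type": bundle.tumor_type,
        "h": h,
        "solver": solver,
        "params": dict(bundle.params),
        "warnings": all_warns,
    }
    return DeconvolutionResult(tables=tables, provenance=provenance)


def aggregate_to_layer(
    res: DeconvolutionResult, tree: HierarchyTree, from_h: int, to_h: int
) -> pd.DataFrame:
    """Roll a deeper layer's table up to a shallower one by summing each
    subtree's columns; exactly reproduces the stored shallower table."""
    if to_h >= from_h:
        raise ValidationError("to_h must be shallower than from_h")
    for k in (from_h, to_h):
        if k not in res.tables:
            raise ValidationError(f"layer {k} was not computed")
    deep = res.tables[from_h]
    target_classes = tree.classes_at_layer(to_h)
    out = pd.DataFrame(0.0, index=deep.index, columns=list(target_classes))
    for col in deep.columns:
        out[_cut_ancestor(tree, col, to_h)] += deep[col]
    return out


def _cut_ancestor(tree: HierarchyTree, node: str, h: int) -> str:
    """Ancestor of an internal node at the depth-h cut."""
    d = tree.depth(node)
    while d > h:
        node = tree.parent_of(node)
        d -= 1
    return node
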