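"""Layer 1: tumor purity from informative differentially methylated CpGs.

The iDMC library is built from tumor and matched-normal training betas:
candidate CpGs must have tumor-sample beta variance above a threshold
(default 0.005), are ranked by two-sided rank-sum (Wilcoxon/Mann-Whitney)
p-value, and the top ``n_top`` (default 1000) are kept. Each iDMC is
labelled *hyper* (mean tumor beta above mean normal beta) or *hypo*.

For a bulk sample, hypermethylated iDMC betas are used as-is and
hypomethylated ones are flipped to ``1 - beta``, so that every transformed
value rises with tumor content; a Gaussian-kernel density is fitted to the
transformed values and the estimated purity is the mode of that density.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import BetaMatrix, ValidationError

__all__ = [
    "IDMCLibrary",
    "PurityEstimate",
    "select_idmc",
    "transform_idmc_betas",
    "estimate_purity",
    "estimate_purity_matrix",
]

HYPER = "hyper"
HYPO = "hypo"


@dataclass
class IDMCLibrary:
    """Ordered iDMC list (most significant first) with directions."""

    entries: pd.DataFrame  # index: probe_id; columns: direction, p, mean_diff
    n_top: int
    var_threshold: float

    def __post_init__(self) -> None:
        if self.entries.index.has_duplicates:
            raise ValidationError("duplicate probes in iDMC library")
        if len(self.entries) > self.n_top:
            raise ValidationError("library longer than n_top")
        bad = ~self.entries["direction"].isin([HYPER, HYPO])
        if bad.any():
            raise ValidationError("every iDMC needs a hyper/hypo direction")

    @property
    def probe_ids(self) -> pd.Index:
        return self.entries.index

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PurityEstimate:
    """Purity (density mode) plus diagnostics for one sample."""

    sample_id: str | None
    purity: float
    n_probes_used: int
    density_grid: tuple[np.ndarray, np.ndarray] | None = None
    multimodal: bool = False
    warnings: list[str] = field(default_factory=list)


def _ranksum_pvalues(
    tumor: np.ndarray, normal: np.ndarray
) -> np.ndarray:
    """Two-sided Mann-Whitney p-values per probe (rows).

    Exact enumeration when the smaller group has <= 10 samples and a probe
    has no ties across groups; otherwise the normal approximation with
    continuity and tie corrections.
    """
    n_t, n_n = tumor.shape[1], normal.shape[1]
    if min(n_t, n_n) <= 10:
        pvals = np.empty(tumor.shape[0])
        for i in range(tumor.shape[0]):
            x, y = tumor[i], normal[i]
            combined = np.concatenate([x, y])
            method = "exact" if len(np.unique(combined)) == len(combined) else "asymptotic"
            pvals[i] = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        return pvals
    res = stats.mannwhitneyu(tumor, normal, alternative="two-sided", method="asymptotic", axis=1)
    return np.asarray(res.pvalue)


def select_idmc(
    tumor: BetaMatrix,
    normal: BetaMatrix,
    n_top: int = 1000,
    var_threshold: float = 0.005,
) -> IDMCLibrary:
    """Build the layer-1 iDMC library from tumor/normal training matrices.

    Candidates are the shared probes whose tumor-sample beta variance
    (unbiased, n-1) exceeds ``var_threshold``; they are ranked by rank-sum
    p-value ascending, ties broken by larger absolute tumor-normal mean
    difference, then probe ID, and the top ``n_top`` kept. Direction is
    hyper when mean tumor beta exceeds mean normal beta, else hypo.
    """
    normal_probes = set(normal.probe_ids)
    shared = [p for p in tumor.probe_ids if p in normal_probes]
    if not shared:
        raise ValidationError("tumor and normal matrices share no probes")
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValidationError("need >= 2 tumor and >= 2 normal samples")

    T = tumor.data.loc[shared].to_numpy(dtype=float)
    N = normal.data.loc[shared].to_numpy(dtype=float)
    if np.isnan(T).any() or np.isnan(N).any():
        raise ValidationError("iDMC selection requires complete training matrices")

    tumor_var = T.var(axis=1, ddof=1)
    cand = tumor_var > var_threshold
    if not cand.any():
        raise ValidationError(
            "zero candidates: no probe exceeds the tumor variance threshold "
            f"{var_threshold}"
        )
    cand_idx = np.flatnonzero(cand)
    pvals = _ranksum_pvalues(T[cand_idx], N[cand_idx])
    mean_diff = T[cand_idx].mean(axis=1) - N[cand_idx].mean(axis=1)

    order = pd.DataFrame(
        {
            "p": pvals,
            "neg_abs_diff": -np.abs(mean_diff),
            "probe": [shared[i] for i in cand_idx],
            "mean_diff": mean_diff,
        }
    ).sort_values(["p", "neg_abs_diff", "probe"], kind="mergesort")

    if len(order) < n_top:
        warnings.warn(
            f"only {len(order)} candidate iDMCs pass the variance filter; "
            f"library shorter than n_top={n_top}",
            stacklevel=2,
        )
    top = order.head(n_top)
    entries = pd.DataFrame(
        {
            "direction": np.where(top["mean_diff"] > 0, HYPER, HYPO),
            "p": top["p"].to_numpy(),
            "mean_diff": top["mean_diff"].to_numpy(),
        },
        index=pd.Index(top["probe"], name="probe_id"),
    )
    return IDMCLibrary(entries=entries, n_top=n_top, var_threshold=var_threshold)


def transform_idmc_betas(
    sample_betas: pd.Series | dict, lib: IDMCLibrary
) -> np.ndarray:
    """Direction-transform a sample's betas over the library probes.

    Hyper iDMCs keep beta; hypo iDMCs become ``1 - beta``. Probes missing
    from the sample (absent or NaN) are skipped. The result is clipped to
    [0, 1] (array betas can sit exactly on the bounds).
    """
    s = pd.Series(sample_betas, dtype=float)
    avail = lib.entries.index.intersection(s.index)
    vals = s.loc[avail]
    keep = vals.notna()
    vals = vals[keep]
    directions = lib.entries.loc[vals.index, "direction"]
    out = np.where(directions == HYPO, 1.0 - vals.to_numpy(), vals.to_numpy())
    return np.clip(out, 0.0, 1.0)


def estimate_purity(
    sample_betas: pd.Series | dict,
    lib: IDMCLibrary,
    grid_step: float = 0.001,
    bw_method: str | float = "silverman",
    sample_id: str | None = None,
) -> PurityEstimate:
    """Estimate tumor purity as the mode of a Gaussian KDE over the
    transformed iDMC betas, evaluated on the closed grid [0, 1].

    Mode ties resolve to the lowest grid value; a multimodality flag is set
    when a secondary local maximum reaches 95% of the global one (bimodal
    purity densities do occur, e.g. in histologically mixed tumors).
    """
    values = transform_idmc_betas(sample_betas, lib)
    warns: list[str] = []
    if len(values) < 10:
        raise ValidationError(
            f"only {len(values)} usable iDMC probes (< 10); cannot estimate purity"
        )
    if len(values) < 0.5 * len(lib):
        warns.append(
            f"only {len(values)}/{len(lib)} library probes available (< 50%)"
        )

    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2.0, grid_step), 12)
    if np.std(values) < 1e-12:
        # degenerate point mass: snap the common value to the grid
        purity = float(grid[np.argmin(np.abs(grid - values[0]))])
        return PurityEstimate(
            sample_id=sample_id,
            purity=purity,
            n_probes_used=len(values),
            density_grid=None,
            multimodal=False,
            warnings=warns + ["degenerate: all transformed values identical"],
        )
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    density = kde(grid)
    purity = float(grid[int(np.argmax(density))])  # argmax -> lowest tied grid point

    interior = (density[1:-1] >= density[:-2]) & (density[1:-1] > density[2:])
    peaks = density[1:-1][interior]
    multimodal = bool(len(peaks) >= 2 and np.sort(peaks)[-2] >= 0.95 * density.max())

    return PurityEstimate(
        sample_id=sample_id,
        purity=purity,
        n_probes_used=int(len(values)),
        density_grid=(grid, density),
        multimodal=multimodal,
        warnings=warns,
    )


def estimate_purity_matrix(
    betas: BetaMatrix,
    lib: IDMCLibrary,
    grid_step: float = 0.001,
    bw_method: str | float = "silverman",
) -> pd.DataFrame:
    """Per-sample purity for every column of ``betas``.

    Returns a DataFrame indexed by sample with columns purity,
    n_probes_used, multimodal_flag.
    """
    rows = []
    for sid in betas.sample_ids:
        est = estimate_purity(
            betas.sample(sid), lib, grid_step=grid_step, bw_method=bw_method, sample_id=sid
        )
        rows.append((sid, est.purity, est.n_probes_used, est.multimodal))
    return pd.DataFrame(
        rows, columns=["sample_id", "purity", "n_probes_used", "multimodal_flag"]
    ).set_index("sample_id")
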