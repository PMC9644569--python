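"""Core in-memory containers: beta matrices, reference panels, probe masks,
proportion tables.

A *beta value* is the per-CpG methylation fraction in [0, 1] measured by an
Infinium array (methylated / total intensity). Everything downstream —
purity estimation, marker selection, constrained projection — operates on
beta matrices with CpG probes in rows and samples in columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "ReferencePanel",
    "ProbeMask",
    "ProportionTable",
    "apply_probe_mask",
]

#: absolute slack allowed beyond [0, 1] before a value is rejected
RANGE_TOL = 1e-9

#: absolute tolerance on proportion-table row sums
ROW_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


class BetaMatrix:
    """A validated CpG-probe x sample matrix of methylation beta values.

    Parameters
    ----------
    data
        DataFrame with probe identifiers as the index and sample identifiers
        as columns. Entries must lie in [0, 1] (within ``1e-9``) or be
        missing (NaN). Missing values are represented internally by NaN,
        pandas' dedicated missing marker — never a sentinel number.
    """

    def __init__(self, data: pd.DataFrame, *, validate: bool = True):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        data = data.astype(float, copy=False)
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        if validate:
            self._validate(data)
        self._data = data

    @staticmethod
    def _validate(data: pd.DataFrame) -> None:
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValidationError("beta matrix needs at least 1 probe and 1 sample")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValidationError(f"duplicate probe identifier: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        vals = data.to_numpy(dtype=float)
        bad = (vals < -RANGE_TOL) | (vals > 1.0 + RANGE_TOL)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0, 1]: {vals[i, j]!r} at probe "
                f"{data.index[i]!r}, sample {data.columns[j]!r}"
            )

    # ------------------------------------------------------------------ API
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def probe_ids(self) -> pd.Index:
        return self._data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self._data.columns

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def sample(self, sample_id: str) -> pd.Series:
        """Beta values of one sample as a probe-indexed Series."""
        return self._data[sample_id]

    def select_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        ids = [p for p in probe_ids if p in self._data.index]
        return BetaMatrix(self._data.loc[ids], validate=False)

    def select_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self._data[list(sample_ids)], validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"

    def equals(self, other: "BetaMatrix", tol: float = 0.0) -> bool:
        if not (self.probe_ids.equals(other.probe_ids) and self.sample_ids.equals(other.sample_ids)):
            return False
        a, b = self.values, other.values
        na, nb = np.isnan(a), np.isnan(b)
        if not (na == nb).all():
            return False
        return bool(np.all(np.abs(a[~na] - b[~nb]) <= tol))


@dataclass
class ReferencePanel:
    """A beta matrix of purified-cell samples plus their cell-class labels."""

    betas: BetaMatrix
    labels: pd.Series  # sample_id -> class name

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).astype(str)
        self.labels.index = self.labels.index.astype(str)
        missing = [s for s in self.betas.sample_ids if s not in self.labels.index]
        if missing:
            raise ValidationError(f"samples without a class label: {missing[:5]}")
        self.labels = self.labels.loc[self.betas.sample_ids]

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.labels:
            seen.setdefault(c, None)
        return list(seen)

    def class_samples(self, class_name: str) -> list[str]:
        return list(self.labels.index[self.labels == class_name])

    def subset_classes(self, classes: Iterable[str]) -> "ReferencePanel":
        keep = self.labels.index[self.labels.isin(list(classes))]
        return ReferencePanel(self.betas.select_samples(keep), self.labels.loc[keep])

    def relabel(self, mapping: Mapping[str, str]) -> "ReferencePanel":
        """Collapse classes: map original class names to group names; samples
        whose class is absent from ``mapping`` are dropped."""
        keep = self.labels.index[self.labels.isin(list(mapping))]
        if len(keep) == 0:
            raise ValidationError("relabeling drops every sample")
        new_labels = self.labels.loc[keep].map(dict(mapping))
        return ReferencePanel(self.betas.select_samples(keep), new_labels)


@dataclass(frozen=True)
class ProbeMask:
    """A set of probe identifiers to exclude (cross-reactive, SNP-related,
    sex-chromosome or otherwise untrusted probes)."""

    excluded_probe_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "excluded_probe_ids", frozenset(map(str, self.excluded_probe_ids)))

    def __len__(self) -> int:
        return len(self.excluded_probe_ids)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.excluded_probe_ids


def apply_probe_mask(m: BetaMatrix, mask: ProbeMask) -> BetaMatrix:
    """Drop masked probes, preserving probe order; mask IDs absent from the
    matrix are ignored. Raises if nothing survives."""
    keep = [p for p in m.probe_ids if p not in mask]
    if not keep:
        raise ValidationError("all probes masked")
    if len(keep) == len(m.probe_ids):
        return m
    return BetaMatrix(m.data.loc[keep], validate=False)


class ProportionTable:
    """Sample x class table of cell-class proportions; each row is a point on
    the probability simplex (non-negative, sums to 1 within 1e-6)."""

    def __init__(self, data: pd.DataFrame, *, validate: bool = True):
        data = data.astype(float, copy=False)
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        if validate:
            self._validate(data)
        self._data = data

    @staticmethod
    def _validate(data: pd.DataFrame) -> None:
        vals = data.to_numpy(dtype=float)
        if (vals < -RANGE_TOL).any():
            raise ValidationError("negative proportion")
        sums = vals.sum(axis=1)
        off = np.abs(sums - 1.0)
        if (off > ROW_SUM_TOL).any():
            i = int(np.argmax(off))
            raise ValidationError(
                f"row {data.index[i]!r} sums to {sums[i]:.8f}, not 1 within {ROW_SUM_TOL}"
            )

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> pd.Index:
        return self._data.index

    @property
    def class_names(self) -> pd.Index:
        return self._data.columns

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ProportionTable({self._data.shape[0]} samples x {self._data.shape[1]} classes)"
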