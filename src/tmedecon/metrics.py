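"""Recovery metrics on the percent scale.

Error is defined as predicted proportion (%) minus true proportion (%);
absolute error is its magnitude. Per class, the RMSE over samples and the
Pearson correlation (with descriptive p-value) across samples are
reported; the overall mean absolute error pools every class x sample
cell. Correlation is flagged undefined — not zeroed — when either vector
is constant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ProportionTable, ValidationError

__all__ = ["RecoveryReport", "error_metrics"]


@dataclass
class RecoveryReport:
    per_class: pd.DataFrame        # class-indexed metric table
    overall_mean_abs_error_pct: float
    overall_sd_abs_error_pct: float
    errors_pct: pd.DataFrame = field(repr=False, default=None)  # samples x classes

    def to_csv(self, path) -> None:
        self.per_class.to_csv(path, float_format="%.10g")

    def __str__(self) -> str:
        lines = [self.per_class.round(3).to_string()]
        lines.append(
            f"overall mean |error|: {self.overall_mean_abs_error_pct:.3f} pct points "
            f"(sd {self.overall_sd_abs_error_pct:.3f})"
        )
        return "\n".join(lines)


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, ProportionTable):
        return x.data
    if hasattr(x, "proportions"):  # SyntheticTruth
        return x.proportions
    return pd.DataFrame(x)


def error_metrics(pred, truth) -> RecoveryReport:
    """Compare predicted and true proportion tables (same samples/classes).

    Accepts ProportionTable, SyntheticTruth or plain DataFrames on the
    [0, 1] proportion scale; all reported metrics are in percentage
    points.
    """
    p = _as_frame(pred).astype(float)
    t = _as_frame(truth).astype(float)
    sample_diff = set(p.index).symmetric_difference(t.index)
    if sample_diff:
        raise ValidationError(f"sample mismatch: {sorted(sample_diff)[:5]}")
    class_diff = set(p.columns).symmetric_difference(t.columns)
    if class_diff:
        raise ValidationError(f"class mismatch: {sorted(class_diff)[:5]}")
    t = t.loc[p.index, p.columns]

    err = (p - t) * 100.0
    abs_err = err.abs()
    rows = []
    for c in p.columns:
        e = err[c].to_numpy()
        pv, tv = p[c].to_numpy(), t[c].to_numpy()
        undefined = np.std(pv) == 0 or np.std(tv) == 0
        if undefined:
            r, r_p = np.nan, np.nan
        else:
            r, r_p = stats.pearsonr(pv, tv)
        rows.append(
            {
                "class": c,
                "n": len(e),
                "mean_error_pct": float(np.mean(e)),
                "mean_abs_error_pct": float(np.mean(np.abs(e))),
                "rmse_pct": float(np.sqrt(np.mean(e**2))),
                "pearson_r": float(r) if not undefined else np.nan,
                "pearson_p": float(r_p) if not undefined else np.nan,
                "r_undefined": bool(undefined),
            }
        )
    per_class = pd.DataFrame(rows).set_index("class")
    pooled = abs_err.to_numpy().ravel()
    return RecoveryReport(
        per_class=per_class,
        overall_mean_abs_error_pct=float(np.mean(pooled)),
        overall_sd_abs_error_pct=float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0,
        errors_pct=err,
    )
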