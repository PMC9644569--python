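"""End-to-end recovery reporting: deconvolve a fixture cohort against its
ground truth and score it."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import load_library_bundle, read_beta_matrix
from .matrix import ValidationError
from .metrics import RecoveryReport, error_metrics
from .projection import deconvolve

__all__ = ["recovery_report", "aggregate_truth"]


def aggregate_truth(truth: pd.DataFrame, tree, h: int) -> pd.DataFrame:
    """Roll leaf-level true proportions up to the depth-h cut classes."""
    classes = tree.classes_at_layer(h)
    out = pd.DataFrame(0.0, index=truth.index, columns=list(classes))
    for leaf in truth.columns:
        out[tree.ancestor_at_depth(leaf, h)] += truth[leaf]
    return out


def recovery_report(
    fixture_dir,
    bundle_dir,
    h: int = 6,
    out_path=None,
    solver: str = "exact",
) -> RecoveryReport:
    """Run the full pipeline on a fixture directory and score recovery.

    The fixture directory must hold ``mixtures.csv`` (beta matrix) and
    ``truth.csv`` (sample x terminal-class proportions). Writes the
    per-class metric table to ``out_path`` if given, and returns the
    report.
    """
    fixture = Path(fixture_dir)
    mix_path = fixture / "mixtures.csv"
    truth_path = fixture / "truth.csv"
    for p in (mix_path, truth_path):
        if not p.exists():
            raise ValidationError(f"fixture missing {p.name}")
    mix = read_beta_matrix(mix_path)
    truth = pd.read_csv(truth_path, index_col=0, float_precision="round_trip")
    bundle = load_library_bundle(bundle_dir)

    res = deconvolve(mix, bundle, h=h, solver=solver)
    pred = res.tables[h]
    truth_h = aggregate_truth(truth, bundle.tree, h)
    report = error_metrics(pred, truth_h)
    if out_path is not None:
        report.to_csv(out_path)
    return report
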