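"""Summaries of a completed run: per-gait descriptive statistics, the
Hildebrand scatter export, accuracy grids and confusion matrices."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd

from .evaluate import CVResult

__all__ = ["gait_descriptives", "hildebrand_export", "write_report"]

_DESCRIPTIVE_VARS = [
    "stride_duration",
    "stride_frequency",
    "stance_duration",
    "duty_factor",
]


def gait_descriptives(features: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the stride temporal variables per gait, plus stride
    counts — the descriptive-statistics table of a run."""
    rows = []
    for gait, grp in features.groupby("gait_label", sort=True):
        row: Dict[str, object] = {"gait": gait, "strides": len(grp)}
        for var in _DESCRIPTIVE_VARS:
            row[f"{var}_mean"] = grp[var].mean()
            row[f"{var}_sd"] = grp[var].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def hildebrand_export(features: pd.DataFrame) -> pd.DataFrame:
    """(gait, x, y) triples, one per complete stride: x = diagonal advanced
    placement, y = lateral advanced placement."""
    return pd.DataFrame(
        {
            "gait": features["gait_label"],
            "x": features["diagonal_advanced_placement"],
            "y": features["lateral_advanced_placement"],
        }
    )


def write_report(
    out_dir,
    features: pd.DataFrame,
    grid_table: Optional[pd.DataFrame] = None,
    cv_results: Optional[Mapping[str, CVResult]] = None,
) -> Path:
    """Write the full report bundle (CSV tables + a human-readable
    summary); returns the summary path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    desc = gait_descriptives(features)
    desc.to_csv(out / "gait_descriptives.csv", index=False)
    hildebrand_export(features).to_csv(out / "hildebrand.csv", index=False)

    lines = ["# Gait classification run report", ""]
    lines.append(f"Strides: {len(features)} across {features['horse_id'].nunique()} horses")
    lines.append("")
    lines.append("Per-gait descriptive statistics (mean, SD):")
    for _, r in desc.iterrows():
        lines.append(
            f"  {r['gait']:<8} n={int(r['strides']):>5}  "
            f"stride {r['stride_duration_mean']:.3f}±{r['stride_duration_sd']:.3f} s  "
            f"freq {r['stride_frequency_mean']:.2f}±{r['stride_frequency_sd']:.2f} Hz  "
            f"duty {r['duty_factor_mean']:.1f}±{r['duty_factor_sd']:.1f} %"
        )

    if grid_table is not None and len(grid_table):
        grid_table.to_csv(out / "accuracy_grid.csv", index=False)
        lines.append("")
        lines.append("Cross-validated accuracy (mean ± SD over folds):")
        summary = (
            grid_table.groupby("cell")[["mean_accuracy", "sd_accuracy"]].first().sort_values(
                "mean_accuracy", ascending=False
            )
        )
        for cell, r in summary.iterrows():
            lines.append(
                f"  {cell:<22} {100 * r['mean_accuracy']:5.1f} ± {100 * r['sd_accuracy']:.1f} %"
            )

    if cv_results:
        for cell, res in cv_results.items():
            safe = cell.replace("/", "_")
            res.pooled.to_frame().to_csv(out / f"confusion_{safe}.csv")

    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    return summary_path
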