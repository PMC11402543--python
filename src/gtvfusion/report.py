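"""Cohort-level summaries and distribution plots.

STAPLE GTV rows report the median (min, max) over patients.  Individual GTV
rows first take each observer's median across patients, then report the mean
of the observers' medians together with the largest and smallest median.
Medians use the midpoint convention for even counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import OverlapRecord, records_to_frame

__all__ = ["CohortSummary", "summarize_cohort", "write_summary_table", "plot_metric_distribution"]

_METRICS = ("dsc", "coverage")


@dataclass
class CohortSummary:
    """Aggregated metric table, one row per (gtv_name, source, margin, metric)."""

    table: pd.DataFrame  # columns: gtv_name, source, margin_mm, metric, value, vmin, vmax

    def row(self, gtv_name: str, source: str, margin_mm: float, metric: str) -> pd.Series:
        t = self.table
        sel = (
            (t.gtv_name == gtv_name)
            & (t.source == source)
            & (t.margin_mm == margin_mm)
            & (t.metric == metric)
        )
        match = t[sel]
        if len(match) != 1:
            raise KeyError(f"no unique summary row for {(gtv_name, source, margin_mm, metric)}")
        return match.iloc[0]


def summarize_cohort(records: list[OverlapRecord]) -> CohortSummary:
    """Aggregate per-patient overlap records into the cohort summary table."""
    if not records:
        raise ValueError("summarize_cohort requires at least one record")
    frame = records_to_frame(records)
    dup_keys = ["patient_id", "gtv_name", "source", "margin_mm", "observer"]
    if frame.duplicated(subset=dup_keys).any():
        dups = frame[frame.duplicated(subset=dup_keys, keep=False)]
        raise ValueError(f"duplicate overlap records:\n{dups[dup_keys].drop_duplicates()}")

    rows = []
    staple = frame[frame.source == "staple"]
    for (gtv, margin), g in staple.groupby(["gtv_name", "margin_mm"], sort=False):
        for metric in _METRICS:
            v = g[metric].to_numpy()
            rows.append(
                dict(
                    gtv_name=gtv,
                    source="staple",
                    margin_mm=margin,
                    metric=metric,
                    value=float(np.median(v)),
                    vmin=float(v.min()),
                    vmax=float(v.max()),
                )
            )
    individual = frame[frame.source == "individual"]
    for (gtv, margin), g in individual.groupby(["gtv_name", "margin_mm"], sort=False):
        for metric in _METRICS:
            medians = g.groupby("observer")[metric].median().to_numpy()
            rows.append(
                dict(
                    gtv_name=gtv,
                    source="individual",
                    margin_mm=margin,
                    metric=metric,
                    value=float(medians.mean()),
                    vmin=float(medians.min()),
                    vmax=float(medians.max()),
                )
            )
    return CohortSummary(table=pd.DataFrame(rows))


def write_summary_table(summary: CohortSummary, path: str) -> str:
    """Write the summary as CSV with both formatted and raw numeric columns."""
    t = summary.table.copy()
    if len(t):
        t["formatted"] = [
            f"{r.value:.2f} ({r.vmin:.2f}, {r.vmax:.2f})" for r in t.itertuples(index=False)
        ]
    else:
        t["formatted"] = pd.Series(dtype=str)
    t.to_csv(path, index=False)
    return str(path)


def plot_metric_distribution(records: list[OverlapRecord], metric: str, path: str) -> str:
    """Box plots of a metric's patient distribution per GTV definition and margin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = records_to_frame(records)
    staple = frame[frame.source == "staple"]
    gtvs = list(dict.fromkeys(staple.gtv_name))
    margins = sorted(staple.margin_mm.unique())
    fig, axes = plt.subplots(1, len(margins), figsize=(4 * len(margins), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, margin in zip(axes, margins):
        data = [
            staple[(staple.gtv_name == g) & (staple.margin_mm == margin)][metric].to_numpy()
            for g in gtvs
        ]
        ax.boxplot(data, tick_labels=gtvs, whis=(0, 100))
        ax.set_title(f"margin {margin:g} mm")
        ax.tick_params(axis="x", rotation=45)
    axes[0].set_ylabel(metric.upper() if metric == "dsc" else "lesion coverage")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
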