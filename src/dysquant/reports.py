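"""Cohort-level tables, figures and statistics reports.

Produces the study-style outputs: a group x antibody summary table of
``mean ± SE`` peak intensities pooled over ROIs, per-antibody violin plots
of the ROI intensity distributions, mean-spectrum overlays per group, a
manual-vs-automatic comparison boxplot, and a plain-text statistics report
(normality, omnibus and pairwise group tests, method equivalence).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import Spectrum
from .stats import compare_groups, compare_methods, normality_test

__all__ = [
    "group_summary_table",
    "stats_report",
    "violin_figure",
    "spectra_figure",
    "method_comparison_figure",
    "write_report",
]

GROUP_ORDER = ["DMD", "BMD", "CONTROL"]


def group_summary_table(roi_df: pd.DataFrame) -> pd.DataFrame:
    """Group x antibody table of pooled-ROI ``mean ± SE`` strings.

    `roi_df` is the long per-ROI table from `workflow.quantify_cohort`
    (columns group, antibody, value); the guide channel is excluded.
    """
    sub = roi_df[roi_df["antibody"] != "beta-spectrin"]
    rows = {}
    for g in [g for g in GROUP_ORDER if g in set(sub["group"])]:
        row = {}
        for ab in sorted(sub["antibody"].unique()):
            v = sub[(sub["group"] == g) & (sub["antibody"] == ab)]["value"].to_numpy()
            if v.size == 0:
                continue
            se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
            row[ab] = f"{v.mean():.1f} ± {se:.1f}"
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def stats_report(
    roi_df: pd.DataFrame,
    manual_summary: pd.DataFrame | None = None,
    auto_summary: pd.DataFrame | None = None,
) -> str:
    """Human-readable statistics report over a quantified cohort.

    Per antibody: Shapiro-Wilk normality per group (subsampled to the test's
    n <= 5000 bound if needed), Kruskal-Wallis omnibus, pairwise rank-sum
    tests.  When both manual- and auto-mode biopsy summaries are given, a
    pooled-variance t-test section compares the two methodologies.
    """
    lines = []
    sub = roi_df[roi_df["antibody"] != "beta-spectrin"]
    for ab in sorted(sub["antibody"].unique()):
        lines.append(f"== {ab} ==")
        by_group = {
            g: d["value"].to_numpy()
            for g, d in sub[sub["antibody"] == ab].groupby("group")
        }
        for g, v in sorted(by_group.items()):
            try:
                p = normality_test(v[:5000])
                lines.append(f"  Shapiro-Wilk {g}: n={v.size}, p={p:.3g}")
            except ValueError as exc:
                lines.append(f"  Shapiro-Wilk {g}: not testable ({exc})")
        if len(by_group) >= 2 and all(v.size >= 3 for v in by_group.values()):
            gc = compare_groups(by_group)
            lines.append(
                f"  Kruskal-Wallis: H={gc.omnibus_stat:.3f}, p={gc.omnibus_p:.3g}"
            )
            for a, b, u, p in gc.pairwise:
                lines.append(f"  rank-sum {a} vs {b}: U={u:.1f}, p={p:.3g}")
            for g, (m, se, n) in sorted(gc.group_summaries.items()):
                lines.append(f"  {g}: {m:.1f} ± {se:.1f} a.u. (n={n} ROIs)")
        else:
            lines.append("  group tests skipped: fewer than two testable groups")
    if manual_summary is not None and auto_summary is not None:
        lines.append("== manual vs automatic ==")
        for ab in sorted(set(manual_summary["antibody"]) & set(auto_summary["antibody"])):
            if ab == "beta-spectrin":
                continue
            m = manual_summary[manual_summary["antibody"] == ab]["mean_intensity"]
            a = auto_summary[auto_summary["antibody"] == ab]["mean_intensity"]
            mc = compare_methods(m.to_numpy(), a.to_numpy())
            lines.append(
                f"  {ab}: t={mc.t_stat:.3f}, p={mc.p:.3g}, "
                f"mean diff={mc.mean_difference:.1f} a.u. "
                f"(n={mc.n_manual} vs {mc.n_auto} biopsies)"
            )
    return "\n".join(lines) + "\n"


def violin_figure(roi_df: pd.DataFrame, antibody: str, path: str | Path) -> Path:
    """Violin plot of per-ROI peak intensities by diagnostic group."""
    sub = roi_df[roi_df["antibody"] == antibody]
    groups = [g for g in GROUP_ORDER if g in set(sub["group"])]
    data = [sub[sub["group"] == g]["value"].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel("peak intensity (a.u.)")
    ax.set_title(f"{antibody} per-ROI intensity by group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def spectra_figure(
    spectra_by_group: Mapping[str, Spectrum], path: str | Path, title: str = "mean ROI spectrum"
) -> Path:
    """Overlay of mean ROI spectra, one curve per diagnostic group."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    styles = {"DMD": ":", "BMD": "-", "CONTROL": "--"}
    for g, spec in spectra_by_group.items():
        ax.plot(spec.axis.centers_nm, spec.values, styles.get(g, "-"), label=g)
    ax.set_xlabel("emission wavelength (nm)")
    ax.set_ylabel("mean intensity (a.u.)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def method_comparison_figure(
    manual_summary: pd.DataFrame, auto_summary: pd.DataFrame, antibody: str, path: str | Path
) -> Path:
    """Boxplots of per-biopsy means, manual vs automatic ROI placement."""
    m = manual_summary[manual_summary["antibody"] == antibody]["mean_intensity"].to_numpy()
    a = auto_summary[auto_summary["antibody"] == antibody]["mean_intensity"].to_numpy()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([m, a], tick_labels=["manual", "automatic"])
    ax.set_ylabel("biopsy mean peak intensity (a.u.)")
    ax.set_title(antibody)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_report(
    roi_df: pd.DataFrame,
    summary_df: pd.DataFrame,
    out_dir: str | Path,
    manual_summary: pd.DataFrame | None = None,
) -> Path:
    """Emit the full report bundle into `out_dir`.

    Writes ``group_summary.csv`` (table-shaped mean ± SE), ``stats.txt``,
    one violin figure per antibody, and — when a manual-mode summary is
    supplied — per-antibody method-comparison boxplots.  Degrades gracefully
    (single-biopsy inputs skip group tests with a note in ``stats.txt``).
    """
    if roi_df.empty:
        raise ValueError("empty results: nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    group_summary_table(roi_df).to_csv(out / "group_summary.csv")
    summary_df.to_csv(out / "biopsy_summary.csv", index=False)
    (out / "stats.txt").write_text(stats_report(roi_df, manual_summary, summary_df))
    for ab in sorted(set(roi_df["antibody"]) - {"beta-spectrin"}):
        violin_figure(roi_df, ab, out / f"violin_{ab}.png")
        if manual_summary is not None:
            method_comparison_figure(
                manual_summary, summary_df, ab, out / f"methods_{ab}.png"
            )
    return out
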