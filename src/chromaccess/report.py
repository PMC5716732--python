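"""Descriptive report rendering: breakdown figures and a text summary.

Figures are descriptive only — no call in the pipeline depends on them.
The clustered heatmap uses agglomerative clustering with Euclidean
distance and average linkage over the most variable probes.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from .events import group_by_timecourse, select_most_variable_probes

__all__ = ["render_report"]

N_HEATMAP_PROBES = 500


def render_report(state: dict, outdir: Path, config) -> list[Path]:
    """Write summary tables and figures for the stages that have run."""
    outdir = Path(outdir)
    outputs: list[Path] = []
    events = state.get("events")
    lines = ["# Run summary", ""]

    if events is None or not len(events):
        lines.append("No events detected (empty event table).")
    else:
        counts = events.records["event_type"].value_counts().to_dict()
        lines.append("Event counts: " + json.dumps(counts, sort_keys=True))

        groups = group_by_timecourse(events)
        lines.append("")
        lines.append("Time-course groups (accessibility changes):")
        group_rows = []
        for (tp, direction), members in sorted(groups.items()):
            lines.append(f"- day {tp}, {direction}: {len(members)} probes")
            group_rows.append({"timepoint_days": tp, "direction": direction, "n": len(members)})
        groups_path = outdir / "timecourse_groups.tsv"
        pd.DataFrame(group_rows).to_csv(groups_path, sep="\t", index=False)
        outputs.append(groups_path)

    breakdown = state.get("breakdown")
    if breakdown is not None:
        fig, ax = plt.subplots(figsize=(7, 4))
        breakdown.table.plot.bar(ax=ax)
        ax.set_ylabel("events")
        ax.set_title("Change events by genomic region")
        fig.tight_layout()
        p = outdir / "events_by_region.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        outputs.append(p)

        fracs = breakdown.tss_island_fractions.dropna()
        if fracs.sum() > 0:
            fig, ax = plt.subplots(figsize=(4, 4))
            positive = fracs[fracs > 0]
            ax.pie(positive, labels=positive.index, autopct="%1.0f%%")
            ax.set_title("TSS methylation changes by island status")
            fig.tight_layout()
            p = outdir / "tss_island_status.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            outputs.append(p)

    joint = state.get("joint")
    if joint is not None and len(joint):
        sample = joint.sample(min(len(joint), 20_000), random_state=0)
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(sample["delta_meth"], sample["delta_access"], s=2, alpha=0.2)
        thr = config.thresholds
        for x in (-thr.meth_change_delta, thr.meth_change_delta):
            ax.axvline(x, color="grey", lw=0.8)
        for y in (-thr.access_change_delta, thr.access_change_delta):
            ax.axhline(y, color="grey", lw=0.8)
        ax.set_xlabel("delta methylation (induced - control)")
        ax.set_ylabel("delta accessibility (induced - control)")
        fig.tight_layout()
        p = outdir / "joint_scatter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        outputs.append(p)

    acc_sim = state.get("acc_sim")
    if acc_sim is not None:
        bm = acc_sim.beta
        top = select_most_variable_probes(bm, min(N_HEATMAP_PROBES, len(bm.probe_ids)))
        sub = bm.values.loc[top].dropna(how="any")
        if len(sub) >= 2:
            cg = sns.clustermap(
                sub,
                method="average",
                metric="euclidean",
                cmap="vlag",
                figsize=(8, 8),
                xticklabels=True,
                yticklabels=False,
            )
            p = outdir / "variable_probe_heatmap.png"
            cg.savefig(p, dpi=120)
            plt.close(cg.fig)
            outputs.append(p)

    screen = state.get("screen")
    if screen is not None:
        lines.append("")
        lines.append(
            f"Driver candidates: {len(screen.decreased_down)} closed/down, "
            f"{len(screen.increased_up)} opened/up, {len(screen.discordant)} discordant."
        )
    refine = state.get("refine")
    if refine is not None:
        d, u = refine.overlap_counts
        lines.append(
            f"Knockdown x signature overlap: {d} down, {u} up; "
            f"{len(refine.refined)} refined mediators after the p-filter."
        )

    summary_path = outdir / "summary.md"
    summary_path.write_text("\n".join(lines) + "\n")
    outputs.append(summary_path)
    return outputs
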