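"""Genomic-context classification of probes and event breakdowns.

Probes are binned into TSS, gene body, other gene-related (5'UTR / first
exon) and gene-desert categories, and TSS probes further by CpG-island
status (island, island-related = shore/shelf, non-island).  The breakdown
tables mirror the region- and island-wise event summaries of the analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EventTable, FeatureGroup, IslandRelation, ProbeAnnotation

__all__ = [
    "RegionCategory",
    "IslandCategory",
    "classify_probe_region",
    "classify_island",
    "RegionBreakdown",
    "tabulate_events_by_region",
]


class RegionCategory(str, enum.Enum):
    TSS = "TSS"
    BODY = "BODY"
    OTHER_GENE_RELATED = "OTHER_GENE_RELATED"
    GENE_DESERT = "GENE_DESERT"


class IslandCategory(str, enum.Enum):
    ISLAND = "ISLAND"
    ISLAND_RELATED = "ISLAND_RELATED"
    NON_ISLAND = "NON_ISLAND"


_TSS_GROUPS = {FeatureGroup.TSS200, FeatureGroup.TSS1500}
_BODY_GROUPS = {FeatureGroup.BODY, FeatureGroup.UTR3}
_OTHER_GROUPS = {FeatureGroup.UTR5, FeatureGroup.EXON1}

UNANNOTATED = "UNANNOTATED"


def classify_probe_region(ann: ProbeAnnotation) -> RegionCategory:
    """Single region call per probe; TSS wins over any other group.

    Precedence TSS > BODY/3'UTR > 5'UTR/first-exon resolves multi-gene
    probes carrying conflicting feature groups; probes with no gene are
    gene desert.
    """
    if not ann.genes:
        return RegionCategory.GENE_DESERT
    groups = set(ann.feature_groups)
    if groups & _TSS_GROUPS:
        return RegionCategory.TSS
    if groups & _BODY_GROUPS:
        return RegionCategory.BODY
    if groups & _OTHER_GROUPS:
        return RegionCategory.OTHER_GENE_RELATED
    # annotated to a gene but with no recognised feature group
    return RegionCategory.OTHER_GENE_RELATED


def classify_island(ann: ProbeAnnotation) -> IslandCategory:
    """Island status: shores and shelves collapse to island-related."""
    if ann.island_relation is IslandRelation.ISLAND:
        return IslandCategory.ISLAND
    if ann.island_relation in (IslandRelation.SHORE, IslandRelation.SHELF):
        return IslandCategory.ISLAND_RELATED
    return IslandCategory.NON_ISLAND


@dataclass
class RegionBreakdown:
    """Event-type x region contingency table with derived summaries.

    ``table`` rows are event types and columns region categories plus an
    UNANNOTATED column.  ``tss_loss_to_gain_ratio`` is the ratio of TSS
    demethylation to TSS methylation-gain events (NaN when the denominator
    is zero).  ``tss_island_fractions`` is the fraction of TSS
    methylation-change probes per island category (sums to 1 when any
    exist).
    """

    table: pd.DataFrame
    tss_loss_to_gain_ratio: float
    body_gain_count: int
    body_loss_count: int
    tss_island_fractions: pd.Series

    @property
    def non_island_fraction(self) -> float:
        return float(self.tss_island_fractions.get(IslandCategory.NON_ISLAND.value, np.nan))

    def summary(self) -> dict:
        return {
            "tss_loss_to_gain_ratio": None
            if np.isnan(self.tss_loss_to_gain_ratio)
            else self.tss_loss_to_gain_ratio,
            "body_gain_count": self.body_gain_count,
            "body_loss_count": self.body_loss_count,
            "tss_island_fractions": {
                k: (None if np.isnan(v) else float(v))
                for k, v in self.tss_island_fractions.items()
            },
        }


def tabulate_events_by_region(
    events: EventTable,
    annotations: Sequence[ProbeAnnotation],
) -> RegionBreakdown:
    """Cross-tabulate events by genomic region and derive summaries.

    Events whose probe is absent from the annotation are counted in an
    UNANNOTATED column rather than dropped, so row sums stay equal to the
    total event counts.
    """
    ann_by_probe = {a.probe_id: a for a in annotations}
    region_cols = [c.value for c in RegionCategory] + [UNANNOTATED]
    event_rows = ["METH_GAIN", "METH_LOSS", "ACCESS_GAIN", "ACCESS_LOSS"]
    table = pd.DataFrame(0, index=event_rows, columns=region_cols)

    island_counts = {c.value: 0 for c in IslandCategory}
    island_counts[UNANNOTATED] = 0

    for _, row in events.records.iterrows():
        ann = ann_by_probe.get(row["probe_id"])
        col = classify_probe_region(ann).value if ann is not None else UNANNOTATED
        table.loc[row["event_type"], col] += 1
        if row["event_type"] in ("METH_GAIN", "METH_LOSS"):
            if ann is not None and classify_probe_region(ann) is RegionCategory.TSS:
                island_counts[classify_island(ann).value] += 1

    tss_gain = table.loc["METH_GAIN", RegionCategory.TSS.value]
    tss_loss = table.loc["METH_LOSS", RegionCategory.TSS.value]
    ratio = float(tss_loss) / float(tss_gain) if tss_gain > 0 else float("nan")

    total_tss_meth = sum(island_counts.values())
    fractions = pd.Series(
        {
            k: (island_counts[k] / total_tss_meth if total_tss_meth else float("nan"))
            for k in island_counts
        }
    )
    return RegionBreakdown(
        table=table,
        tss_loss_to_gain_ratio=ratio,
        body_gain_count=int(table.loc["METH_GAIN", RegionCategory.BODY.value]),
        body_loss_count=int(table.loc["METH_LOSS", RegionCategory.BODY.value]),
        tss_island_fractions=fractions,
    )
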