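"""Tabular input/output and validated domain containers.

The pipeline starts from beta-value matrices as exported from methylation
array platforms (probes x samples, values in [0, 1], missing allowed), a
450K-style probe manifest, and plain one-symbol-per-line gene sets.  This
module parses those formats into validated domain types and writes event
tables back out as TSV or BED.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "Condition",
    "FeatureGroup",
    "IslandRelation",
    "SampleMeta",
    "BetaMatrix",
    "ProbeAnnotation",
    "GeneSet",
    "EventTable",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_gene_set",
    "write_event_table",
    "read_event_table",
]


class Arm(str, enum.Enum):
    """Assay arm: chromatin treated with the CpG methyltransferase, or mock."""

    SSSI = "SSSI"
    NO_ENZYME = "NO_ENZYME"


class Condition(str, enum.Enum):
    INDUCED = "INDUCED"
    CONTROL = "CONTROL"


class FeatureGroup(str, enum.Enum):
    TSS200 = "TSS200"
    TSS1500 = "TSS1500"
    UTR5 = "UTR5"
    EXON1 = "EXON1"
    BODY = "BODY"
    UTR3 = "UTR3"


class IslandRelation(str, enum.Enum):
    ISLAND = "ISLAND"
    SHORE = "SHORE"
    SHELF = "SHELF"
    OPEN_SEA = "OPEN_SEA"


#: Manifest tokens collapse to one island-relation category (N/S distinction
#: is dropped); unrecognised tokens raise.
_ISLAND_TOKEN_MAP = {
    "ISLAND": IslandRelation.ISLAND,
    "N_SHORE": IslandRelation.SHORE,
    "S_SHORE": IslandRelation.SHORE,
    "SHORE": IslandRelation.SHORE,
    "N_SHELF": IslandRelation.SHELF,
    "S_SHELF": IslandRelation.SHELF,
    "SHELF": IslandRelation.SHELF,
    "": IslandRelation.OPEN_SEA,
    "OPENSEA": IslandRelation.OPEN_SEA,
    "OPEN_SEA": IslandRelation.OPEN_SEA,
}

_FEATURE_TOKEN_MAP = {
    "TSS200": FeatureGroup.TSS200,
    "TSS1500": FeatureGroup.TSS1500,
    "5'UTR": FeatureGroup.UTR5,
    "UTR5": FeatureGroup.UTR5,
    "1STEXON": FeatureGroup.EXON1,
    "EXON1": FeatureGroup.EXON1,
    "BODY": FeatureGroup.BODY,
    "3'UTR": FeatureGroup.UTR3,
    "UTR3": FeatureGroup.UTR3,
}


def collapse_island_token(token: str) -> IslandRelation:
    """Map a manifest island-relation token to its category.

    Total on the known vocabulary; anything else raises ``ValueError``.
    """
    key = token.strip().upper()
    try:
        return _ISLAND_TOKEN_MAP[key]
    except KeyError:
        raise ValueError(f"unknown island-relation token: {token!r}") from None


def _parse_feature_token(token: str) -> FeatureGroup:
    key = token.strip().upper()
    try:
        return _FEATURE_TOKEN_MAP[key]
    except KeyError:
        raise ValueError(f"unknown gene-feature-group token: {token!r}") from None


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one array sample (one column of a beta matrix)."""

    label: str
    arm: Arm
    condition: Condition
    timepoint_days: int

    def __post_init__(self) -> None:
        if self.timepoint_days <= 0:
            raise ValueError(f"timepoint_days must be positive, got {self.timepoint_days}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values (fraction methylated, in [0,1]).

    ``values`` is indexed by probe id with one column per sample label;
    missing entries are NaN.  ``samples`` carries the assay arm, condition
    and time point of each column.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate sample labels")
        if list(self.values.columns) != labels:
            raise ValueError("sample-sheet labels do not match matrix columns")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def sample_labels(
        self,
        arm: Arm | None = None,
        condition: Condition | None = None,
        timepoint_days: int | None = None,
    ) -> list[str]:
        out = []
        for s in self.samples:
            if arm is not None and s.arm != arm:
                continue
            if condition is not None and s.condition != condition:
                continue
            if timepoint_days is not None and s.timepoint_days != timepoint_days:
                continue
            out.append(s.label)
        return out

    def arm_mean(self, arm: Arm, condition: Condition, timepoint_days: int) -> pd.Series:
        """Per-probe beta for one (arm, condition, timepoint) cell.

        Replicate columns are averaged over non-missing entries before any
        downstream delta is formed.
        """
        labels = self.sample_labels(arm, condition, timepoint_days)
        if not labels:
            raise KeyError(
                f"no sample with arm={arm.value}, condition={condition.value}, "
                f"day {timepoint_days}"
            )
        return self.values[labels].mean(axis=1, skipna=True)

    def timepoints(self) -> list[int]:
        return sorted({s.timepoint_days for s in self.samples})


@dataclass(frozen=True)
class ProbeAnnotation:
    """One manifest row: where a probe sits in the genome and gene model."""

    probe_id: str
    chrom: str
    pos: int  # 1-based
    strand: str = "unknown"
    genes: tuple[str, ...] = ()
    feature_groups: tuple[FeatureGroup, ...] = ()
    island_relation: IslandRelation = IslandRelation.OPEN_SEA

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1, got {self.pos}")
        if len(self.genes) != len(self.feature_groups):
            raise ValueError(
                f"probe {self.probe_id}: genes ({len(self.genes)}) and feature groups "
                f"({len(self.feature_groups)}) have different arity"
            )


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols, upper-cased and de-duplicated."""

    name: str
    symbols: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        cleaned = frozenset(s.strip().upper() for s in symbols if s.strip())
        return cls(name=name, symbols=cleaned)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols


EVENT_TYPES = ("METH_GAIN", "METH_LOSS", "ACCESS_GAIN", "ACCESS_LOSS")

_EVENT_COLUMNS = ["probe_id", "gene", "timepoint_days", "event_type", "delta"]


@dataclass
class EventTable:
    """Per-probe methylation / accessibility change events.

    One row per (probe, timepoint, event type); ``delta`` is the signed
    change whose magnitude exceeded the governing threshold.  ``gene`` is
    optional annotation (empty string when unannotated).
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_EVENT_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = self.records
        if df.empty:
            df = pd.DataFrame(columns=_EVENT_COLUMNS)
        if "gene" not in df.columns:
            df = df.assign(gene="")
        df = df[_EVENT_COLUMNS].copy()
        df["gene"] = df["gene"].fillna("")
        if len(df):
            unknown = set(df["event_type"]) - set(EVENT_TYPES)
            if unknown:
                raise ValueError(f"unknown event types: {sorted(unknown)}")
            df["timepoint_days"] = df["timepoint_days"].astype(int)
            df["delta"] = df["delta"].astype(float)
            meth = df[df["event_type"].str.startswith("METH")]
            acc = df[df["event_type"].str.startswith("ACCESS")]
            for sub, what in ((meth, "methylation"), (acc, "accessibility")):
                if sub.duplicated(subset=["probe_id", "timepoint_days"]).any():
                    raise ValueError(f"more than one {what} event per (probe, timepoint)")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def of_type(self, *event_types: str) -> pd.DataFrame:
        return self.records[self.records["event_type"].isin(event_types)]

    def probes(self) -> set[str]:
        return set(self.records["probe_id"])

    @classmethod
    def concat(cls, tables: Sequence["EventTable"]) -> "EventTable":
        frames = [t.records for t in tables if len(t)]
        if not frames:
            return cls()
        return cls(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def read_beta_matrix(path: str | Path, sample_sheet: str | Path) -> BetaMatrix:
    """Read a delimited beta matrix plus its sample sheet.

    The matrix has probe ids in the first column and one column per sample;
    the sample sheet maps each column label to (arm, condition, timepoint).
    Blank or ``NA`` cells become missing; values outside [0, 1] are rejected
    naming the offending probe and sample.
    """
    raw = pd.read_csv(path, sep=None, engine="python", index_col=0)
    raw.index = raw.index.astype(str)
    sheet = _read_table(sample_sheet)
    required = {"label", "arm", "condition", "timepoint_days"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    samples = [
        SampleMeta(
            label=row["label"],
            arm=Arm(row["arm"].strip().upper()),
            condition=Condition(row["condition"].strip().upper()),
            timepoint_days=int(row["timepoint_days"]),
        )
        for _, row in sheet.iterrows()
    ]
    missing = [s.label for s in samples if s.label not in raw.columns]
    if missing:
        raise ValueError(f"sample-sheet labels absent from matrix: {missing}")
    values = raw[[s.label for s in samples]].astype(float)
    return BetaMatrix(values=values, samples=samples)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, sample_sheet: str | Path) -> None:
    bm.values.round(6).to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")
    pd.DataFrame(
        {
            "label": [s.label for s in bm.samples],
            "arm": [s.arm.value for s in bm.samples],
            "condition": [s.condition.value for s in bm.samples],
            "timepoint_days": [s.timepoint_days for s in bm.samples],
        }
    ).to_csv(sample_sheet, sep="\t", index=False)


def read_probe_manifest(path: str | Path) -> list[ProbeAnnotation]:
    """Read a 450K-style manifest into validated probe annotations.

    Expected columns: probe_id, chrom, pos, genes (semicolon-separated, may
    be empty), feature_groups (semicolon-separated, same arity as genes),
    island_relation (empty field means open sea).  Optional column: strand.
    """
    df = _read_table(path)
    required = {"probe_id", "chrom", "pos", "genes", "feature_groups", "island_relation"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    out: list[ProbeAnnotation] = []
    for _, row in df.iterrows():
        genes = tuple(g.strip().upper() for g in row["genes"].split(";") if g.strip())
        groups = tuple(
            _parse_feature_token(t) for t in row["feature_groups"].split(";") if t.strip()
        )
        out.append(
            ProbeAnnotation(
                probe_id=row["probe_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                strand=row.get("strand", "unknown") or "unknown",
                genes=genes,
                feature_groups=groups,
                island_relation=collapse_island_token(row["island_relation"]),
            )
        )
    return out


def write_probe_manifest(annotations: Sequence[ProbeAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in annotations],
            "chrom": [a.chrom for a in annotations],
            "pos": [a.pos for a in annotations],
            "strand": [a.strand for a in annotations],
            "genes": [";".join(a.genes) for a in annotations],
            "feature_groups": [";".join(g.value for g in a.feature_groups) for a in annotations],
            "island_relation": [a.island_relation.value for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a one-symbol-per-line (or single-column) gene set file."""
    lines = Path(path).read_text().splitlines()
    symbols = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if not symbols:
        raise ValueError(f"gene-set file {path} is empty")
    return GeneSet.from_symbols(name, symbols)


def write_event_table(
    events: EventTable,
    path: str | Path,
    format: str = "TSV",
    annotations: Sequence[ProbeAnnotation] | None = None,
) -> None:
    """Write events as TSV, or BED (0-based half-open width-1 intervals).

    BED requires annotations to supply coordinates; the BED name field is
    ``probe_id|event_type|d<timepoint>``.
    """
    fmt = format.upper()
    if fmt == "TSV":
        events.records.round({"delta": 6}).to_csv(path, sep="\t", index=False)
    elif fmt == "BED":
        if annotations is None:
            raise ValueError("BED output requires probe annotations for coordinates")
        ann = {a.probe_id: a for a in annotations}
        lines = []
        for _, row in events.records.iterrows():
            a = ann.get(row["probe_id"])
            if a is None:
                raise ValueError(f"no coordinates for probe {row['probe_id']!r}")
            name = f"{row['probe_id']}|{row['event_type'].lower()}|d{row['timepoint_days']}"
            lines.append(f"{a.chrom}\t{a.pos - 1}\t{a.pos}\t{name}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown event-table format: {format!r}")


def read_event_table(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str})
    if df.empty:
        return EventTable()
    return EventTable(df)
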