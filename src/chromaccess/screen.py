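"""Two-stage EMT driver-gene screens.

Stage one intersects genes with an early (day 2) TSS accessibility change
with a published core EMT expression signature, keeping only concordant
pairs (chromatin closing with downregulation, opening with upregulation).
Stage two re-screens the signature against knockdown differential
expression on the shared gene universe, split by direction and filtered at
p < 0.05, yielding the refined mediator list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .expression import DEResult, Direction
from .io import EventTable, GeneSet

__all__ = [
    "DriverCandidate",
    "ScreenResult",
    "RefinedMediator",
    "RefineResult",
    "screen_driver_candidates",
    "refine_mediators",
    "expected_table1_panel",
]


@dataclass(frozen=True)
class DriverCandidate:
    """Signature gene whose early chromatin change matches its expression."""

    gene: str
    accessibility_direction: str  # DECREASED (closed) or INCREASED (opened)
    expression_direction: Direction
    timepoint_days: int

    def __post_init__(self) -> None:
        concordant = (
            (self.accessibility_direction == "DECREASED" and self.expression_direction is Direction.DOWN)
            or (self.accessibility_direction == "INCREASED" and self.expression_direction is Direction.UP)
        )
        if not concordant:
            raise ValueError(
                f"{self.gene}: discordant pair {self.accessibility_direction}/"
                f"{self.expression_direction.value}"
            )


@dataclass
class ScreenResult:
    decreased_down: list[DriverCandidate] = field(default_factory=list)
    increased_up: list[DriverCandidate] = field(default_factory=list)
    discordant: list[str] = field(default_factory=list)

    @property
    def candidates(self) -> list[DriverCandidate]:
        return self.decreased_down + self.increased_up

    def genes(self) -> set[str]:
        return {c.gene for c in self.candidates}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [c.gene for c in self.candidates],
                "accessibility": [c.accessibility_direction for c in self.candidates],
                "expression": [c.expression_direction.value for c in self.candidates],
                "timepoint_days": [c.timepoint_days for c in self.candidates],
            }
        )


def _direction_map(de: "list[DEResult] | Mapping[str, Direction]") -> dict[str, Direction]:
    if isinstance(de, Mapping):
        return {g.upper(): Direction(d) for g, d in de.items()}
    return {r.gene.upper(): r.direction for r in de}


def screen_driver_candidates(
    access_events: EventTable,
    de: "list[DEResult] | Mapping[str, Direction]",
    signature: GeneSet,
    early_timepoint: int = 2,
) -> ScreenResult:
    """Early TSS accessibility change x expression direction x signature.

    ``access_events`` must already be gene-aggregated over TSS probes (the
    ``gene`` column set; any qualifying TSS probe calls the gene).  A gene
    is a candidate when it lost accessibility at the early timepoint and is
    downregulated, or gained accessibility and is upregulated, and belongs
    to the signature.  Discordant signature genes are reported separately.
    """
    if not len(signature):
        raise ValueError("signature gene set is empty")
    directions = _direction_map(de)

    recs = access_events.records
    early = recs[(recs["timepoint_days"] == early_timepoint) & (recs["gene"] != "")]
    lost = {g.upper() for g in early.loc[early["event_type"] == "ACCESS_LOSS", "gene"]}
    gained = {g.upper() for g in early.loc[early["event_type"] == "ACCESS_GAIN", "gene"]}

    result = ScreenResult()
    for gene in sorted(lost | gained):
        if gene not in signature or gene not in directions:
            continue
        d = directions[gene]
        if gene in lost and d is Direction.DOWN:
            result.decreased_down.append(
                DriverCandidate(gene, "DECREASED", Direction.DOWN, early_timepoint)
            )
        elif gene in gained and d is Direction.UP:
            result.increased_up.append(
                DriverCandidate(gene, "INCREASED", Direction.UP, early_timepoint)
            )
        else:
            result.discordant.append(gene)
    return result


@dataclass(frozen=True)
class RefinedMediator:
    gene: str
    direction: Direction
    p_value: float

    def __post_init__(self) -> None:
        if not self.p_value < 0.05:
            raise ValueError(f"{self.gene}: refined mediators require p < 0.05")


@dataclass
class RefineResult:
    """Direction-wise signature/knockdown overlap and its p-filtered core."""

    overlap_down: list[str]
    overlap_up: list[str]
    refined: list[RefinedMediator]

    @property
    def overlap_counts(self) -> tuple[int, int]:
        return (len(self.overlap_down), len(self.overlap_up))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [m.gene for m in self.refined],
                "direction": [m.direction.value for m in self.refined],
                "p_value": [m.p_value for m in self.refined],
            }
        )


def refine_mediators(
    kd_de: list[DEResult],
    signature_directions: Mapping[str, Direction],
    alpha: float = 0.05,
    fc_cutoff: float = 1.5,
) -> RefineResult:
    """Knockdown DE x signature, same direction, then p < alpha.

    ``kd_de`` must already be harmonized to the shared platform universe.
    The overlap is between the knockdown-affected genes (fold change >=
    ``fc_cutoff``) and signature genes of the same direction, reported
    before the p-filter; the refined list keeps overlap genes with
    p < alpha.  Signature genes with no stated direction are skipped with
    a warning.
    """
    sig_dir: dict[str, Direction] = {}
    for g, d in signature_directions.items():
        if d is None:
            warnings.warn(f"signature gene {g} has no direction; skipped", stacklevel=2)
            continue
        sig_dir[g.upper()] = Direction(d)

    overlap_down, overlap_up, refined = [], [], []
    for r in sorted(kd_de, key=lambda r: r.gene):
        gene = r.gene.upper()
        if r.fold_change < fc_cutoff:
            continue
        if gene not in sig_dir or sig_dir[gene] is not r.direction:
            continue
        (overlap_down if r.direction is Direction.DOWN else overlap_up).append(gene)
        if r.p_value < alpha:
            refined.append(RefinedMediator(gene, r.direction, r.p_value))
    return RefineResult(overlap_down=overlap_down, overlap_up=overlap_up, refined=refined)


#: Regression panel of published driver candidates for accession runs:
#: 14 genes closing with downregulation and 4 opening with upregulation at
#: day 2 of TWIST-induced EMT.
_PANEL_DECREASED_DOWN = (
    "KRT5", "IRF6", "MAP7", "PTPN3", "SNCA", "MST1R", "CYP27B1",
    "EPHA1", "CYP4F11", "GNAL", "DDR1", "IL1RN", "WWC1", "TRIM29",
)
_PANEL_INCREASED_UP = ("FADS1", "RGS4", "ACP1", "VIM")


def expected_table1_panel() -> dict[str, tuple[str, ...]]:
    """Packaged ground-truth driver-candidate panel (regression fixture)."""
    return {
        "decreased_down": _PANEL_DECREASED_DOWN,
        "increased_up": _PANEL_INCREASED_UP,
    }
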