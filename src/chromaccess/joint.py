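"""Joint classification of methylation and accessibility changes.

Each probe's (delta-methylation, delta-accessibility) pair — both computed
as treated minus control — falls in one of six regions of the plane, a-f,
separating methylation-dependent chromatin changes (a: demethylation with
opening, d: methylation gain with closing) from methylation-independent
ones (e: opening, f: closing without a methylation change) and from
methylation changes without any chromatin change (b, c), which are
passenger candidates.  The letter-to-quadrant mapping is configurable; the
default is the canonical demethylation<->opening pairing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .events import Thresholds
from .io import ProbeAnnotation

__all__ = [
    "Region",
    "Dependence",
    "JointClass",
    "DEFAULT_REGION_MAP",
    "classify_joint",
    "classify_joint_table",
    "functional_change_catalog",
]


class Region(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    NONE = "NONE"


class Dependence(str, enum.Enum):
    METH_DEPENDENT = "METH_DEPENDENT"
    METH_ONLY = "METH_ONLY"
    METH_INDEPENDENT = "METH_INDEPENDENT"
    NONE = "NONE"


_DEPENDENCE_OF_REGION = {
    Region.A: Dependence.METH_DEPENDENT,
    Region.D: Dependence.METH_DEPENDENT,
    Region.B: Dependence.METH_ONLY,
    Region.C: Dependence.METH_ONLY,
    Region.E: Dependence.METH_INDEPENDENT,
    Region.F: Dependence.METH_INDEPENDENT,
    Region.NONE: Dependence.NONE,
}


@dataclass(frozen=True)
class JointClass:
    region: Region
    dependence: Dependence

    def __post_init__(self) -> None:
        if _DEPENDENCE_OF_REGION[self.region] is not self.dependence:
            raise ValueError(f"dependence {self.dependence} inconsistent with region {self.region}")


# cells of the 3x3 plane partition: (meth axis, access axis) with each axis
# in {-1: loss/closing, 0: no change, +1: gain/opening}
_Cell = tuple[int, int]

#: Default letter layout: a = demethylation+opening, d = methylation+closing,
#: b/c = methylation change only, e/f = accessibility change only.  The two
#: discordant corners and the centre are unassigned (NONE).
DEFAULT_REGION_MAP: dict[_Cell, Region] = {
    (-1, +1): Region.A,
    (+1, -1): Region.D,
    (+1, 0): Region.B,
    (-1, 0): Region.C,
    (0, +1): Region.E,
    (0, -1): Region.F,
}


def _axis_sign(value: float, cutoff: float) -> int:
    """-1 / 0 / +1 partition of one axis with closed outer half-lines."""
    if value >= cutoff:
        return 1
    if value <= -cutoff:
        return -1
    return 0


def classify_joint(
    delta_meth: float,
    delta_access: float,
    thr: Thresholds | None = None,
    region_map: Mapping[_Cell, Region] | None = None,
) -> JointClass:
    """Assign one (delta-meth, delta-access) pair to a region a-f.

    The methylation axis splits at +/-0.2 and the accessibility axis at
    +/-0.3 (the change-event cutoffs, boundary values inclusive); cells not
    present in ``region_map`` — by default the centre and the two
    discordant corners — map to NONE.
    """
    thr = thr or Thresholds()
    region_map = region_map or DEFAULT_REGION_MAP
    cell = (
        _axis_sign(float(delta_meth), thr.meth_change_delta),
        _axis_sign(float(delta_access), thr.access_change_delta),
    )
    region = region_map.get(cell, Region.NONE)
    return JointClass(region=region, dependence=_DEPENDENCE_OF_REGION[region])


def classify_joint_table(
    deltas: pd.DataFrame,
    thr: Thresholds | None = None,
    region_map: Mapping[_Cell, Region] | None = None,
) -> pd.DataFrame:
    """Vectorised classification of a frame with delta_meth / delta_access.

    Returns the input plus ``region`` and ``dependence`` columns; rows with
    a missing delta are dropped (missing propagates, never imputed).
    """
    required = {"delta_meth", "delta_access"}
    if not required.issubset(deltas.columns):
        raise ValueError(f"need columns {sorted(required)}")
    out = deltas.dropna(subset=["delta_meth", "delta_access"]).copy()
    classes = [
        classify_joint(m, a, thr, region_map)
        for m, a in zip(out["delta_meth"], out["delta_access"])
    ]
    out["region"] = [c.region.value for c in classes]
    out["dependence"] = [c.dependence.value for c in classes]
    return out


_FUNCTIONAL_REGIONS = {Region.A, Region.D, Region.E, Region.F}
#: Per-gene precedence: any functional TSS probe outranks passenger-only.
_REGION_PRIORITY = [Region.A, Region.D, Region.E, Region.F, Region.B, Region.C]


def functional_change_catalog(
    joint: pd.DataFrame,
    annotations: Sequence[ProbeAnnotation],
    tss_only: bool = True,
) -> pd.DataFrame:
    """Aggregate per-probe joint classes to per-gene functional calls.

    A gene is "functional" when any of its TSS probes falls in a region
    with a chromatin-accessibility change (a, d, e, f); genes whose probes
    sit only in b/c are flagged passenger candidates.  ``joint`` needs
    columns probe_id, region and (optionally) timepoint_days.

    Returns a frame with gene, call ∈ {functional, passenger_candidate},
    dependence, region and earliest qualifying timepoint.
    """
    from .context import RegionCategory, classify_probe_region

    ann_by_probe = {a.probe_id: a for a in annotations}
    rows = []
    for _, row in joint.iterrows():
        region = Region(row["region"])
        if region is Region.NONE:
            continue
        ann = ann_by_probe.get(row["probe_id"])
        if ann is None:
            continue
        if tss_only and classify_probe_region(ann) is not RegionCategory.TSS:
            continue
        tp = int(row["timepoint_days"]) if "timepoint_days" in row else 0
        for gene in set(ann.genes):
            rows.append({"gene": gene, "region": region, "timepoint_days": tp})
    if not rows:
        return pd.DataFrame(columns=["gene", "call", "dependence", "region", "timepoint_days"])

    df = pd.DataFrame(rows)
    priority = {r: i for i, r in enumerate(_REGION_PRIORITY)}
    out = []
    for gene, sub in df.groupby("gene"):
        best = min(sub["region"], key=lambda r: priority[r])
        qualifying = sub[sub["region"] == best]
        out.append(
            {
                "gene": gene,
                "call": "functional" if best in _FUNCTIONAL_REGIONS else "passenger_candidate",
                "dependence": _DEPENDENCE_OF_REGION[best].value,
                "region": best.value,
                "timepoint_days": int(qualifying["timepoint_days"].min()),
            }
        )
    return pd.DataFrame(out).sort_values("gene").reset_index(drop=True)
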