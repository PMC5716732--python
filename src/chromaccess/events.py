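"""Accessibility scale, methylation-state calls, and change-event detection.

Chromatin accessibility is read out as the beta-value difference between
the methyltransferase-treated arm and the no-enzyme control (delta-beta on
a 0-1 scale); probes with a negative raw difference are removed rather than
clipped.  Change events over the induction time course are called against
fixed delta-beta cutoffs: 0.2 for methylation changes and 0.3 for
accessibility changes, both strict.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Arm, BetaMatrix, Condition, EventTable

__all__ = [
    "Thresholds",
    "MethState",
    "DetectionMode",
    "AccessibilityMatrix",
    "compute_accessibility",
    "accessibility_from_beta",
    "call_accessible",
    "call_methylation_state",
    "detect_methylation_changes",
    "detect_accessibility_changes",
    "group_by_timecourse",
    "select_most_variable_probes",
]


@dataclass(frozen=True)
class Thresholds:
    """Fixed beta / delta-beta cutoffs.

    meth_high / meth_low
        Methylation-state call boundaries: beta > 0.7 methylated,
        beta < 0.3 unmethylated, in between partially methylated.
    accessible_delta
        A probe is accessible when its (treated - control) delta-beta
        exceeds 0.2 (strict; cutoff fixed by prior ROC calibration).
    meth_change_delta / access_change_delta
        Minimum |delta-beta| for a methylation (0.2) or accessibility (0.3)
        change event between induced and control.
    """

    meth_high: float = 0.7
    meth_low: float = 0.3
    accessible_delta: float = 0.2
    meth_change_delta: float = 0.2
    access_change_delta: float = 0.3

    def __post_init__(self) -> None:
        for name in ("meth_high", "meth_low", "accessible_delta",
                     "meth_change_delta", "access_change_delta"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.meth_low >= self.meth_high:
            raise ValueError("meth_low must be below meth_high")


class MethState(str, enum.Enum):
    METHYLATED = "METHYLATED"
    UNMETHYLATED = "UNMETHYLATED"
    PARTIAL = "PARTIAL"


class DetectionMode(str, enum.Enum):
    PER_TIMEPOINT = "PER_TIMEPOINT"
    ANY_TIMEPOINT = "ANY_TIMEPOINT"


FLAG_OK = "OK"
FLAG_REMOVED_NEGATIVE = "REMOVED_NEGATIVE"
FLAG_MISSING_INPUT = "MISSING_INPUT"


@dataclass
class AccessibilityMatrix:
    """Per-probe accessibility (delta-beta) per (condition, timepoint).

    ``values`` columns are a MultiIndex (condition value, timepoint_days);
    entries are NaN where the input was missing or the raw delta-beta was
    negative, with the reason in ``flags``.
    """

    values: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("retained accessibility values must lie in [0,1]")
        removed = (self.flags == FLAG_REMOVED_NEGATIVE).to_numpy()
        if np.any(removed & ~np.isnan(vals)):
            raise ValueError("REMOVED_NEGATIVE probes must carry no value")

    def column(self, condition: Condition, timepoint_days: int) -> pd.Series:
        return self.values[(condition.value, timepoint_days)]

    def timepoints(self) -> list[int]:
        return sorted({tp for _, tp in self.values.columns})


def compute_accessibility(
    beta_sssi: pd.DataFrame,
    beta_control: pd.DataFrame,
    thr: Thresholds | None = None,
) -> AccessibilityMatrix:
    """Accessibility = beta(treated) - beta(no-enzyme), negatives removed.

    The two frames must cover identical probes and identical matched
    columns (one per (condition, timepoint)).  A probe-column whose raw
    delta-beta is negative is flagged REMOVED_NEGATIVE and excluded from
    every downstream call; missing inputs propagate as MISSING_INPUT.
    """
    if not beta_sssi.index.equals(beta_control.index):
        raise ValueError("probe sets of the two arms differ")
    if list(beta_sssi.columns) != list(beta_control.columns):
        raise ValueError("unmatched arm pairing: column keys differ between arms")
    delta = beta_sssi.astype(float) - beta_control.astype(float)
    flags = pd.DataFrame(FLAG_OK, index=delta.index, columns=delta.columns)
    missing = delta.isna()
    negative = (delta < 0) & ~missing
    flags = flags.mask(missing, FLAG_MISSING_INPUT).mask(negative, FLAG_REMOVED_NEGATIVE)
    values = delta.mask(negative)
    return AccessibilityMatrix(values=values, flags=flags)


def accessibility_from_beta(bm: BetaMatrix, thr: Thresholds | None = None) -> AccessibilityMatrix:
    """Build the full accessibility matrix from a paired-arm beta matrix.

    Requires both arms for every (condition, timepoint) present in the
    SssI arm; replicates are averaged within each cell first.
    """
    cells = sorted(
        {(s.condition, s.timepoint_days) for s in bm.samples if s.arm == Arm.SSSI},
        key=lambda c: (c[0].value, c[1]),
    )
    if not cells:
        raise ValueError("no methyltransferase-treated samples present")
    cols = {}
    for condition, tp in cells:
        sssi = bm.arm_mean(Arm.SSSI, condition, tp)
        ctrl = bm.arm_mean(Arm.NO_ENZYME, condition, tp)
        cols[(condition.value, tp)] = (sssi, ctrl)
    sssi_df = pd.DataFrame({k: v[0] for k, v in cols.items()})
    ctrl_df = pd.DataFrame({k: v[1] for k, v in cols.items()})
    sssi_df.columns = pd.MultiIndex.from_tuples(sssi_df.columns)
    ctrl_df.columns = pd.MultiIndex.from_tuples(ctrl_df.columns)
    return compute_accessibility(sssi_df, ctrl_df, thr)


def call_accessible(accessibility: float, thr: Thresholds | None = None) -> bool | None:
    """True when delta-beta strictly exceeds the accessible cutoff (0.2).

    Missing input returns ``None`` (missing output, never imputed).
    """
    thr = thr or Thresholds()
    if accessibility is None or (isinstance(accessibility, float) and np.isnan(accessibility)):
        return None
    return float(accessibility) > thr.accessible_delta


def call_methylation_state(beta: float, thr: Thresholds | None = None) -> MethState:
    """Three-state methylation call: >0.7 methylated, <0.3 unmethylated."""
    thr = thr or Thresholds()
    b = float(beta)
    if not 0 <= b <= 1:
        raise ValueError(f"beta out of [0,1]: {b}")
    if b > thr.meth_high:
        return MethState.METHYLATED
    if b < thr.meth_low:
        return MethState.UNMETHYLATED
    return MethState.PARTIAL


def _events_from_delta(
    delta: pd.DataFrame,
    cutoff: float,
    gain_label: str,
    loss_label: str,
    mode: DetectionMode,
) -> EventTable:
    """Threshold a probes x timepoints delta frame into an event table."""
    timepoints = sorted(delta.columns)
    frames = []
    for tp in timepoints:
        d = delta[tp]
        gain = d[d > cutoff]
        loss = d[d < -cutoff]
        for sub, label in ((gain, gain_label), (loss, loss_label)):
            if len(sub):
                frames.append(
                    pd.DataFrame(
                        {
                            "probe_id": sub.index,
                            "gene": "",
                            "timepoint_days": tp,
                            "event_type": label,
                            "delta": sub.to_numpy(),
                        }
                    )
                )
    if not frames:
        return EventTable()
    records = pd.concat(frames, ignore_index=True)
    if mode is DetectionMode.ANY_TIMEPOINT:
        # one record per (probe, direction): the earliest qualifying timepoint
        records = (
            records.sort_values(["probe_id", "event_type", "timepoint_days"])
            .drop_duplicates(subset=["probe_id", "event_type"], keep="first")
            .reset_index(drop=True)
        )
    return EventTable(records)


def detect_methylation_changes(
    beta_induced: pd.DataFrame,
    beta_control: pd.DataFrame,
    thr: Thresholds | None = None,
    mode: DetectionMode = DetectionMode.ANY_TIMEPOINT,
) -> EventTable:
    """Call methylation gain/loss events from paired no-enzyme betas.

    Inputs are probes x timepoints frames of no-enzyme-arm betas for the
    induced and control conditions.  delta = induced - control; values
    above +0.2 emit METH_GAIN, below -0.2 METH_LOSS (strict).  In
    ANY_TIMEPOINT mode a probe is reported once per direction at the
    earliest qualifying timepoint.
    """
    thr = thr or Thresholds()
    if not beta_induced.index.equals(beta_control.index):
        raise ValueError("probe sets differ between induced and control")
    shared = [tp for tp in beta_induced.columns if tp in set(beta_control.columns)]
    if not shared:
        raise ValueError("no shared timepoints")
    delta = beta_induced[shared].astype(float) - beta_control[shared].astype(float)
    return _events_from_delta(delta, thr.meth_change_delta, "METH_GAIN", "METH_LOSS", mode)


def detect_accessibility_changes(
    acc_induced: AccessibilityMatrix | pd.DataFrame,
    acc_control: AccessibilityMatrix | pd.DataFrame,
    thr: Thresholds | None = None,
    mode: DetectionMode = DetectionMode.ANY_TIMEPOINT,
) -> EventTable:
    """Call accessibility gain/loss events between induced and control.

    delta = accessibility(induced) - accessibility(control) per probe per
    timepoint; |delta| > 0.3 (strict) emits ACCESS_GAIN / ACCESS_LOSS.
    Probes missing (or removed as negative) in either matrix at a timepoint
    are skipped at that timepoint.  A probe qualifying in both directions
    at different timepoints reports both.
    """
    thr = thr or Thresholds()
    ind = _condition_frame(acc_induced, Condition.INDUCED)
    ctl = _condition_frame(acc_control, Condition.CONTROL)
    if not ind.index.equals(ctl.index):
        raise ValueError("probe sets differ between induced and control")
    shared = [tp for tp in ind.columns if tp in set(ctl.columns)]
    if not shared:
        raise ValueError("no shared timepoints between the two matrices")
    delta = ind[shared] - ctl[shared]
    return _events_from_delta(delta, thr.access_change_delta, "ACCESS_GAIN", "ACCESS_LOSS", mode)


def _condition_frame(acc, condition: Condition) -> pd.DataFrame:
    """Probes x timepoints accessibility for one condition."""
    if isinstance(acc, pd.DataFrame):
        return acc.astype(float)
    cols = [c for c in acc.values.columns if c[0] == condition.value]
    if not cols:
        # single-condition matrix: use whatever condition it holds
        conds = {c[0] for c in acc.values.columns}
        if len(conds) != 1:
            raise ValueError(f"no {condition.value} columns in accessibility matrix")
        cols = list(acc.values.columns)
    frame = acc.values[cols].copy()
    frame.columns = [tp for _, tp in cols]
    return frame


def group_by_timecourse(
    events: EventTable,
    gene_map: Mapping[str, tuple[str, ...]] | None = None,
) -> dict[tuple[int, str], set[str]]:
    """Catalogue accessibility-change probes (or genes) into the 6 groups.

    Groups are (timepoint, direction) with direction in {opening, closing},
    3 timepoints x 2 directions.  Within a direction a probe belongs to the
    earliest timepoint at which it qualifies, so groups are disjoint per
    direction.  With ``gene_map`` (probe id -> gene symbols) groups hold
    gene symbols instead of probe ids.
    """
    acc = events.of_type("ACCESS_GAIN", "ACCESS_LOSS")
    timepoints = sorted(set(acc["timepoint_days"])) if len(acc) else []
    if len(timepoints) < 3 and len(acc):
        all_tps = sorted(set(events.records["timepoint_days"]))
        timepoints = all_tps if len(all_tps) >= 3 else timepoints
    if not timepoints:
        timepoints = [2, 8, 12]
    direction_of = {"ACCESS_GAIN": "opening", "ACCESS_LOSS": "closing"}
    groups: dict[tuple[int, str], set[str]] = {
        (tp, d): set() for tp in timepoints for d in ("opening", "closing")
    }
    earliest = (
        acc.sort_values("timepoint_days")
        .drop_duplicates(subset=["probe_id", "event_type"], keep="first")
    )
    for _, row in earliest.iterrows():
        key = (int(row["timepoint_days"]), direction_of[row["event_type"]])
        if key not in groups:
            groups[key] = set()
        if gene_map is not None:
            groups[key].update(gene_map.get(row["probe_id"], ()))
        else:
            groups[key].add(row["probe_id"])
    return groups


def select_most_variable_probes(bm: BetaMatrix, n: int) -> list[str]:
    """Top-n probes by beta variance across all samples.

    Variance is over non-missing entries; ties (and the all-constant case)
    break by probe-id lexical order.  Asking for more probes than exist
    returns the full set with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(bm.probe_ids):
        warnings.warn(
            f"requested {n} probes but matrix has {len(bm.probe_ids)}; returning all",
            stacklevel=2,
        )
        n = len(bm.probe_ids)
    var = bm.values.var(axis=1, skipna=True, ddof=1).fillna(0.0)
    order = sorted(var.index, key=lambda p: (-var[p], p))
    return order[:n]
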