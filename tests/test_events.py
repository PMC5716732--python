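import numpy as np
import pandas as pd
import pytest

from chromaccess.events import (
    DetectionMode,
    MethState,
    Thresholds,
    accessibility_from_beta,
    call_accessible,
    call_methylation_state,
    compute_accessibility,
    detect_accessibility_changes,
    detect_methylation_changes,
    group_by_timecourse,
    select_most_variable_probes,
    FLAG_REMOVED_NEGATIVE,
)
from chromaccess.io import Arm, BetaMatrix, Condition, EventTable, SampleMeta


def brute_force_events(delta: pd.DataFrame, cutoff: float, gain: str, loss: str):
    """Independent double-loop oracle over probes x timepoints."""
    records = []
    for probe in delta.index:
        for tp in delta.columns:
            d = delta.loc[probe, tp]
            if np.isnan(d):
                continue
            if d > cutoff:
                records.append((probe, tp, gain))
            elif d < -cutoff:
                records.append((probe, tp, loss))
    return records


def frame(values, columns=(2, 8, 12), probes=None):
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=probes, columns=list(columns))


class TestAccessibilityScale:
    def test_subtraction(self):
        acc = compute_accessibility(frame([[0.95]], [2]), frame([[0.10]], [2]))
        assert acc.values.iloc[0, 0] == pytest.approx(0.85)

    def test_negative_delta_removed_and_flagged(self):
        acc = compute_accessibility(frame([[0.30]], [2]), frame([[0.50]], [2]))
        assert np.isnan(acc.values.iloc[0, 0])
        assert acc.flags.iloc[0, 0] == FLAG_REMOVED_NEGATIVE

    def test_zero_delta_retained(self):
        acc = compute_accessibility(frame([[0.50]], [2]), frame([[0.50]], [2]))
        assert acc.values.iloc[0, 0] == pytest.approx(0.0)

    def test_probe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="probe sets"):
            compute_accessibility(
                frame([[0.5]], [2], ["cgA"]), frame([[0.5]], [2], ["cgB"])
            )

    def test_removed_probe_never_scored_downstream(self, small_beta_matrix):
        acc = accessibility_from_beta(small_beta_matrix)
        removed = acc.flags == FLAG_REMOVED_NEGATIVE
        # cg003's treated arm sits below its control arm in the induced
        # condition at both timepoints, so it is removed there ...
        assert removed.loc["cg003", ("INDUCED", 2)]
        assert acc.values[removed].isna().all().all()
        # ... and can never surface as an accessibility-change event
        events = detect_accessibility_changes(acc, acc)
        assert "cg003" not in events.probes()

    def test_retained_values_in_unit_interval(self, noiseless_sim):
        acc = accessibility_from_beta(noiseless_sim.beta)
        vals = acc.values.to_numpy()
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        assert ok.all()


class TestStateCalls:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.25, True), (0.20, False), (0.0, False), (0.2000001, True)],
    )
    def test_accessible_strict_cutoff(self, value, expected):
        assert call_accessible(value) is expected

    def test_missing_accessibility_gives_missing_call(self):
        assert call_accessible(float("nan")) is None

    @pytest.mark.parametrize(
        "beta,state",
        [
            (0.75, MethState.METHYLATED),
            (0.25, MethState.UNMETHYLATED),
            (0.50, MethState.PARTIAL),
            (0.70, MethState.PARTIAL),
            (0.30, MethState.PARTIAL),
        ],
    )
    def test_methylation_states(self, beta, state):
        assert call_methylation_state(beta) is state

    def test_out_of_range_beta_rejected(self):
        with pytest.raises(ValueError):
            call_methylation_state(1.5)


class TestMethylationChanges:
    def test_gain_loss_and_subthreshold(self):
        induced = frame([[0.75], [0.25], [0.65]], [2])
        control = frame([[0.50], [0.50], [0.50]], [2])
        events = detect_methylation_changes(induced, control)
        by_probe = dict(zip(events.records["probe_id"], events.records["event_type"]))
        assert by_probe == {"cg0": "METH_GAIN", "cg1": "METH_LOSS"}
        gain_delta = events.records.loc[events.records["probe_id"] == "cg0", "delta"].iloc[0]
        assert gain_delta == pytest.approx(0.25)

    def test_mismatched_probes_rejected(self):
        with pytest.raises(ValueError):
            detect_methylation_changes(
                frame([[0.5]], [2], ["a"]), frame([[0.5]], [2], ["b"])
            )


class TestAccessibilityChanges:
    def test_loss_at_day2(self):
        ind = frame([[0.10]], [2])
        ctl = frame([[0.45]], [2])
        events = detect_accessibility_changes(ind, ctl)
        rec = events.records.iloc[0]
        assert rec["event_type"] == "ACCESS_LOSS"
        assert rec["timepoint_days"] == 2
        assert rec["delta"] == pytest.approx(-0.35)

    def test_any_timepoint_reports_earliest_qualifying(self):
        ind = frame([[0.50, 0.72]], [2, 8])
        ctl = frame([[0.40, 0.40]], [2, 8])
        events = detect_accessibility_changes(ind, ctl, mode=DetectionMode.ANY_TIMEPOINT)
        assert len(events) == 1
        rec = events.records.iloc[0]
        assert (rec["event_type"], rec["timepoint_days"]) == ("ACCESS_GAIN", 8)
        assert rec["delta"] == pytest.approx(0.32)

    def test_subthreshold_silent(self):
        events = detect_accessibility_changes(
            frame([[0.5, 0.5]], [2, 8]), frame([[0.3, 0.25]], [2, 8])
        )
        assert len(events) == 0

    def test_both_directions_at_different_timepoints_both_reported(self):
        ind = frame([[0.9, 0.1]], [2, 8])
        ctl = frame([[0.4, 0.5]], [2, 8])
        events = detect_accessibility_changes(ind, ctl)
        assert set(events.records["event_type"]) == {"ACCESS_GAIN", "ACCESS_LOSS"}

    def test_no_shared_timepoints_rejected(self):
        with pytest.raises(ValueError, match="timepoint"):
            detect_accessibility_changes(frame([[0.5]], [2]), frame([[0.5]], [8]))


class TestDetectionProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        induced = frame(rng.random((n, 3)))
        control = frame(rng.random((n, 3)))
        thr = Thresholds()
        events = detect_methylation_changes(
            induced, control, thr, DetectionMode.PER_TIMEPOINT
        )
        oracle = brute_force_events(induced - control, thr.meth_change_delta,
                                    "METH_GAIN", "METH_LOSS")
        got = set(zip(events.records["probe_id"], events.records["timepoint_days"],
                      events.records["event_type"]))
        assert got == set(oracle)

    def test_monotonicity_in_threshold(self):
        rng = np.random.default_rng(3)
        induced, control = frame(rng.random((500, 3))), frame(rng.random((500, 3)))
        counts = []
        for cutoff in (0.1, 0.2, 0.3, 0.5):
            thr = Thresholds(meth_change_delta=cutoff)
            counts.append(len(detect_methylation_changes(induced, control, thr)))
        assert counts == sorted(counts, reverse=True)

    def test_swap_symmetry_exchanges_gain_and_loss(self):
        rng = np.random.default_rng(4)
        induced, control = frame(rng.random((400, 3))), frame(rng.random((400, 3)))
        fwd = detect_methylation_changes(induced, control,
                                         mode=DetectionMode.PER_TIMEPOINT)
        rev = detect_methylation_changes(control, induced,
                                         mode=DetectionMode.PER_TIMEPOINT)
        assert len(fwd.of_type("METH_GAIN")) == len(rev.of_type("METH_LOSS"))
        assert len(fwd.of_type("METH_LOSS")) == len(rev.of_type("METH_GAIN"))


class TestTimecourseGroups:
    def test_earliest_assignment_within_direction(self):
        events = EventTable(
            pd.DataFrame(
                [
                    {"probe_id": "cg1", "timepoint_days": 2, "event_type": "ACCESS_LOSS", "delta": -0.4},
                    {"probe_id": "cg1", "timepoint_days": 8, "event_type": "ACCESS_LOSS", "delta": -0.5},
                    {"probe_id": "cg2", "timepoint_days": 12, "event_type": "ACCESS_GAIN", "delta": 0.4},
                ]
            )
        )
        groups = group_by_timecourse(events)
        assert groups[(2, "closing")] == {"cg1"}
        assert groups[(8, "closing")] == set()
        assert groups[(12, "opening")] == {"cg2"}

    def test_six_groups_disjoint_within_direction(self, noiseless_sim):
        acc = accessibility_from_beta(noiseless_sim.beta)
        events = detect_accessibility_changes(acc, acc, mode=DetectionMode.PER_TIMEPOINT)
        groups = group_by_timecourse(events)
        assert len(groups) == 6
        for direction in ("opening", "closing"):
            members = [groups[(tp, direction)] for tp in (2, 8, 12)]
            assert sum(len(m) for m in members) == len(set().union(*members))

    def test_empty_table_gives_six_empty_groups(self):
        groups = group_by_timecourse(EventTable())
        assert len(groups) == 6
        assert all(not members for members in groups.values())


class TestVariableProbes:
    def _matrix(self, values, probes):
        samples = [
            SampleMeta(label=f"s{i}", arm=Arm.NO_ENZYME, condition=Condition.CONTROL,
                       timepoint_days=2)
            for i in range(len(values[0]))
        ]
        return BetaMatrix(
            values=pd.DataFrame(values, index=probes, columns=[s.label for s in samples]),
            samples=samples,
        )

    def test_top_by_variance(self):
        bm = self._matrix([[0.1, 0.9], [0.5, 0.55]], ["cgA", "cgB"])
        assert select_most_variable_probes(bm, 1) == ["cgA"]

    def test_constant_matrix_breaks_ties_lexically(self):
        bm = self._matrix([[0.5, 0.5]] * 5, ["cgE", "cgC", "cgA", "cgD", "cgB"])
        assert select_most_variable_probes(bm, 3) == ["cgA", "cgB", "cgC"]

    def test_oversized_request_warns_and_returns_all(self):
        bm = self._matrix([[0.1, 0.9], [0.5, 0.5]], ["cgA", "cgB"])
        with pytest.warns(UserWarning, match="returning all"):
            out = select_most_variable_probes(bm, 10)
        assert set(out) == {"cgA", "cgB"}
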