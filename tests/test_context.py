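import numpy as np
import pandas as pd
import pytest

from chromaccess.context import (
    IslandCategory,
    RegionCategory,
    classify_island,
    classify_probe_region,
    tabulate_events_by_region,
)
from chromaccess.io import EventTable, FeatureGroup, IslandRelation
from tests.conftest import make_annotation


class TestRegionClassifier:
    @pytest.mark.parametrize(
        "groups,expected",
        [
            ((FeatureGroup.TSS200, FeatureGroup.BODY), RegionCategory.TSS),
            ((FeatureGroup.TSS1500,), RegionCategory.TSS),
            ((FeatureGroup.BODY,), RegionCategory.BODY),
            ((FeatureGroup.UTR3,), RegionCategory.BODY),
            ((FeatureGroup.UTR5,), RegionCategory.OTHER_GENE_RELATED),
            ((FeatureGroup.EXON1, FeatureGroup.BODY), RegionCategory.BODY),
            ((FeatureGroup.EXON1,), RegionCategory.OTHER_GENE_RELATED),
        ],
    )
    def test_precedence(self, groups, expected):
        genes = tuple(f"G{i}" for i in range(len(groups)))
        ann = make_annotation(genes=genes, groups=groups)
        assert classify_probe_region(ann) is expected

    def test_no_gene_is_desert(self):
        ann = make_annotation(genes=(), groups=())
        assert classify_probe_region(ann) is RegionCategory.GENE_DESERT

    def test_total_and_order_independent(self):
        ann1 = make_annotation(genes=("A", "B"), groups=(FeatureGroup.BODY, FeatureGroup.TSS200))
        ann2 = make_annotation(genes=("B", "A"), groups=(FeatureGroup.TSS200, FeatureGroup.BODY))
        assert classify_probe_region(ann1) is classify_probe_region(ann2)


class TestIslandClassifier:
    @pytest.mark.parametrize(
        "relation,expected",
        [
            (IslandRelation.ISLAND, IslandCategory.ISLAND),
            (IslandRelation.SHORE, IslandCategory.ISLAND_RELATED),
            (IslandRelation.SHELF, IslandCategory.ISLAND_RELATED),
            (IslandRelation.OPEN_SEA, IslandCategory.NON_ISLAND),
        ],
    )
    def test_mapping(self, relation, expected):
        assert classify_island(make_annotation(island=relation)) is expected


def _events(rows):
    return EventTable(pd.DataFrame(rows))


class TestBreakdown:
    def test_tss_loss_to_gain_ratio(self):
        anns = [
            make_annotation(probe_id=f"cg{i}", groups=(FeatureGroup.TSS200,), genes=("G",))
            for i in range(15)
        ]
        rows = [
            {"probe_id": f"cg{i}", "timepoint_days": 2,
             "event_type": "METH_LOSS" if i < 10 else "METH_GAIN", "delta": -0.3 if i < 10 else 0.3}
            for i in range(15)
        ]
        bd = tabulate_events_by_region(_events(rows), anns)
        assert bd.tss_loss_to_gain_ratio == pytest.approx(2.0)

    def test_zero_denominator_gives_missing_ratio(self):
        anns = [make_annotation(probe_id="cg0", groups=(FeatureGroup.TSS200,), genes=("G",))]
        bd = tabulate_events_by_region(
            _events([{"probe_id": "cg0", "timepoint_days": 2,
                      "event_type": "METH_LOSS", "delta": -0.3}]),
            anns,
        )
        assert np.isnan(bd.tss_loss_to_gain_ratio)

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(11)
        groups_pool = [
            (("G",), (FeatureGroup.TSS200,)),
            (("G",), (FeatureGroup.BODY,)),
            (("G",), (FeatureGroup.UTR5,)),
            ((), ()),
        ]
        anns, expected = [], {}
        rows = []
        for i in range(200):
            genes, groups = groups_pool[rng.integers(len(groups_pool))]
            ann = make_annotation(probe_id=f"cg{i}", genes=genes, groups=groups)
            anns.append(ann)
            etype = ["METH_GAIN", "METH_LOSS", "ACCESS_GAIN", "ACCESS_LOSS"][rng.integers(4)]
            rows.append({"probe_id": f"cg{i}", "timepoint_days": 2, "event_type": etype,
                         "delta": 0.4 if "GAIN" in etype else -0.4})
            key = (etype, classify_probe_region(ann).value)
            expected[key] = expected.get(key, 0) + 1
        bd = tabulate_events_by_region(_events(rows), anns)
        for (etype, region), count in expected.items():
            assert bd.table.loc[etype, region] == count

    def test_row_sums_conserve_event_counts(self, noiseless_sim):
        from chromaccess.events import accessibility_from_beta, detect_accessibility_changes

        acc = accessibility_from_beta(noiseless_sim.beta)
        events = detect_accessibility_changes(acc, acc)
        bd = tabulate_events_by_region(events, noiseless_sim.manifest)
        counts = events.records["event_type"].value_counts()
        for etype in ("ACCESS_GAIN", "ACCESS_LOSS"):
            assert bd.table.loc[etype].sum() == counts.get(etype, 0)

    def test_unannotated_probe_counted_not_dropped(self):
        bd = tabulate_events_by_region(
            _events([{"probe_id": "cgX", "timepoint_days": 2,
                      "event_type": "ACCESS_GAIN", "delta": 0.4}]),
            [],
        )
        assert bd.table.loc["ACCESS_GAIN", "UNANNOTATED"] == 1

    def test_island_fractions_sum_to_one(self):
        anns = [
            make_annotation(probe_id=f"cg{i}", groups=(FeatureGroup.TSS200,), genes=("G",),
                            island=rel)
            for i, rel in enumerate(
                [IslandRelation.ISLAND, IslandRelation.SHORE, IslandRelation.OPEN_SEA,
                 IslandRelation.OPEN_SEA]
            )
        ]
        rows = [{"probe_id": f"cg{i}", "timepoint_days": 2, "event_type": "METH_GAIN",
                 "delta": 0.3} for i in range(4)]
        bd = tabulate_events_by_region(_events(rows), anns)
        assert bd.tss_island_fractions.sum() == pytest.approx(1.0)
        assert bd.non_island_fraction == pytest.approx(0.5)
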