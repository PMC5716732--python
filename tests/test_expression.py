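import math

import numpy as np
import pandas as pd
import pytest

from chromaccess.expression import (
    DEResult,
    Direction,
    ExpressionMatrix,
    Group,
    chip_enrichment,
    collapse_probes_to_genes,
    differential_expression,
    harmonize_platforms,
    normalize_expression,
    quantile_normalize,
)

# hand-computed reference for the 2x2 case: columns (1,3) and (2,4);
# log2 -> (0, log2 3) and (1, 2); both ascending, so each column becomes
# the row-mean of the sorted columns: (0.5, (log2 3 + 2)/2)
REF_2X2 = (0.5, (math.log2(3) + 2) / 2)


def _matrix(values, n_treated, n_control, is_log2=False, index=None):
    labels = [f"T{i}" for i in range(n_treated)] + [f"C{i}" for i in range(n_control)]
    groups = {
        lab: (Group.TREATED if lab.startswith("T") else Group.CONTROL) for lab in labels
    }
    df = pd.DataFrame(np.asarray(values, dtype=float), columns=labels, index=index)
    return ExpressionMatrix(values=df, groups=groups, is_log2=is_log2)


class TestQuantileNormalization:
    def test_two_by_two_hand_computed(self):
        raw = _matrix([[1, 2], [3, 4]], 1, 1)
        norm = normalize_expression(raw)
        for col in norm.values.columns:
            assert norm.values[col].tolist() == pytest.approx(REF_2X2)

    def test_identical_columns_are_fixed_point(self):
        df = pd.DataFrame({"a": [0.0, 2.0, 5.0], "b": [0.0, 2.0, 5.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_sorted_columns_identical_after_normalization(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = quantile_normalize(df)
        ref = np.sort(out["a"].to_numpy())
        for col in "bcd":
            np.testing.assert_allclose(np.sort(out[col].to_numpy()), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(100, 3)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.abs(twice.to_numpy() - once.to_numpy()).max() < 1e-9

    def test_ties_get_mean_of_spanned_quantiles(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[1, -2], [3, 4]], 1, 1)


class TestDifferentialExpression:
    def test_passing_gene(self):
        r = DEResult("G", log2fc=0.70, p_value=0.01, p_adjusted=0.02)
        assert r.fold_change == pytest.approx(2 ** 0.70)
        assert r.direction is Direction.UP
        assert r.passes()

    def test_fold_below_cutoff_fails_despite_small_p(self):
        r = DEResult("G", log2fc=math.log2(1.40), p_value=0.001, p_adjusted=0.01)
        assert not r.passes()

    def test_identical_group_means_fail(self):
        norm = _matrix([[1.0, 1.0, 1.0, 1.0]], 2, 2, is_log2=True, index=["G"])
        (r,) = differential_expression(norm)
        assert r.log2fc == pytest.approx(0.0)
        assert not r.passes()

    def test_sample_permutation_within_group_invariant(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 6))
        norm = _matrix(vals, 3, 3, is_log2=True)
        permuted = _matrix(vals[:, [2, 0, 1, 5, 3, 4]], 3, 3, is_log2=True)
        for a, b in zip(differential_expression(norm), differential_expression(permuted)):
            assert a.log2fc == pytest.approx(b.log2fc)
            assert a.p_value == pytest.approx(b.p_value)

    def test_planted_fold_two_recovered(self):
        rng = np.random.default_rng(3)
        n, sd = 300, 0.2
        base = rng.uniform(6, 12, size=n)
        shift = np.zeros(n)
        shift[:50] = 1.0  # fold 2 on log2 scale
        treated = base[:, None] + shift[:, None] + rng.normal(0, sd, size=(n, 3))
        control = base[:, None] + rng.normal(0, sd, size=(n, 3))
        norm = _matrix(np.hstack([treated, control]), 3, 3, is_log2=True)
        results = differential_expression(norm)
        called = sum(r.passes() for r in results[:50])
        assert called / 50 >= 0.9

    def test_zero_variance_resolved_by_means(self):
        norm = _matrix([[2.0, 2.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]], 2, 2,
                       is_log2=True, index=["G1", "G2"])
        r1, r2 = differential_expression(norm)
        assert r1.p_value == 0.0
        assert r2.p_value == 1.0

    def test_single_sample_falls_back_to_rank_p(self):
        norm = _matrix([[5.0, 1.0], [1.2, 1.0], [1.1, 1.0]], 1, 1,
                       is_log2=True, index=["G1", "G2", "G3"])
        results = {r.gene: r for r in differential_expression(norm)}
        assert results["G1"].p_value < results["G3"].p_value

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"T0": [1.0]}, index=["G"])
        norm = ExpressionMatrix(df, {"T0": Group.TREATED}, is_log2=True)
        with pytest.raises(ValueError, match="both groups"):
            differential_expression(norm)


class TestCollapseAndHarmonize:
    def test_collapse_by_max_abs_fold(self):
        results = [
            DEResult("p1", 0.5, 0.01, 0.02),
            DEResult("p2", -1.5, 0.03, 0.04),
        ]
        (out,) = collapse_probes_to_genes(results, {"p1": "GENE", "p2": "GENE"})
        assert out.log2fc == pytest.approx(-1.5)

    def test_harmonize_restricts_to_intersection(self):
        results = [DEResult("A", 1, 0.01, 0.02), DEResult("B", 1, 0.01, 0.02)]
        kept, dropped = harmonize_platforms({"A", "B", "C"}, {"B", "C", "D"}, results)
        assert [r.gene for r in kept] == ["B"]
        assert dropped == ["A"]

    def test_identical_universes_identity(self):
        results = [DEResult("A", 1, 0.01, 0.02)]
        kept, dropped = harmonize_platforms({"A", "B"}, {"A", "B"}, results)
        assert kept == results and dropped == []

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            harmonize_platforms({"A"}, {"B"}, [])


class TestChipEnrichment:
    @pytest.mark.parametrize("ip,igg,inp,expected", [(5, 1, 9, 0.5), (1, 1, 9, 0.0)])
    def test_formula(self, ip, igg, inp, expected):
        assert chip_enrichment(ip, igg, inp) == pytest.approx(expected)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            chip_enrichment(5, 1, 1)
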