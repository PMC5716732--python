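"""Expression-microarray normalization and differential expression.

Raw bead-array intensities are log2-transformed and quantile-normalized,
then genes are called differentially expressed under a 1.5-fold change
cutoff at raw p < 0.05 (two-sided Welch t-test; Benjamini-Hochberg
adjusted p-values are reported alongside but do not gate, mirroring the
original rule while exposing the modern correction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Group",
    "Direction",
    "ExpressionMatrix",
    "DEResult",
    "normalize_expression",
    "quantile_normalize",
    "differential_expression",
    "collapse_probes_to_genes",
    "harmonize_platforms",
    "chip_enrichment",
]


class Group(str, enum.Enum):
    TREATED = "TREATED"  # knockdown or induced
    CONTROL = "CONTROL"


class Direction(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"


@dataclass
class ExpressionMatrix:
    """Features x samples intensity matrix with per-sample group labels.

    ``values`` holds raw positive intensities unless ``is_log2`` is set.
    ``groups`` maps every sample label to TREATED or CONTROL.
    """

    values: pd.DataFrame
    groups: dict[str, Group]
    is_log2: bool = False

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if not self.is_log2:
            arr = self.values.to_numpy(dtype=float)
            if np.any(arr[~np.isnan(arr)] <= 0):
                raise ValueError("raw intensities must be positive before log transform")

    def labels(self, group: Group) -> list[str]:
        return [c for c in self.values.columns if self.groups[c] is group]


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression call under the fold/p rule."""

    gene: str
    log2fc: float  # treated minus control
    p_value: float
    p_adjusted: float

    @property
    def fold_change(self) -> float:
        return float(2 ** abs(self.log2fc))

    @property
    def direction(self) -> Direction:
        return Direction.UP if self.log2fc >= 0 else Direction.DOWN

    def passes(self, fc_cutoff: float = 1.5, alpha: float = 0.05) -> bool:
        return self.fold_change >= fc_cutoff and self.p_value < alpha


def quantile_normalize(log_values: pd.DataFrame) -> pd.DataFrame:
    """Force all columns onto the mean empirical distribution.

    Each column's sorted values are replaced by the row-wise mean of the
    sorted columns; tied entries receive the mean of the quantile values
    they span (average ranks, linear interpolation).  Idempotent.
    """
    arr = log_values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    ranks = log_values.rank(method="average").to_numpy() - 1.0  # 0-based, fractional on ties
    grid = np.arange(arr.shape[0], dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, reference)
    return pd.DataFrame(out, index=log_values.index, columns=log_values.columns)


def normalize_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """log2 transform then quantile-normalize across samples."""
    if raw.is_log2:
        logged = raw.values.astype(float)
    else:
        arr = raw.values.to_numpy(dtype=float)
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise ValueError("non-positive intensity encountered")
        logged = pd.DataFrame(np.log2(arr), index=raw.values.index, columns=raw.values.columns)
    return ExpressionMatrix(
        values=quantile_normalize(logged), groups=dict(raw.groups), is_log2=True
    )


def _welch_p(treated: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values with degenerate handling.

    Zero within-group variance in both groups is resolved by the means:
    equal means -> p = 1, distinct means -> p = 0 (perfect separation).
    """
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trigger scipy's precision-loss warning; they are
        # resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(treated, control, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var0 = (treated.var(axis=1, ddof=1) == 0) & (control.var(axis=1, ddof=1) == 0)
    diff = treated.mean(axis=1) != control.mean(axis=1)
    p[var0 & diff] = 0.0
    p[var0 & ~diff] = 1.0
    return p


def differential_expression(
    norm: ExpressionMatrix,
    fc_cutoff: float = 1.5,
    alpha: float = 0.05,
) -> list[DEResult]:
    """Per-feature DE between TREATED and CONTROL on log2 values.

    log2fc = mean(treated) - mean(control).  With >=2 samples per group
    the p-value is a two-sided Welch t-test; with a single sample in
    either group it falls back to a rank-based ordering p (rank of
    |log2fc|, descending, divided by the feature count) — an ordering
    heuristic, not a calibrated test.
    """
    if not norm.is_log2:
        raise ValueError("differential expression expects a normalized (log2) matrix")
    treated_labels = norm.labels(Group.TREATED)
    control_labels = norm.labels(Group.CONTROL)
    if not treated_labels or not control_labels:
        raise ValueError("both groups need at least one sample")
    treated = norm.values[treated_labels].to_numpy(dtype=float)
    control = norm.values[control_labels].to_numpy(dtype=float)
    log2fc = treated.mean(axis=1) - control.mean(axis=1)

    if treated.shape[1] >= 2 and control.shape[1] >= 2:
        p = _welch_p(treated, control)
    else:
        order = pd.Series(np.abs(log2fc)).rank(ascending=False, method="average")
        p = (order / len(log2fc)).to_numpy()

    p_adj = multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")[1]
    return [
        DEResult(gene=str(g), log2fc=float(fc), p_value=float(pv), p_adjusted=float(pa))
        for g, fc, pv, pa in zip(norm.values.index, log2fc, p, p_adj)
    ]


def collapse_probes_to_genes(
    results: list[DEResult],
    probe_to_gene: dict[str, str],
    how: str = "max_abs",
) -> list[DEResult]:
    """Collapse probe-level results to one record per gene symbol.

    ``max_abs`` (default) keeps the probe with the largest |log2fc| per
    symbol; ``mean`` averages log2fc and takes the minimum p.  Probes with
    no mapping are dropped.
    """
    by_gene: dict[str, list[DEResult]] = {}
    for r in results:
        gene = probe_to_gene.get(r.gene)
        if gene:
            by_gene.setdefault(gene.upper(), []).append(r)
    out = []
    for gene, rs in sorted(by_gene.items()):
        if how == "max_abs":
            best = max(rs, key=lambda r: abs(r.log2fc))
            out.append(DEResult(gene, best.log2fc, best.p_value, best.p_adjusted))
        elif how == "mean":
            out.append(
                DEResult(
                    gene,
                    float(np.mean([r.log2fc for r in rs])),
                    float(min(r.p_value for r in rs)),
                    float(min(r.p_adjusted for r in rs)),
                )
            )
        else:
            raise ValueError(f"unknown collapse rule: {how!r}")
    return out


def harmonize_platforms(
    universe_a: set[str],
    universe_b: set[str],
    results: list[DEResult],
) -> tuple[list[DEResult], list[str]]:
    """Restrict DE results to the genes measurable on both platforms.

    Two different array chips share only part of their gene universes;
    downstream overlaps are only meaningful on the intersection.  Returns
    (filtered results, dropped symbols).
    """
    if not universe_a or not universe_b:
        raise ValueError("both gene universes must be non-empty")
    common = {s.upper() for s in universe_a} & {s.upper() for s in universe_b}
    if not common:
        raise ValueError(
            "gene universes are disjoint: no shared symbols "
            f"({len(universe_a)} vs {len(universe_b)} genes)"
        )
    kept = [r for r in results if r.gene.upper() in common]
    dropped = sorted({r.gene.upper() for r in results} - common)
    return kept, dropped


def chip_enrichment(ip: float, igg: float, input_signal: float) -> float:
    """ChIP enrichment with IgG background subtraction: (IP-IgG)/(Input-IgG)."""
    denom = input_signal - igg
    if denom <= 0:
        raise ValueError(f"input ({input_signal}) must exceed IgG background ({igg})")
    return (ip - igg) / denom
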