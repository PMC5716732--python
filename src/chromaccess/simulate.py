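"""Synthetic paired-arm array data with planted ground truth.

Emulates the statistical structure the pipeline assumes: paired
methyltransferase-treated / no-enzyme beta values for induced and control
conditions over a 3-point induction time course, with planted promoter
opening/closing and methylation gain/loss events persisting from their
onset; a 450K-style manifest; and a knockdown expression matrix whose
planted fold changes overlap a planted signature by construction.

Observation noise is Beta-distributed around the target mean with a fixed
concentration (mean*c, (1-mean)*c), which respects the [0, 1] support of
beta values; concentration 100 gives sd ~= 0.05 near mean 0.5, and an
infinite concentration is the exact zero-noise limit.

What this emulates — and what it does not: probe intensities are
conditionally independent given the planted state; there is no probe
cross-hybridization, batch structure, or spatial correlation along the
genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import Direction, ExpressionMatrix, Group
from .io import (
    Arm,
    BetaMatrix,
    Condition,
    FeatureGroup,
    GeneSet,
    IslandRelation,
    ProbeAnnotation,
    SampleMeta,
)

__all__ = [
    "SimConfig",
    "AccessibilitySim",
    "KnockdownSim",
    "simulate_accessibility_experiment",
    "simulate_knockdown_expression",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Fractions are per event family (gain + loss <= 1 within the
    methylation and within the accessibility family).  ``effect_access``
    (default 0.5) and ``effect_meth`` (default 0.3) are the planted mean
    shifts on the delta-beta scale; ``beta_noise_concentration`` is the
    precision of the Beta observation noise (``math.inf`` = noiseless).
    """

    n_probes: int = 10_000
    n_genes: int = 2_000
    timepoints: tuple[int, ...] = (2, 8, 12)
    seed: int = 0
    frac_access_loss: float = 0.05
    frac_access_gain: float = 0.05
    frac_meth_gain: float = 0.05
    frac_meth_loss: float = 0.05
    effect_access: float = 0.5
    effect_meth: float = 0.3
    beta_noise_concentration: float = 100.0
    expr_log2fc: float = 1.0
    expr_sd: float = 0.2
    frac_expr_up: float = 0.05
    frac_expr_down: float = 0.05
    n_samples_per_group: int = 3
    signature_size: int = 220
    signature_overlap: "int | tuple[int, int]" = 10
    early_timepoint: int = 2

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_genes < 1:
            raise ValueError("n_probes and n_genes must be positive")
        if self.frac_access_loss + self.frac_access_gain > 1:
            raise ValueError("accessibility event fractions sum above 1")
        if self.frac_meth_gain + self.frac_meth_loss > 1:
            raise ValueError("methylation event fractions sum above 1")
        for name in ("effect_access", "effect_meth"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.beta_noise_concentration <= 0:
            raise ValueError("beta_noise_concentration must be positive")
        if not self.timepoints:
            raise ValueError("at least one timepoint required")

    @property
    def overlap_down_up(self) -> tuple[int, int]:
        if isinstance(self.signature_overlap, tuple):
            return self.signature_overlap
        return (self.signature_overlap, self.signature_overlap)


@dataclass
class AccessibilitySim:
    """Synthetic paired-arm experiment plus its ground truth.

    ``probe_truth`` has one row per planted event (probe_id, event_type,
    onset_day, effect).  ``gene_truth`` has one row per gene carrying a
    planted TSS accessibility event, with its concordant expression
    direction and signature membership.
    """

    beta: BetaMatrix
    manifest: list[ProbeAnnotation]
    probe_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    signature: GeneSet
    expr_directions: dict[str, Direction]
    config: SimConfig

    def expected_candidates(self) -> tuple[set[str], set[str]]:
        """Signature genes with a concordant TSS event at the early timepoint."""
        gt = self.gene_truth
        early = gt[(gt["onset_day"] == self.config.early_timepoint) & gt["in_signature"]]
        down = set(early.loc[early["access_direction"] == "DECREASED", "gene"])
        up = set(early.loc[early["access_direction"] == "INCREASED", "gene"])
        return down, up


def _beta_noise(rng: np.random.Generator, mean: np.ndarray, concentration: float) -> np.ndarray:
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    if math.isinf(concentration):
        return mean.copy()
    return rng.beta(mean * concentration, (1 - mean) * concentration)


def _make_manifest(cfg: SimConfig, rng: np.random.Generator) -> list[ProbeAnnotation]:
    genes = [f"GENE{i:05d}" for i in range(1, cfg.n_genes + 1)]
    feature_choices = [
        FeatureGroup.TSS200,
        FeatureGroup.TSS1500,
        FeatureGroup.BODY,
        FeatureGroup.UTR3,
        FeatureGroup.UTR5,
        FeatureGroup.EXON1,
    ]
    feature_probs = np.array([0.25, 0.15, 0.30, 0.10, 0.10, 0.10])
    island_choices = [
        IslandRelation.ISLAND,
        IslandRelation.SHORE,
        IslandRelation.SHELF,
        IslandRelation.OPEN_SEA,
    ]
    island_probs = np.array([0.30, 0.20, 0.10, 0.40])

    desert = rng.random(cfg.n_probes) < 0.10
    gene_idx = rng.integers(0, cfg.n_genes, size=cfg.n_probes)
    features = [
        feature_choices[i]
        for i in rng.choice(len(feature_choices), size=cfg.n_probes, p=feature_probs)
    ]
    islands = [
        island_choices[i]
        for i in rng.choice(len(island_choices), size=cfg.n_probes, p=island_probs)
    ]
    chroms = rng.integers(1, 23, size=cfg.n_probes)
    positions = rng.integers(1, 200_000_000, size=cfg.n_probes)

    out = []
    for i in range(cfg.n_probes):
        pid = f"cg{i:08d}"
        if desert[i]:
            out.append(
                ProbeAnnotation(
                    probe_id=pid,
                    chrom=f"chr{chroms[i]}",
                    pos=int(positions[i]),
                    island_relation=islands[i],
                )
            )
        else:
            out.append(
                ProbeAnnotation(
                    probe_id=pid,
                    chrom=f"chr{chroms[i]}",
                    pos=int(positions[i]),
                    genes=(genes[gene_idx[i]],),
                    feature_groups=(features[i],),
                    island_relation=islands[i],
                )
            )
    return out


def _plant_events(
    cfg: SimConfig, rng: np.random.Generator, manifest: list[ProbeAnnotation]
) -> pd.DataFrame:
    """Choose event probes (at most one planted event per gene) and onsets."""
    counts = {
        "ACCESS_LOSS": round(cfg.frac_access_loss * cfg.n_probes),
        "ACCESS_GAIN": round(cfg.frac_access_gain * cfg.n_probes),
        "METH_GAIN": round(cfg.frac_meth_gain * cfg.n_probes),
        "METH_LOSS": round(cfg.frac_meth_loss * cfg.n_probes),
    }
    effects = {
        "ACCESS_LOSS": -cfg.effect_access,
        "ACCESS_GAIN": cfg.effect_access,
        "METH_GAIN": cfg.effect_meth,
        "METH_LOSS": -cfg.effect_meth,
    }
    order = rng.permutation(cfg.n_probes)
    taken_genes: set[str] = set()
    rows = []
    cursor = 0
    for etype, n_events in counts.items():
        placed = 0
        while placed < n_events and cursor < cfg.n_probes:
            ann = manifest[order[cursor]]
            cursor += 1
            if ann.genes and set(ann.genes) & taken_genes:
                continue
            taken_genes.update(ann.genes)
            onset = int(rng.choice(cfg.timepoints))
            rows.append(
                {
                    "probe_id": ann.probe_id,
                    "event_type": etype,
                    "onset_day": onset,
                    "effect": effects[etype],
                }
            )
            placed += 1
        if placed < n_events:
            raise ValueError("not enough probes to place the requested events")
    return pd.DataFrame(rows, columns=["probe_id", "event_type", "onset_day", "effect"])


def simulate_accessibility_experiment(cfg: SimConfig) -> AccessibilitySim:
    """Generate the full paired-arm beta matrix with planted events.

    Per-probe target means: no-enzyme beta = endogenous methylation m;
    treated beta = min(m + a, 1) where a is the probe's accessibility.
    Planted events shift the induced condition from their onset timepoint
    onward (monotone trajectories); the control condition is stationary.
    Fixing the seed makes the output bit-identical across runs.
    """
    rng = np.random.default_rng(cfg.seed)
    manifest = _make_manifest(cfg, rng)
    probe_ids = [a.probe_id for a in manifest]
    truth = _plant_events(cfg, rng, manifest)

    n = cfg.n_probes
    idx = {pid: i for i, pid in enumerate(probe_ids)}

    # baseline endogenous methylation: bimodal background
    u = rng.random(n)
    m0 = np.where(
        u < 0.5,
        rng.uniform(0.02, 0.20, size=n),
        np.where(u < 0.8, rng.uniform(0.70, 0.95, size=n), rng.uniform(0.30, 0.60, size=n)),
    )
    # baseline accessibility: mostly closed, a minority of open promoters
    v = rng.random(n)
    a0 = np.where(v < 0.6, rng.uniform(0.0, 0.15, size=n), rng.uniform(0.40, 0.80, size=n))

    # planted probes get baselines that leave room for the shift and keep
    # the treated-arm mean inside [0, 1]
    for _, row in truth.iterrows():
        i = idx[row["probe_id"]]
        if row["event_type"] == "ACCESS_LOSS":
            a0[i] = rng.uniform(0.70, 0.90)
            m0[i] = rng.uniform(0.02, 0.08)
        elif row["event_type"] == "ACCESS_GAIN":
            a0[i] = rng.uniform(0.0, 0.12)
            m0[i] = rng.uniform(0.02, 0.08)
        elif row["event_type"] == "METH_GAIN":
            m0[i] = rng.uniform(0.10, 0.50)
            a0[i] = rng.uniform(0.0, 0.15)
        else:  # METH_LOSS
            m0[i] = rng.uniform(0.50, 0.90)
            a0[i] = rng.uniform(0.0, 0.15)

    meth_shift = np.zeros(n)
    acc_shift = np.zeros(n)
    onset = np.full(n, np.iinfo(np.int32).max)
    for _, row in truth.iterrows():
        i = idx[row["probe_id"]]
        onset[i] = row["onset_day"]
        if row["event_type"].startswith("METH"):
            meth_shift[i] = row["effect"]
        else:
            acc_shift[i] = row["effect"]

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    for condition in (Condition.CONTROL, Condition.INDUCED):
        for tp in cfg.timepoints:
            active = (condition is Condition.INDUCED) & (onset <= tp)
            m = np.clip(m0 + np.where(active, meth_shift, 0.0), 0.0, 1.0)
            a = np.clip(a0 + np.where(active, acc_shift, 0.0), 0.0, 1.0)
            for arm, target in ((Arm.NO_ENZYME, m), (Arm.SSSI, np.minimum(m + a, 1.0))):
                label = f"{condition.value}_{arm.value}_d{tp}"
                columns[label] = _beta_noise(rng, target, cfg.beta_noise_concentration)
                samples.append(
                    SampleMeta(label=label, arm=arm, condition=condition, timepoint_days=tp)
                )

    beta = BetaMatrix(
        values=pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id")),
        samples=samples,
    )

    gene_truth, signature, expr_directions = _gene_truth_and_signature(cfg, rng, manifest, truth)
    return AccessibilitySim(
        beta=beta,
        manifest=manifest,
        probe_truth=truth,
        gene_truth=gene_truth,
        signature=signature,
        expr_directions=expr_directions,
        config=cfg,
    )


def _gene_truth_and_signature(
    cfg: SimConfig,
    rng: np.random.Generator,
    manifest: list[ProbeAnnotation],
    truth: pd.DataFrame,
) -> tuple[pd.DataFrame, GeneSet, dict[str, Direction]]:
    """Gene-level planted directions and a signature with known overlap."""
    from .context import RegionCategory, classify_probe_region

    ann_by_probe = {a.probe_id: a for a in manifest}
    rows = []
    for _, row in truth.iterrows():
        if not row["event_type"].startswith("ACCESS"):
            continue
        ann = ann_by_probe[row["probe_id"]]
        if not ann.genes or classify_probe_region(ann) is not RegionCategory.TSS:
            continue
        direction = "DECREASED" if row["event_type"] == "ACCESS_LOSS" else "INCREASED"
        for gene in ann.genes:
            rows.append(
                {
                    "gene": gene,
                    "access_direction": direction,
                    "onset_day": int(row["onset_day"]),
                    "expr_direction": "DOWN" if direction == "DECREASED" else "UP",
                }
            )
    gene_truth = pd.DataFrame(
        rows, columns=["gene", "access_direction", "onset_day", "expr_direction"]
    )

    k_down, k_up = cfg.overlap_down_up
    early = gene_truth[gene_truth["onset_day"] == cfg.early_timepoint]
    pool_down = sorted(early.loc[early["access_direction"] == "DECREASED", "gene"])
    pool_up = sorted(early.loc[early["access_direction"] == "INCREASED", "gene"])
    if k_down > len(pool_down) or k_up > len(pool_up):
        raise ValueError(
            f"signature_overlap ({k_down} down, {k_up} up) exceeds planted early TSS "
            f"event genes ({len(pool_down)} down, {len(pool_up)} up)"
        )
    chosen_down = list(rng.choice(pool_down, size=k_down, replace=False)) if k_down else []
    chosen_up = list(rng.choice(pool_up, size=k_up, replace=False)) if k_up else []

    event_genes = set(gene_truth["gene"])
    all_genes = [f"GENE{i:05d}" for i in range(1, cfg.n_genes + 1)]
    fillers = [g for g in all_genes if g not in event_genes]
    n_fill = max(0, cfg.signature_size - k_down - k_up)
    filler = list(rng.choice(fillers, size=min(n_fill, len(fillers)), replace=False))
    signature = GeneSet.from_symbols("synthetic_core_signature", chosen_down + chosen_up + filler)

    gene_truth["in_signature"] = gene_truth["gene"].isin(signature.symbols)
    expr_directions = {
        row["gene"]: Direction(row["expr_direction"]) for _, row in gene_truth.iterrows()
    }
    return gene_truth, signature, expr_directions


@dataclass
class KnockdownSim:
    """Synthetic knockdown expression experiment with planted DE."""

    expression: ExpressionMatrix
    truth: pd.DataFrame  # gene, direction (planted; absent genes are null)
    signature: GeneSet
    signature_directions: dict[str, Direction]
    config: SimConfig

    def planted(self, direction: Direction) -> set[str]:
        return set(self.truth.loc[self.truth["direction"] == direction.value, "gene"])


def simulate_knockdown_expression(cfg: SimConfig) -> KnockdownSim:
    """Log-normal intensities with planted fold changes and signature overlap.

    Planted DE genes shift the treated group by +/- ``expr_log2fc`` on the
    log2 scale with within-group sd ``expr_sd``; the signature contains
    exactly ``signature_overlap`` planted genes per direction (error if
    more are requested than planted), padded with null genes to
    ``signature_size``.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from the array sim
    genes = [f"GENE{i:05d}" for i in range(1, cfg.n_genes + 1)]
    n_down = round(cfg.frac_expr_down * cfg.n_genes)
    n_up = round(cfg.frac_expr_up * cfg.n_genes)
    if n_down + n_up > cfg.n_genes:
        raise ValueError("expression DE fractions sum above 1")
    perm = rng.permutation(cfg.n_genes)
    down_genes = [genes[i] for i in perm[:n_down]]
    up_genes = [genes[i] for i in perm[n_down : n_down + n_up]]

    shift = np.zeros(cfg.n_genes)
    for g in down_genes:
        shift[genes.index(g)] = -cfg.expr_log2fc
    for g in up_genes:
        shift[genes.index(g)] = cfg.expr_log2fc

    baseline = rng.uniform(6.0, 12.0, size=cfg.n_genes)
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, Group] = {}
    for j in range(cfg.n_samples_per_group):
        label = f"CTRL_{j + 1}"
        cols[label] = baseline + rng.normal(0.0, cfg.expr_sd, size=cfg.n_genes)
        groups[label] = Group.CONTROL
    for j in range(cfg.n_samples_per_group):
        label = f"KD_{j + 1}"
        cols[label] = baseline + shift + rng.normal(0.0, cfg.expr_sd, size=cfg.n_genes)
        groups[label] = Group.TREATED

    raw = pd.DataFrame(
        {k: np.power(2.0, v) for k, v in cols.items()}, index=pd.Index(genes, name="gene")
    )
    expression = ExpressionMatrix(values=raw, groups=groups, is_log2=False)

    k_down, k_up = cfg.overlap_down_up
    if k_down > n_down or k_up > n_up:
        raise ValueError("signature_overlap exceeds the planted DE gene count")
    sig_down = down_genes[:k_down]
    sig_up = up_genes[:k_up]
    null_genes = [g for g in genes if g not in set(down_genes) | set(up_genes)]
    n_fill = max(0, cfg.signature_size - k_down - k_up)
    filler = list(rng.choice(null_genes, size=min(n_fill, len(null_genes)), replace=False))

    signature = GeneSet.from_symbols("synthetic_core_signature", sig_down + sig_up + filler)
    signature_directions: dict[str, Direction] = {}
    for g in sig_down:
        signature_directions[g] = Direction.DOWN
    for g in sig_up:
        signature_directions[g] = Direction.UP
    for i, g in enumerate(filler):
        # null signature members still carry a direction in the published list
        signature_directions[g] = Direction.DOWN if i % 2 == 0 else Direction.UP

    truth = pd.DataFrame(
        {
            "gene": down_genes + up_genes,
            "direction": ["DOWN"] * len(down_genes) + ["UP"] * len(up_genes),
            "log2fc": [-cfg.expr_log2fc] * len(down_genes) + [cfg.expr_log2fc] * len(up_genes),
        }
    )
    return KnockdownSim(
        expression=expression,
        truth=truth,
        signature=signature,
        signature_directions=signature_directions,
        config=cfg,
    )
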