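"""Stage orchestration: simulate → accessibility → events → … → screen.

Each stage consumes the in-memory products of its prerequisites, writes its
tables under the run's output directory, and records every output with a
content hash in a run log, so a re-run with the same config and seed
reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .context import tabulate_events_by_region
from .events import (
    AccessibilityMatrix,
    DetectionMode,
    Thresholds,
    accessibility_from_beta,
    detect_accessibility_changes,
    detect_methylation_changes,
)
from .expression import Direction, differential_expression, normalize_expression
from .io import (
    Arm,
    Condition,
    EventTable,
    write_beta_matrix,
    write_event_table,
    write_probe_manifest,
)
from .joint import classify_joint_table, functional_change_catalog
from .screen import refine_mediators, screen_driver_candidates
from .simulate import SimConfig, simulate_accessibility_experiment, simulate_knockdown_expression

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "accessibility", "events", "context", "joint", "de", "screen", "report")

_REQUIRES = {
    "accessibility": ("simulate",),
    "events": ("accessibility",),
    "context": ("events",),
    "joint": ("accessibility",),
    "de": ("simulate",),
    "screen": ("events", "de"),
    "report": ("events",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Single structured configuration for a pipeline run."""

    outdir: Path = Path("chromaccess_run")
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    early_timepoint: int = 2
    sim: SimConfig = field(default_factory=SimConfig)
    detection_mode: DetectionMode = DetectionMode.ANY_TIMEPOINT

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"invalid config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "outdir" in data:
            kwargs["outdir"] = Path(data["outdir"])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "early_timepoint" in data:
            kwargs["early_timepoint"] = int(data["early_timepoint"])
        if "thresholds" in data:
            kwargs["thresholds"] = Thresholds(**data["thresholds"])
        if "sim" in data:
            sim = dict(data["sim"])
            if "timepoints" in sim:
                sim["timepoints"] = tuple(sim["timepoints"])
            kwargs["sim"] = SimConfig(**sim)
        if "detection_mode" in data:
            kwargs["detection_mode"] = DetectionMode(data["detection_mode"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "early_timepoint": self.early_timepoint,
                "thresholds": dataclasses.asdict(self.thresholds),
                "sim": dataclasses.asdict(
                    dataclasses.replace(self.sim, seed=self.seed)
                ),
                "detection_mode": self.detection_mode.value,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | list[str] = STAGES) -> dict:
    """Execute the requested stages in order; returns the run manifest.

    Stage dependencies are enforced: asking for a stage whose prerequisite
    was neither requested nor already satisfiable raises ``PipelineError``
    naming the missing stage.
    """
    stages = tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    requested = set(stages)
    for st in stages:
        for req in _REQUIRES.get(st, ()):
            if req not in requested:
                raise PipelineError(f"stage {st!r} requires missing upstream stage {req!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    outputs: list[Path] = []

    ordered = [s for s in STAGES if s in requested]
    for st in ordered:
        outputs.extend(_STAGE_FNS[st](config, state, outdir))

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ordered,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    state["manifest"] = manifest
    return manifest


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> list[Path]:
    cfg = dataclasses.replace(config.sim, seed=config.seed)
    acc_sim = simulate_accessibility_experiment(cfg)
    kd_sim = simulate_knockdown_expression(cfg)
    state["acc_sim"], state["kd_sim"] = acc_sim, kd_sim

    paths = []
    beta_path, sheet_path = outdir / "beta_matrix.tsv", outdir / "sample_sheet.tsv"
    write_beta_matrix(acc_sim.beta, beta_path, sheet_path)
    manifest_path = outdir / "probe_manifest.tsv"
    write_probe_manifest(acc_sim.manifest, manifest_path)
    truth_path = outdir / "ground_truth.tsv"
    acc_sim.probe_truth.to_csv(truth_path, sep="\t", index=False)
    gene_truth_path = outdir / "gene_truth.tsv"
    acc_sim.gene_truth.to_csv(gene_truth_path, sep="\t", index=False)
    sig_path = outdir / "signature.txt"
    sig_path.write_text("\n".join(sorted(acc_sim.signature.symbols)) + "\n")
    expr_path = outdir / "knockdown_expression.tsv"
    kd_sim.expression.values.round(6).to_csv(expr_path, sep="\t")
    paths += [beta_path, sheet_path, manifest_path, truth_path, gene_truth_path, sig_path, expr_path]
    return paths


def _stage_accessibility(config: RunConfig, state: dict, outdir: Path) -> list[Path]:
    if "acc_sim" not in state:
        raise PipelineError("stage 'accessibility' requires outputs of stage 'simulate'")
    acc = accessibility_from_beta(state["acc_sim"].beta, config.thresholds)
    state["accessibility"] = acc
    path = outdir / "accessibility.tsv"
    flat = acc.values.copy()
    flat.columns = [f"{c}_d{tp}" for c, tp in flat.columns]
    flat.round(6).to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")
    return [path]


def _no_enzyme_frame(beta, condition: Condition) -> pd.DataFrame:
    cols = {}
    for tp in beta.timepoints():
        cols[tp] = beta.arm_mean(Arm.NO_ENZYME, condition, tp)
    return pd.DataFrame(cols)


def _stage_events(config: RunConfig, state: dict, outdir: Path) -> list[Path]:
    if "accessibility" not in state:
        raise PipelineError("stage 'events' requires outputs of stage 'accessibility'")
    beta = state["acc_sim"].beta
    thr, mode = config.thresholds, config.detection_mode
    meth = detect_methylation_changes(
        _no_enzyme_frame(beta, Condition.INDUCED),
        _no_enzyme_frame(beta, Condition.CONTROL),
        thr,
        mode,
    )
    acc = state["accessibility"]
    access = detect_accessibility_changes(acc, acc, thr, mode)
    events = EventTable.concat([meth, access])
    # annotate genes
    gene_of = {a.probe_id: ";".join(a.genes) for a in state["acc_sim"].manifest}
    events.records["gene"] = events.records["probe_id"].map(gene_of).fillna("")
    state["events"] = events
    path = outdir / "events.tsv"
    write_event_table(events, path, "TSV")
    return [path]


def _stage_context(config: RunConfig, state: dict, outdir: Path) -> list[Path]:
    if "events" not in state:
        raise PipelineError("stage 'context' requires outputs of stage 'events'")
    breakdown = tabulate_events_by_region(state["events"], state["acc_sim"].manifest)
    state["breakdown"] = breakdown
    table_path = outdir / "region_breakdown.tsv"
    breakdown.table.to_csv(table_path, sep="\t", index_label="event_type")
    summary_path = outdir / "context_summary.json"
    summary_path.write_text(json.dumps(breakdown.summary(), indent=2, sort_keys=True) + "\n")
    return [table_path, summary_path]


def _stage_joint(config: RunConfig, state: dict, outdir: Path) -> list[Path]:
    if "accessibility" not in state:
        raise PipelineError("stage 'joint' requires outputs of stage 'accessibility'")
    beta = state["acc_sim"].beta
    acc = state["accessibility"]
    frames = []
    for tp in beta.timepoints():
        dm = beta.arm_mean(Arm.NO_ENZYME, Condition.INDUCED, tp) - beta.arm_mean(
            Arm.NO_ENZYME, Condition.CONTROL, tp
        )
        da = acc.column(Condition.INDUCED, tp) - acc.column(Condition.CONTROL, tp)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": dm.index,
                    "timepoint_days": tp,
                    "delta_meth": dm.to_numpy(),
                    "delta_access": da.to_numpy(),
                }
            )
        )
    deltas = pd.concat(frames, ignore_index=True)
    joint = classify_joint_table(deltas, config.thresholds)
    state["joint"] = joint
    catalog = functional_change_catalog(joint, state["acc_sim"].manifest)
    state["functional_catalog"] = catalog
    joint_path = outdir / "joint_classes.tsv"
    joint.round({"delta_meth": 6, "delta_access": 6}).to_csv(joint_path, sep="\t", index=False)
    cat_path = outdir / "functional_catalog.tsv"
    catalog.to_csv(cat_path, sep="\t", index=False)
    return [joint_path, cat_path]


def _stage_de(config: RunConfig, state: dict, outdir: Path) -> list[Path]:
    if "kd_sim" not in state:
        raise PipelineError("stage 'de' requires outputs of stage 'simulate'")
    norm = normalize_expression(state["kd_sim"].expression)
    results = differential_expression(norm)
    state["kd_de"] = results
    path = outdir / "knockdown_de.tsv"
    pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "log2fc": [round(r.log2fc, 6) for r in results],
            "fold_change": [round(r.fold_change, 6) for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "direction": [r.direction.value for r in results],
            "passes": [r.passes() for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
    return [path]


def _stage_screen(config: RunConfig, state: dict, outdir: Path) -> list[Path]:
    for req, stage in (("events", "events"), ("kd_de", "de")):
        if req not in state:
            raise PipelineError(f"stage 'screen' requires outputs of stage {stage!r}")
    acc_sim = state["acc_sim"]
    from .context import RegionCategory, classify_probe_region

    tss_probes = {
        a.probe_id
        for a in acc_sim.manifest
        if classify_probe_region(a) is RegionCategory.TSS
    }
    recs = state["events"].records
    tss_events = EventTable(recs[recs["probe_id"].isin(tss_probes)].copy())

    screen = screen_driver_candidates(
        tss_events, acc_sim.expr_directions, acc_sim.signature, config.early_timepoint
    )
    state["screen"] = screen
    refine = refine_mediators(state["kd_de"], state["kd_sim"].signature_directions)
    state["refine"] = refine

    cand_path = outdir / "driver_candidates.tsv"
    screen.to_frame().to_csv(cand_path, sep="\t", index=False)
    refined_path = outdir / "refined_mediators.tsv"
    refine.to_frame().to_csv(refined_path, sep="\t", index=False)
    return [cand_path, refined_path]


def _stage_report(config: RunConfig, state: dict, outdir: Path) -> list[Path]:
    if "events" not in state:
        raise PipelineError("stage 'report' requires outputs of stage 'events'")
    from .report import render_report

    return render_report(state, outdir, config)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "accessibility": _stage_accessibility,
    "events": _stage_events,
    "context": _stage_context,
    "joint": _stage_joint,
    "de": _stage_de,
    "screen": _stage_screen,
    "report": _stage_report,
}
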