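"""Shared run configuration for the numbered analysis scripts.

All scripts drive the same deterministic pipeline run (seed 1, 10,000
probes at the standard study conditions) into ``results/pipeline``; each
script requests the stages it needs, so they can be run independently or
in order.
"""

from pathlib import Path

from chromaccess.pipeline import RunConfig, run_pipeline
from chromaccess.simulate import SimConfig

RESULTS = Path("results")
OUTDIR = RESULTS / "pipeline"
SEED = 1

CONFIG = RunConfig(
    outdir=OUTDIR,
    seed=SEED,
    sim=SimConfig(n_probes=10_000, n_genes=2_000, signature_overlap=10),
)


def run_stages(*stages):
    return run_pipeline(CONFIG, stages)
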