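import math

import pandas as pd
import pytest

from chromaccess.io import (
    Arm,
    BetaMatrix,
    Condition,
    FeatureGroup,
    IslandRelation,
    ProbeAnnotation,
    SampleMeta,
)
from chromaccess.simulate import SimConfig, simulate_accessibility_experiment


def make_annotation(
    probe_id="cg001",
    chrom="chr1",
    pos=100,
    genes=("GENEA",),
    groups=(FeatureGroup.TSS200,),
    island=IslandRelation.ISLAND,
):
    return ProbeAnnotation(
        probe_id=probe_id,
        chrom=chrom,
        pos=pos,
        genes=tuple(genes),
        feature_groups=tuple(groups),
        island_relation=island,
    )


@pytest.fixture
def small_beta_matrix():
    """Two conditions x two arms x two timepoints, three probes."""
    samples = []
    cols = {}
    base = {
        ("CONTROL", "NO_ENZYME"): [0.1, 0.8, 0.5],
        ("CONTROL", "SSSI"): [0.7, 0.9, 0.5],
        ("INDUCED", "NO_ENZYME"): [0.1, 0.4, 0.5],
        # cg003 treated arm below its control arm: negative raw delta-beta
        ("INDUCED", "SSSI"): [0.3, 0.5, 0.2],
    }
    for tp in (2, 8):
        for (cond, arm), vals in base.items():
            label = f"{cond}_{arm}_d{tp}"
            cols[label] = vals
            samples.append(
                SampleMeta(
                    label=label,
                    arm=Arm(arm),
                    condition=Condition(cond),
                    timepoint_days=tp,
                )
            )
    values = pd.DataFrame(cols, index=["cg001", "cg002", "cg003"])
    return BetaMatrix(values=values, samples=samples)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small zero-noise synthetic experiment shared across tests."""
    cfg = SimConfig(
        n_probes=2000,
        n_genes=500,
        seed=7,
        beta_noise_concentration=math.inf,
        signature_overlap=3,
        signature_size=50,
    )
    return simulate_accessibility_experiment(cfg)
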