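"""Classify probes jointly by methylation and accessibility change.

Assigns every probe's (delta-methylation, delta-accessibility) pair to
regions a-f, separating methylation-dependent chromatin changes (a, d)
from methylation-independent ones (e, f) and passenger-candidate
methylation-only changes (b, c), and aggregates TSS probes to a per-gene
functional-change catalog.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import CONFIG, run_stages


def main() -> None:
    run_stages("simulate", "accessibility", "joint")
    joint = pd.read_csv(CONFIG.outdir / "joint_classes.tsv", sep="\t")
    counts = joint["region"].value_counts()
    print("probe-timepoint pairs per joint region:")
    print(counts.to_string())
    catalog = pd.read_csv(CONFIG.outdir / "functional_catalog.tsv", sep="\t")
    n_func = (catalog["call"] == "functional").sum()
    n_pass = (catalog["call"] == "passenger_candidate").sum()
    print(f"{n_func} genes with functional chromatin changes, "
          f"{n_pass} passenger candidates")


if __name__ == "__main__":
    main()
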