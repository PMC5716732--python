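"""Two-stage driver screen on the synthetic run.

Stage 1 intersects genes with an early (day 2) TSS accessibility change
with the planted core signature, keeping concordant chromatin/expression
pairs.  Stage 2 overlaps the knockdown DE genes with the signature by
direction and applies the p < 0.05 filter, yielding refined mediators.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import CONFIG, run_stages


def main() -> None:
    run_stages("simulate", "accessibility", "events", "de", "screen")
    cand = pd.read_csv(CONFIG.outdir / "driver_candidates.tsv", sep="\t")
    closed = cand[cand["accessibility"] == "DECREASED"]
    opened = cand[cand["accessibility"] == "INCREASED"]
    print(f"driver candidates: {len(closed)} closed/downregulated, "
          f"{len(opened)} opened/upregulated")
    print(cand.to_string(index=False))
    refined = pd.read_csv(CONFIG.outdir / "refined_mediators.tsv", sep="\t")
    print(f"refined mediators after signature overlap and p-filter: {len(refined)}")


if __name__ == "__main__":
    main()
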