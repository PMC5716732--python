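"""Differential expression of the synthetic knockdown experiment.

log2-transforms and quantile-normalizes the intensity matrix, then calls
genes at 1.5-fold / p < 0.05 (Welch t-test; BH-adjusted p reported
alongside), writing results/pipeline/knockdown_de.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import CONFIG, run_stages


def main() -> None:
    run_stages("simulate", "de")
    de = pd.read_csv(CONFIG.outdir / "knockdown_de.tsv", sep="\t")
    called = de[de["passes"]]
    print(f"{len(called)}/{len(de)} genes pass 1.5-fold at p<0.05 "
          f"({(called['direction'] == 'DOWN').sum()} down, "
          f"{(called['direction'] == 'UP').sum()} up)")


if __name__ == "__main__":
    main()
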