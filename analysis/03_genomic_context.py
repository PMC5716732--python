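"""Break events down by genomic context.

Tabulates change events by region (TSS, gene body, other gene-related,
gene desert) and TSS methylation changes by CpG-island status, writing
results/pipeline/region_breakdown.tsv and context_summary.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import CONFIG, run_stages


def main() -> None:
    run_stages("simulate", "accessibility", "events", "context")
    summary = json.loads((CONFIG.outdir / "context_summary.json").read_text())
    ratio = summary["tss_loss_to_gain_ratio"]
    print((CONFIG.outdir / "region_breakdown.tsv").read_text())
    print(f"TSS demethylation : methylation-gain ratio = {ratio:.2f}")
    fr = summary["tss_island_fractions"]
    print(
        "TSS methylation changes by island status: "
        + ", ".join(f"{k}={v:.2f}" for k, v in fr.items() if v)
    )


if __name__ == "__main__":
    main()
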