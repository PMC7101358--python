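#!/usr/bin/env python
"""Assemble the run report: stratum length/GC statistics, SSR composition,
DE counts, set-logic region sizes, NAT concordance and miRNA summaries.
"""

import argparse
import json
from pathlib import Path

from saltlnc.pipeline import run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/synthetic_run"))
    args = parser.parse_args()

    run_pipeline(args.run_dir, stages=["report"])
    report = json.loads((args.run_dir / "report.json").read_text())
    print("label counts:", report["label_counts"])
    print("lncRNA stratum:", report["lncrna_stats"])
    print("coding stratum:", report["coding_stats"])
    print("DE counts:", report.get("de_counts", {}))
    if "nat" in report:
        print("NAT concordance:", report["nat"])
    if "mirna" in report:
        print("pooled miRNA:",
              report["mirna"]["pooled_distinct_precursors"], "precursors /",
              report["mirna"]["pooled_distinct_families"], "families")
    print(f"full report: {args.run_dir / 'report.json'}")


if __name__ == "__main__":
    main()
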