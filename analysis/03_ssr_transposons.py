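#!/usr/bin/env python
"""Scan lncRNA and coding transcripts for perfect microsatellites (2-6 nt
motifs at 6/5/5/4/4 minimum repeats) and flag probable transposon carriers.
"""

import argparse
from pathlib import Path

from saltlnc.pipeline import run_pipeline
from saltlnc.simulate import SyntheticTruth
from saltlnc.ssr import SsrLocus, ssr_summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run-dir", type=Path, default=Path("results/synthetic_run"))
    args = parser.parse_args()

    run_pipeline(args.run_dir, stages=["ssr"])
    rows = (args.run_dir / "ssr.tsv").read_text().strip().splitlines()[1:]
    loci = [
        SsrLocus(f[0], f[2], f[3], int(f[7]), int(f[5]) - 1, int(f[6]))
        for f in (r.split("\t") for r in rows)
    ]
    summary = ssr_summary(loci)
    print(f"{summary.n_loci} SSR loci in {summary.n_transcripts_with_ssr} transcripts")
    print("percent by motif length:",
          {k: round(v, 1) for k, v in summary.by_motif_length_pct.items()})
    print("canonical classes:", summary.by_canonical)

    truth = SyntheticTruth.from_json(args.run_dir / "truth.json")
    found = {(l.transcript_id, l.motif, l.start) for l in loci}
    planted = {(d["transcript_id"], d["motif"], d["start"]) for d in truth.ssr_loci}
    print(f"planted loci recovered: {len(found & planted)}/{len(planted)}")

    flagged = (args.run_dir / "transposons.tsv").read_text().split()[1:]
    print(f"transposon-flagged transcripts: {len(flagged)} "
          f"(planted: {len(truth.transposon_ids)})")


if __name__ == "__main__":
    main()
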