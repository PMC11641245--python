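#!/usr/bin/env python
"""Classify hemisegment defects and summarize cohorts.

Reads the counts tables written by 01_simulate_cohorts.py, calls per-
hemisegment defects (full-information classifier where pericardial counts
exist, CC-only otherwise), writes per-hemisegment calls, per-embryo
proportion summaries, and the pooled per-genotype percentage table
(the bar-chart-style cohort summary).
"""

import argparse
from pathlib import Path

from cardiodiv.classify import classify_embryo, summarize_embryo
from cardiodiv.io import read_counts_table, write_calls_table, write_summary_table
from cardiodiv.pipeline import summarize_cohort


def process(counts_path: Path, prefix: str, out: Path) -> None:
    embryos = read_counts_table(counts_path)
    calls_by_embryo = [(e, classify_embryo(e)) for e in embryos]
    write_calls_table(calls_by_embryo, out / f"{prefix}_calls.tsv")
    summaries = [s for e, c in calls_by_embryo if (s := summarize_embryo(e, c)) is not None]
    write_summary_table(summaries, out / f"{prefix}_embryo_summaries.tsv")
    cohort = summarize_cohort(summaries)
    cohort.to_csv(out / f"{prefix}_cohort_summary.tsv", sep="\t", index=False)
    print(f"{prefix}:")
    print(cohort.to_string(index=False))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    process(args.results / "screen_counts.tsv", "screen", args.results)
    process(args.results / "synergy_counts.tsv", "synergy", args.results)


if __name__ == "__main__":
    main()
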