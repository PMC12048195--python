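#!/usr/bin/env python
"""Cohort-level statistics: variant frequencies, zygosity breakdowns,
demographics, depth range — the full summary report.

Writes results/cohort_report.txt, results/per_variant.tsv and
results/summary.json; prints the report.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from pahscreen.cohort import load_packaged_cohort
from pahscreen.stats import render_report, summarize

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = load_packaged_cohort()
    summary = summarize(cohort)

    report = render_report(summary)
    (OUT / "cohort_report.txt").write_text(report)
    pd.DataFrame(summary.per_variant).to_csv(
        OUT / "per_variant.tsv", sep="\t", index=False
    )
    payload = asdict(summary)
    payload.pop("per_variant")
    (OUT / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(report)


if __name__ == "__main__":
    main()
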