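#!/usr/bin/env python
"""Paired rest vs cold-pressor comparison of the extracted biomarkers.

Reads results/biomarker_panels.csv (run analysis/02 first), pairs subjects
across conditions, and applies the study statistics: Shapiro-Wilk on the
paired differences and a paired t-test per biomarker.  Writes
results/comparison.json and prints the table.  The expected outcome under
the default conditions is the sympathetic dissociation: PRD significantly
higher under cold pressor, HRV indices and DC unchanged.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from prsaecg.pipeline import BIOMARKERS, BiomarkerPanel, compare_conditions, comparison_table

ROOT = Path(__file__).resolve().parents[1]


def panels_by_condition(df: pd.DataFrame, condition: str) -> dict:
    sub = df[df["condition"] == condition]
    return {
        int(row["subject"]): BiomarkerPanel(**{k: row[k] for k in BIOMARKERS})
        for _, row in sub.iterrows()
    }


def main() -> None:
    path = ROOT / "results" / "biomarker_panels.csv"
    if not path.exists():
        sys.exit("no panels found; run analysis/02_extract_biomarkers.py first")
    df = pd.read_csv(path)
    results = compare_conditions(
        panels_by_condition(df, "rest"), panels_by_condition(df, "stress")
    )
    (ROOT / "results" / "comparison.json").write_text(
        json.dumps([vars(r) for r in results], indent=2, default=float)
    )
    table = comparison_table(results)
    with pd.option_context("display.width", 140, "display.precision", 4):
        print(table.to_string(index=False))
    sig = [r.biomarker for r in results if r.p_value < 0.05]
    print(f"\nsignificant at p<0.05: {sig or 'none'}")


if __name__ == "__main__":
    main()
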