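#!/usr/bin/env python
"""Run the full biomarker pipeline over the simulated cohort.

Reads every recording listed in scratch/cohort/manifest.json (run
analysis/01_simulate_cohort.py first), applies preprocessing, the
tetrahedron-to-VCG transform, delineation, and the HRV / DC / PRD
extractors, and writes one row per recording to
results/biomarker_panels.csv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from prsaecg.pipeline import analyze_recording

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest_path = ROOT / "scratch" / "cohort" / "manifest.json"
    if not manifest_path.exists():
        sys.exit("no cohort found; run analysis/01_simulate_cohort.py first")
    manifest = json.loads(manifest_path.read_text())
    rows = []
    for rec in manifest:
        panel = analyze_recording(manifest_path.parent / rec["recording"])
        rows.append(
            {"subject": rec["subject"], "condition": rec["condition"],
             **panel.to_dict()}
        )
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "biomarker_panels.csv", index=False)
    print(f"analyzed {len(df)} recordings")
    print(df.groupby("condition")[["mean_rr", "hr", "lf", "hf", "dc", "prd"]]
          .mean().round(3))


if __name__ == "__main__":
    main()
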