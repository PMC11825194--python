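"""Detect dose-optimization events and summarize triggers and thresholds."""

import argparse
from pathlib import Path

from persistkit import cohort, dose_optimization, records_io

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

patients, infusions, _ = records_io.read_tables(
    args.data / "patients.csv", args.data / "infusions.csv", args.data / "tdm.csv"
)
sel = cohort.select_overall(patients, infusions)
inf = infusions[infusions["patient_id"].isin(sel.included["patient_id"])]
events = dose_optimization.detect_all(inf, patients=patients)
records_io.write_analysis_table(events, args.out / "dose_optimization_events.csv")

n_pat = events["patient_id"].nunique()
print(f"{len(events)} escalation events in {n_pat} patients "
      f"({n_pat / len(sel.included):.1%} of the included population)")
print("\nby trigger:")
print(events["trigger"].value_counts().to_string())
print(f"\nmeeting the high threshold: {int(events['meets_high'].sum())} "
      f"({events['meets_high'].mean():.1%} of low-threshold events)")
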