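"""Tipping-point quantitative bias analysis for the subgroup association.

Iteratively shortens the post-exposure persistence of dose-optimized (subset
B) patients in 25-day steps, refitting the model at each step, until the
association is no longer significant; reports the median per-patient
reduction and its 8-week-cycle equivalent.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from persistkit import bias, records_io, reporting

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--step-days", type=float, default=25.0)
args = parser.parse_args()

patients, infusions, tdm = records_io.read_tables(
    args.data / "patients.csv", args.data / "infusions.csv", args.data / "tdm.csv"
)
frame = reporting.subgroup_analysis_frame(patients, infusions, tdm)
tip = bias.tipping_point(frame, reporting.fit_subgroup_m1, step_days=args.step_days)

traj = pd.DataFrame(tip.trajectory, columns=["nominal_days", "median_achieved_days", "p_value"])
records_io.write_analysis_table(traj, args.out / "tipping_trajectory.csv")
(args.out / "tipping_point.json").write_text(json.dumps(tip.as_dict(), indent=2))

print(traj.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
if tip.tipping_median_days is None:
    print("\nassociation never lost significance on the grid")
else:
    print(
        f"\ntipping point: median post-TDM persistence reduction of "
        f"{tip.tipping_median_days:.0f} days "
        f"({tip.tipping_cycles} eight-week treatment cycles)"
    )
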