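"""End-to-end desynchrony analysis on a small synthetic cohort.

Generates raw wearable files, runs the full pipeline (binning, sleep
detection, sequential CRHR fits, pacemaker DLMO prediction, alignment),
and prints the cohort headline statistics.
"""

import tempfile
from pathlib import Path

from circwear import AlignmentConfig, CohortSpec, RunConfig
from circwear.pipeline import run_cohort, simulate_to_dir

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp)
    spec = CohortSpec(n_per_group=(2, 2, 2), days_pre=7, days_post=7, seed=3)
    raw = simulate_to_dir(spec, out)
    config = RunConfig(out_dir=out / "run", seed=1, profile="fast",
                       align=AlignmentConfig(pre_window_days=7,
                                             post_window_days=7))
    summary = run_cohort(raw, out / "metadata.csv", config)

pp = summary["pre_post"]
print(f"subjects analyzed: {summary['n_subjects']}")
print(f"% days aligned  pre {pp['mean_pre']:5.1f}  ->  post {pp['mean_post']:5.1f}"
      f"   (paired t p = {pp['paired_t_p']:.3f})")
for group, g in summary["group_shifts"]["groups"].items():
    print(f"  {group:>8} phase shift: {g['mean']:+.2f} +/- {g['sem']:.2f} h "
          f"(n={g['n']})")
if "uncertainty_data_corr" in summary:
    c = summary["uncertainty_data_corr"]
    print(f"usable-bins vs phase-uncertainty correlation: r = {c['r']:+.2f}")
# A drop in % aligned days after the event reflects internal desynchrony:
# the heart-rate phase drifting away from the activity-predicted DLMO.
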