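"""Per-animal syllable velocity, usage, and duration; usage filter and
velocity ranking; recovery check against generator ground truth."""

import numpy as np
import pandas as pd

import sylseq as q
from common import TABLES, load_or_simulate

sessions = load_or_simulate()
stats = q.cohort_stats(sessions)
uf = q.filter_by_usage(stats, min_usage=0.005)
filtered = uf.apply(stats)

TABLES.mkdir(parents=True, exist_ok=True)
stats.to_csv(TABLES / "syllable_stats.csv", index=False)

order = q.rank_by_velocity(filtered, control_group="control")
gmean = (filtered.groupby(["group", "syllable"])
         [["velocity_cm_s", "usage", "mean_duration_ms"]].mean())
gmean.to_csv(TABLES / "syllable_group_means.csv")

speeds = {g: [q.session_speed(s) for s in sessions if s.group == g]
          for g in ("control", "lesion", "lesion_treated")}
summary = q.summarize({g: np.array(v) for g, v in speeds.items()})
summary.to_csv(TABLES / "session_speed_summary.csv", index=False)

print(f"{stats['syllable'].nunique()} syllables expressed; "
      f"{len(uf.retained)} retained at >{uf.min_usage:.1%} usage "
      f"(basis: {', '.join(uf.basis)})")
print(f"velocity ranking (fastest first): {order[:6]} ...")
ctrl_dur = filtered[filtered.group == 'control']['mean_duration_ms']
print(f"control mean syllable duration {ctrl_dur.mean():.0f} ms")
for g, row in summary.set_index("group").iterrows():
    print(f"session speed {g:15s} {row['mean']:.2f} +/- {row['sem']:.2f} cm/s (n={int(row['n'])})")
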