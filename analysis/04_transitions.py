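"""Per-animal transition matrices, steady states, entropy rates, and
transition frequencies; group-averaged matrices and difference edges."""

import numpy as np
import pandas as pd

import sylseq as q
from common import TABLES, load_or_simulate

sessions = load_or_simulate()
models = {s.animal_id: q.transition_model(np.asarray(s.labels), fps=s.fps)
          for s in sessions}
group_of = {s.animal_id: s.group for s in sessions}

rows = [{"animal_id": a, "group": group_of[a], "entropy_nats": m.entropy,
         "row_entropy_sum_nats": m.row_entropy_sum,
         "transition_frequency_per_s": m.transition_frequency}
        for a, m in models.items()]
per_animal = pd.DataFrame(rows)

TABLES.mkdir(parents=True, exist_ok=True)
per_animal.to_csv(TABLES / "transition_per_animal.csv", index=False)

means, diff = q.group_transition_summary(models, group_of,
                                         pair=("control", "lesion"),
                                         threshold=0.01)
pd.DataFrame(diff.edges, columns=["from", "to", "delta_p", "sign"]).to_csv(
    TABLES / "transition_diff_control_vs_lesion.csv", index=False)

for g in ("control", "lesion", "lesion_treated"):
    sub = per_animal[per_animal.group == g]
    print(f"{g:15s} transition frequency "
          f"{sub.transition_frequency_per_s.mean():.2f} +/- "
          f"{sub.transition_frequency_per_s.sem():.2f} /s; "
          f"entropy rate {sub.entropy_nats.mean():.2f} +/- "
          f"{sub.entropy_nats.sem():.2f} nats")
n_up = sum(1 for e in diff.edges if e[3] == "up")
n_down = sum(1 for e in diff.edges if e[3] == "down")
print(f"lesion - control transition graph: {n_up} edges up, {n_down} down "
      f"(|delta| > {diff.threshold})")
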