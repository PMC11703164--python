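"""Shared study definition for the analysis scripts.

Three groups emulating the experimental design: control, lesion
(dopamine-depleted: proportional velocity loss beta=0.4, usage shift
delta=0.3, transition damping 0.8), and lesion_treated (symptomatic
treatment restoring syllable speeds but not usage/transition structure).
"""

from pathlib import Path

import sylseq as q

ROOT = Path(__file__).resolve().parent.parent
TABLES = ROOT / "results" / "tables"
DATA = ROOT / "scratch" / "data"
GROUPS = ("control", "lesion", "lesion_treated")
SEED = 20


def study_config() -> q.SimConfig:
    return q.SimConfig(
        n_syllables=20, v_min=3.0, v_max=17.0, n_animals_per_group=8,
        velocity_slope_beta=0.4, usage_shift_delta=0.3,
        transition_damping=0.8, seed=SEED,
    )


def load_or_simulate() -> list[q.LabeledSession]:
    """Reuse 01's frame table when present; otherwise resimulate (the
    cohort is fully determined by the seed either way)."""
    path = DATA / "sessions.csv"
    if path.exists():
        return q.read_frame_table(path, fps=30.0)
    return q.simulate_cohort(study_config(), groups=GROUPS).sessions
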