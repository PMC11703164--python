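import numpy as np
import pytest

from sylseq import SimConfig, simulate_cohort
from sylseq.simulate import make_skeleton_templates, SkeletonSpec


@pytest.fixture(scope="session")
def small_config():
    """Short sessions, few syllables: fast but exercises everything."""
    return SimConfig(n_syllables=6, session_length=60.0, n_animals_per_group=3, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def three_state_keypoints():
    """A labeled session with well-separated per-syllable templates."""
    cfg = SimConfig(
        n_syllables=3, session_length=120.0, mean_duration_frames=12.0,
        transition_concentration=np.inf, n_animals_per_group=1, seed=5,
    )
    cohort = simulate_cohort(cfg, groups=("control",))
    session = cohort.sessions[0]
    rng = np.random.default_rng(0)
    templates = make_skeleton_templates(3, n_keypoints=6, rng=rng, spread=1.5)
    skeleton = SkeletonSpec(templates=templates, noise_sigma=0.05)
    return session, skeleton, cfg
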