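"""Synthetic open-field cohorts with known syllable structure.

Forward model: an inter-syllable Markov chain with geometric dwell times
drives a 2-D bounded random walk whose per-frame step length is set by the
active syllable's characteristic speed.  Group effects (Parkinsonian-like
lesion, dopaminergic treatment) are applied to the generating parameters,
so every downstream estimator can be checked against ground truth.

Conventions: coordinates in cm with origin at the arena's lower-left
corner; frame indices 0-based; speeds in cm/s; dwell times in frames.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "SimConfig",
    "GroundTruth",
    "LabeledSession",
    "KeypointSession",
    "SkeletonSpec",
    "make_velocity_profile",
    "make_transition_structure",
    "apply_group_effect",
    "simulate_session",
    "simulate_keypoints",
    "simulate_cohort",
    "expected_usage",
]


class InvalidConfigError(ValueError):
    """A simulation parameter violates its documented range."""


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate the study conditions.

    20-min sessions in a 40x40 cm arena filmed at 30 fps, ~20 syllables
    spanning freezing-like (3 cm/s) to run-like (17 cm/s) speeds, mean
    dwell 12-18 frames (400-600 ms).
    """

    n_syllables: int = 20
    fps: float = 30.0
    arena_side: float = 40.0
    session_length: float = 1200.0
    n_animals_per_group: int = 8
    v_min: float = 3.0
    v_max: float = 17.0
    #: per-syllable mean dwell (frames) drawn uniformly from this range;
    #: a scalar pins every syllable to the same mean.
    mean_duration_frames: tuple[float, float] | float = (12.0, 18.0)
    #: Dirichlet concentration of the off-diagonal transition rows.
    transition_concentration: float = 5.0
    #: proportional velocity loss of the lesion group (slope of dv vs v).
    velocity_slope_beta: float = 0.0
    #: probability mass moved from the fastest to the slowest speed tercile.
    usage_shift_delta: float = 0.0
    #: lesion dwell means are divided by this (<1 means longer dwells,
    #: hence fewer syllable transitions per second).
    transition_damping: float = 1.0
    #: sd of per-frame step length noise, cm.
    step_noise_sigma: float = 0.02
    #: sd of the per-animal lognormal speed multiplier.
    animal_scale_sigma: float = 0.05
    #: sd of the per-frame heading increment, radians.
    heading_sigma: float = 0.35
    #: dwell-time law: "geometric" (memoryless, HMM-consistent) or
    #: "fixed" (every instance lasts its syllable's mean, rounded).
    dwell_law: str = "geometric"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_syllables < 2:
            raise InvalidConfigError("n_syllables must be >= 2")
        if self.fps <= 0:
            raise InvalidConfigError("fps must be positive")
        if not 0 < self.v_min < self.v_max:
            raise InvalidConfigError("require 0 < v_min < v_max")
        lo, hi = self.dwell_range
        if lo < 1:
            raise InvalidConfigError("mean_duration_frames must be >= 1")
        if hi < lo:
            raise InvalidConfigError("mean_duration_frames range inverted")
        if not 0 <= self.velocity_slope_beta < 1:
            raise InvalidConfigError("velocity_slope_beta must be in [0, 1)")
        if not 0 <= self.usage_shift_delta <= 1:
            raise InvalidConfigError("usage_shift_delta must be in [0, 1]")
        if not 0 < self.transition_damping <= 1:
            raise InvalidConfigError("transition_damping must be in (0, 1]")
        if self.arena_side <= 0 or self.step_noise_sigma < 0:
            raise InvalidConfigError("arena_side > 0 and step_noise_sigma >= 0 required")
        if self.dwell_law not in ("geometric", "fixed"):
            raise InvalidConfigError("dwell_law must be 'geometric' or 'fixed'")

    @property
    def dwell_range(self) -> tuple[float, float]:
        d = self.mean_duration_frames
        if np.isscalar(d):
            return float(d), float(d)
        lo, hi = d  # type: ignore[misc]
        return float(lo), float(hi)

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length * self.fps))


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one group: the targets every estimator is tested against."""

    speeds: np.ndarray          # (S,) cm/s, per-syllable mean speed
    transitions: np.ndarray     # (S,S) inter-syllable matrix, zero diagonal
    dwell_means: np.ndarray     # (S,) expected dwell, frames

    def __post_init__(self) -> None:
        A = np.asarray(self.transitions, float)
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-9) or np.any(np.diag(A) != 0):
            raise InvalidConfigError("transition rows must sum to 1 with zero diagonal")
        if np.any(np.asarray(self.speeds) <= 0):
            raise InvalidConfigError("speeds must be strictly positive")

    @property
    def n_syllables(self) -> int:
        return len(self.speeds)

    @property
    def usage(self) -> np.ndarray:
        """Expected fraction of frames per syllable (dwell-weighted stationary law)."""
        return expected_usage(self.transitions, self.dwell_means)


@dataclass
class LabeledSession:
    """One animal-session: centroid track plus ground-truth (or decoded) labels."""

    animal_id: str
    group: str
    fps: float
    x: np.ndarray               # (T,) cm
    y: np.ndarray               # (T,) cm
    labels: np.ndarray | None   # (T,) int syllable ids, or None if unlabeled
    arena_side: float = 40.0
    heading: np.ndarray | None = None  # (T,) rad, heading of the step into each frame

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class KeypointSession:
    """Per-frame planar keypoints for one animal (input to segmentation)."""

    animal_id: str
    fps: float
    keypoints: np.ndarray       # (T, K, 2) cm
    pixel_to_cm: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.keypoints.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.keypoints.shape[1]


@dataclass(frozen=True)
class SkeletonSpec:
    """Per-syllable rigid postural templates (centroid-centered, heading along +x)."""

    templates: np.ndarray       # (S, K, 2) cm
    noise_sigma: float = 0.0
    anterior: int = 0
    posterior: int = 1

    def __post_init__(self) -> None:
        if self.templates.ndim != 3 or self.templates.shape[1] < 2:
            raise InvalidConfigError("skeleton needs >= 2 keypoints per template")


# ---------------------------------------------------------------------------
# ground-truth construction


def make_velocity_profile(config: SimConfig) -> np.ndarray:
    """Log-spaced per-syllable mean speeds from v_min to v_max (cm/s).

    Log spacing concentrates syllables at the slow end, mirroring the
    preponderance of pause/walk-like over run-like modules.
    """
    return np.geomspace(config.v_min, config.v_max, config.n_syllables)


def make_transition_structure(
    config: SimConfig, rng: np.random.Generator
) -> GroundTruth:
    """Draw the control group's generating parameters.

    Off-diagonal transition rows are Dirichlet with concentration
    ``transition_concentration`` (infinite concentration gives uniform
    rows); dwell means are uniform over ``mean_duration_frames``.
    """
    S = config.n_syllables
    A = np.zeros((S, S))
    off = ~np.eye(S, dtype=bool)
    conc = config.transition_concentration
    for i in range(S):
        if np.isinf(conc):
            row = np.full(S - 1, 1.0 / (S - 1))
        else:
            row = rng.dirichlet(np.full(S - 1, conc))
        A[i, off[i]] = row
    lo, hi = config.dwell_range
    dwell = rng.uniform(lo, hi, size=S)
    return GroundTruth(speeds=make_velocity_profile(config), transitions=A, dwell_means=dwell)


def expected_usage(transitions: np.ndarray, dwell_means: np.ndarray) -> np.ndarray:
    """Long-run fraction of frames per syllable.

    The embedded (inter-syllable) chain has stationary law pi; time share
    weights each visit by its expected dwell: u_s = pi_s d_s / sum pi d.
    """
    A = np.asarray(transitions, float)
    # stationary law of the embedded chain by eigenvector (small S, exact)
    w, v = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    u = pi * np.asarray(dwell_means, float)
    return u / u.sum()


def apply_group_effect(truth: GroundTruth, config: SimConfig) -> GroundTruth:
    """Derive the lesion group's ground truth from the control's.

    Velocity: each syllable loses a fraction of its speed in excess of
    v_min, ``v' = v - beta (v - v_min)``, so the loss ramps from zero for
    the slowest syllable up the speed profile and the noiseless
    regression of (control - lesion) speed on control speed has slope
    exactly beta with R^2 = 1.

    Usage: a fraction ``usage_shift_delta`` of each row's incoming
    probability to fastest-tercile syllables is re-routed to
    slowest-tercile syllables (proportionally to their existing mass),
    shifting occupancy from fast to slow modules.

    Dwell: means divided by ``transition_damping`` (longer dwells, fewer
    transitions per second).
    """
    beta = config.velocity_slope_beta
    delta = config.usage_shift_delta
    if not 0 <= beta < 1 or not 0 <= delta <= 1:
        raise InvalidConfigError("beta in [0,1) and delta in [0,1] required")
    v = truth.speeds
    speeds = v - beta * (v - config.v_min)

    S = truth.n_syllables
    order = np.argsort(v)            # slow -> fast
    k = S // 3
    slow = set(order[:k].tolist())
    fast = set(order[-k:].tolist())
    A = truth.transitions.copy()
    if delta > 0 and k > 0:
        for i in range(S):
            fast_j = [j for j in fast if j != i]
            slow_j = [j for j in slow if j != i]
            moved = delta * A[i, fast_j].sum()
            if moved <= 0 or not slow_j:
                continue
            A[i, fast_j] *= 1 - delta
            w = A[i, slow_j]
            if w.sum() > 0:
                A[i, slow_j] += moved * w / w.sum()
            else:
                A[i, slow_j] += moved / len(slow_j)
        A /= A.sum(axis=1, keepdims=True)

    dwell = truth.dwell_means / config.transition_damping
    return GroundTruth(speeds=speeds, transitions=A, dwell_means=dwell)


# ---------------------------------------------------------------------------
# forward simulation (numba kernels keep whole-cohort runs cheap)


@njit(cache=True)
def _chain_labels(cum_rows, log_q, start, u_next, u_dwell, n_frames,
                  fixed_dwell, dwell_means):  # pragma: no cover
    labels = np.empty(n_frames, np.int64)
    s = start
    t = 0
    i = 0
    while t < n_frames:
        if fixed_dwell:
            d = max(1, int(round(dwell_means[s])))
        elif log_q[s] < 0.0:
            d = 1 + int(np.log(u_dwell[i]) / log_q[s])
        else:
            d = 1
        end = min(t + d, n_frames)
        for j in range(t, end):
            labels[j] = s
        t = end
        # next state from the inverse CDF of row s
        u = u_next[i]
        row = cum_rows[s]
        nxt = 0
        while row[nxt] < u:
            nxt += 1
        s = nxt
        i += 1
    return labels


@njit(cache=True)
def _bounded_walk(step_r, dheading, x0, y0, h0, side):  # pragma: no cover
    n = step_r.size
    x = np.empty(n + 1)
    y = np.empty(n + 1)
    head = np.empty(n + 1)
    x[0], y[0], head[0] = x0, y0, h0
    h = h0
    for t in range(n):
        h += dheading[t]
        dx = step_r[t] * np.cos(h)
        dy = step_r[t] * np.sin(h)
        # reflect the step vector (not the position): keeps |step| exact
        if x[t] + dx < 0.0 or x[t] + dx > side:
            dx = -dx
        if y[t] + dy < 0.0 or y[t] + dy > side:
            dy = -dy
        if step_r[t] > 0.0:
            h = np.arctan2(dy, dx)
        x[t + 1] = x[t] + dx
        y[t + 1] = y[t] + dy
        head[t + 1] = h
    return x, y, head


def simulate_session(
    truth: GroundTruth,
    config: SimConfig,
    animal_seed: int,
    animal_id: str = "a0",
    group: str = "control",
) -> LabeledSession:
    """Simulate one labeled session.

    The syllable chain is an inter-syllable Markov chain with geometric
    dwells; the step into frame t has length Normal(speed[label_t]/fps,
    step_noise_sigma) clipped at zero, heading follows a persistent
    random walk, and steps that would leave the arena are reflected off
    the wall with their length preserved.
    """
    n_frames = config.n_frames
    if n_frames < 2:
        raise InvalidConfigError("session must span at least 2 frames")
    rng = np.random.default_rng(animal_seed)

    cum_rows = np.cumsum(truth.transitions, axis=1)
    cum_rows[:, -1] = 1.0
    q = 1.0 - 1.0 / np.maximum(truth.dwell_means, 1.0)
    log_q = np.where(q > 0, np.log(np.maximum(q, 1e-300)), 0.0)
    start = int(rng.choice(truth.n_syllables, p=_embedded_stationary(truth.transitions)))
    u_next = rng.random(n_frames)
    u_dwell = rng.random(n_frames)
    labels = _chain_labels(cum_rows, log_q, start, u_next, u_dwell, n_frames,
                           config.dwell_law == "fixed",
                           np.asarray(truth.dwell_means, float))

    scale = float(rng.lognormal(mean=0.0, sigma=config.animal_scale_sigma))
    mean_step = truth.speeds[labels[1:]] * scale / config.fps
    step_r = np.maximum(
        0.0, rng.normal(mean_step, config.step_noise_sigma)
    ) if config.step_noise_sigma > 0 else mean_step.copy()

    dheading = rng.normal(0.0, config.heading_sigma, size=n_frames - 1)
    margin = 0.02 * config.arena_side
    x0, y0 = rng.uniform(margin, config.arena_side - margin, size=2)
    h0 = rng.uniform(-np.pi, np.pi)
    x, y, head = _bounded_walk(step_r, dheading, x0, y0, h0, config.arena_side)

    return LabeledSession(
        animal_id=animal_id, group=group, fps=config.fps,
        x=x, y=y, labels=labels, arena_side=config.arena_side, heading=head,
    )


def _embedded_stationary(A: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.abs(np.real(v[:, i]))
    return pi / pi.sum()


def make_skeleton_templates(
    n_syllables: int,
    n_keypoints: int = 6,
    rng: np.random.Generator | None = None,
    body_length: float = 6.0,
    spread: float = 1.0,
) -> np.ndarray:
    """Random per-syllable postural templates.

    Keypoint 0 is the anterior (nose) and keypoint 1 the posterior
    (tail-base), placed on the body axis; remaining keypoints get
    syllable-specific jittered positions so distinct syllables have
    distinct aligned poses.  Templates are centroid-centered.
    """
    if n_keypoints < 2:
        raise InvalidConfigError("need at least 2 keypoints")
    rng = np.random.default_rng(0) if rng is None else rng
    T = np.zeros((n_syllables, n_keypoints, 2))
    T[:, 0] = (body_length / 2, 0.0)
    T[:, 1] = (-body_length / 2, 0.0)
    for s in range(n_syllables):
        for k in range(2, n_keypoints):
            along = rng.uniform(-body_length / 2, body_length / 2)
            T[s, k] = (along, rng.normal(0.0, spread))
    T -= T.mean(axis=1, keepdims=True)
    return T


def simulate_keypoints(session: LabeledSession, skeleton: SkeletonSpec,
                       seed: int = 0) -> KeypointSession:
    """Place per-syllable templates at the session's centroid/heading.

    Each frame's keypoints are the active syllable's template rotated to
    the frame heading, translated to the centroid, plus isotropic
    Gaussian noise of sd ``skeleton.noise_sigma``.
    """
    if skeleton.templates.shape[1] < 2:
        raise InvalidConfigError("need at least 2 keypoints")
    if session.labels is None:
        raise InvalidConfigError("session must carry syllable labels")
    h = session.heading
    if h is None:
        dx = np.diff(session.x)
        dy = np.diff(session.y)
        h = np.zeros(session.n_frames)
        ang = np.arctan2(dy, dx)
        moved = np.hypot(dx, dy) > 0
        last = 0.0
        for t in range(1, session.n_frames):
            if moved[t - 1]:
                last = ang[t - 1]
            h[t] = last
        h[0] = h[1]
    c, s = np.cos(h), np.sin(h)
    rot = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], -2)  # (T,2,2)
    temp = skeleton.templates[session.labels]                          # (T,K,2)
    kps = np.einsum("tij,tkj->tki", rot, temp)
    kps[..., 0] += session.x[:, None]
    kps[..., 1] += session.y[:, None]
    if skeleton.noise_sigma > 0:
        kps = kps + np.random.default_rng(seed).normal(0, skeleton.noise_sigma, kps.shape)
    return KeypointSession(animal_id=session.animal_id, fps=session.fps, keypoints=kps)


# ---------------------------------------------------------------------------
# cohorts


def animal_seed(master_seed: int, group: str, index: int) -> int:
    """Stable, collision-resistant per-animal seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{group}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class Cohort:
    sessions: list[LabeledSession]
    truths: dict[str, GroundTruth]
    config: SimConfig

    def group_sessions(self, group: str) -> list[LabeledSession]:
        return [s for s in self.sessions if s.group == group]


def simulate_cohort(
    config: SimConfig,
    groups: tuple[str, ...] = ("control", "lesion"),
) -> Cohort:
    """Simulate n_animals_per_group sessions per group.

    ``control`` uses the base ground truth; ``lesion`` applies the
    configured velocity/usage/damping effects; ``lesion_treated``
    models symptomatic dopaminergic treatment: control speeds restored,
    but lesion usage structure and dwells retained.
    """
    rng = np.random.default_rng(config.seed)
    control = make_transition_structure(config, rng)
    lesion = apply_group_effect(control, config)
    truths: dict[str, GroundTruth] = {}
    for g in groups:
        if g == "control":
            truths[g] = control
        elif g == "lesion":
            truths[g] = lesion
        elif g == "lesion_treated":
            truths[g] = replace(lesion, speeds=control.speeds.copy())
        else:
            raise InvalidConfigError(f"unknown group '{g}'")
    sessions = []
    for g in groups:
        for i in range(config.n_animals_per_group):
            sid = animal_seed(config.seed, g, i)
            sessions.append(
                simulate_session(truths[g], config, sid, animal_id=f"{g}_{i:02d}", group=g)
            )
    return Cohort(sessions=sessions, truths=truths, config=config)
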