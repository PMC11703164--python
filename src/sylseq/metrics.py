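"""Per-animal syllable kinematics and expression.

Velocity of a syllable is the mean frame-to-frame centroid displacement
over all frames assigned to it, scaled to cm/s; usage is the fraction of
session frames (time share, not instance share); durations come from
run-length encoding of the label sequence.  Rarely expressed syllables
are dropped by a group-level usage threshold (default 0.5% of time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import LabeledSession

__all__ = [
    "run_length_encode",
    "syllable_velocity",
    "session_speed",
    "syllable_usage",
    "syllable_durations",
    "session_stats",
    "cohort_stats",
    "filter_by_usage",
    "rank_by_velocity",
    "UsageFilter",
]


class InvalidInputError(ValueError):
    pass


def run_length_encode(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal labels as (syllable, start_frame, length)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidInputError("empty label sequence")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _displacements(session: LabeledSession) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-frame displacement magnitudes for frames 1..T-1.

    Returns (disp, valid_mask, n_skipped): frames with missing coordinates
    on either end of the step are masked out and counted, never
    interpolated.
    """
    x, y = np.asarray(session.x, float), np.asarray(session.y, float)
    if x.size < 2:
        raise InvalidInputError("need at least 2 frames")
    ok = np.isfinite(x) & np.isfinite(y)
    disp = np.hypot(np.diff(x), np.diff(y))
    valid = ok[1:] & ok[:-1]
    return disp, valid, int((~valid).sum())


def syllable_velocity(session: LabeledSession) -> tuple[dict[int, float], dict]:
    """Mean per-syllable speed (cm/s) and a QC report.

    The step into frame t is attributed to the syllable active at t; the
    first frame contributes no displacement.
    """
    if session.labels is None:
        raise InvalidInputError("session has no syllable labels")
    disp, valid, n_skipped = _displacements(session)
    lab = np.asarray(session.labels)[1:]
    out: dict[int, float] = {}
    for s in np.unique(np.asarray(session.labels)):
        m = (lab == s) & valid
        out[int(s)] = float(disp[m].mean() * session.fps) if m.any() else np.nan
    qc = {"n_frames": session.n_frames, "n_skipped_steps": n_skipped}
    return out, qc


def session_speed(session: LabeledSession) -> float:
    """Total distance traveled divided by session duration (cm/s)."""
    disp, valid, _ = _displacements(session)
    return float(disp[valid].sum() / session.duration_s)


def syllable_usage(session: LabeledSession) -> dict[int, float]:
    """Fraction of frames spent in each syllable; sums to 1."""
    if session.labels is None:
        raise InvalidInputError("session has no syllable labels")
    lab = np.asarray(session.labels)
    lab = lab[lab >= 0]
    if lab.size == 0:
        raise InvalidInputError("no labeled frames")
    ids, counts = np.unique(lab, return_counts=True)
    return {int(s): float(c) / lab.size for s, c in zip(ids, counts)}


def syllable_durations(
    session: LabeledSession,
) -> tuple[dict[int, float], dict[int, int], float]:
    """Mean instance duration (ms) and instance count per syllable.

    Returns (mean_duration_ms, n_instances, overall_mean_ms) where the
    overall mean is across all instances regardless of syllable.
    """
    if session.labels is None:
        raise InvalidInputError("session has no syllable labels")
    rle = run_length_encode(session.labels)
    per_ms = 1000.0 / session.fps
    lens: dict[int, list[int]] = {}
    for s, _, ln in rle:
        lens.setdefault(s, []).append(ln)
    mean_ms = {s: float(np.mean(v) * per_ms) for s, v in lens.items()}
    counts = {s: len(v) for s, v in lens.items()}
    overall = float(np.mean([ln for _, _, ln in rle]) * per_ms)
    return mean_ms, counts, overall


def session_stats(session: LabeledSession) -> pd.DataFrame:
    """One row per syllable expressed in this session."""
    vel, _ = syllable_velocity(session)
    use = syllable_usage(session)
    dur, counts, _ = syllable_durations(session)
    rows = [
        {
            "animal_id": session.animal_id,
            "group": session.group,
            "syllable": s,
            "velocity_cm_s": vel.get(s, np.nan),
            "usage": use[s],
            "mean_duration_ms": dur[s],
            "n_instances": counts[s],
        }
        for s in sorted(use)
    ]
    return pd.DataFrame(rows)


def cohort_stats(sessions: list[LabeledSession]) -> pd.DataFrame:
    """Stack per-session syllable stats into one animal x syllable table."""
    if not sessions:
        raise InvalidInputError("no sessions")
    return pd.concat([session_stats(s) for s in sessions], ignore_index=True)


@dataclass(frozen=True)
class UsageFilter:
    min_usage: float
    retained: tuple[int, ...]
    basis: tuple[str, ...]      # groups whose mean usage was tested

    def apply(self, stats: pd.DataFrame) -> pd.DataFrame:
        return stats[stats["syllable"].isin(self.retained)].reset_index(drop=True)


def filter_by_usage(stats: pd.DataFrame, min_usage: float = 0.005) -> UsageFilter:
    """Retain syllables whose group-mean usage exceeds the threshold in >= 1 group.

    Absent animal-syllable combinations count as zero usage in the group
    mean, so a syllable expressed by a single animal cannot sneak past
    the threshold.
    """
    groups = tuple(sorted(stats["group"].unique()))
    syllables = sorted(stats["syllable"].unique())
    retained = []
    for s in syllables:
        for g in groups:
            sub = stats[stats["group"] == g]
            n_animals = sub["animal_id"].nunique()
            tot = sub.loc[sub["syllable"] == s, "usage"].sum()
            if n_animals and tot / n_animals > min_usage:
                retained.append(int(s))
                break
    return UsageFilter(min_usage=min_usage, retained=tuple(retained), basis=groups)


def rank_by_velocity(stats: pd.DataFrame, control_group: str = "control") -> list[int]:
    """Syllables ordered by descending control-group mean velocity (ties: id asc)."""
    sub = stats[stats["group"] == control_group]
    if sub.empty:
        raise InvalidInputError(f"no rows for group '{control_group}'")
    mv = sub.groupby("syllable")["velocity_cm_s"].mean()
    order = sorted(mv.index, key=lambda s: (-mv[s], s))
    return [int(s) for s in order]
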