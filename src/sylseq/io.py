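"""File formats, run configuration, and pipeline orchestration.

Frame tables are plain CSV (comma, UTF-8, '.' decimal, header row) with
columns ``frame, x_cm, y_cm, syllable, animal_id, group``; keypoint
tables add ``kp{i}_x, kp{i}_y`` pairs.  Frame indices are 0-based and
consecutive per animal; coordinates are cm from the arena's lower-left
corner.  Every pipeline run writes a manifest with the config snapshot,
seed, and a checksum per output file, so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as met
from . import stats as st
from . import transitions as tr
from .segmentation import ARHMMHyperparams, ARHMMModel
from .simulate import Cohort, LabeledSession, KeypointSession, SimConfig, simulate_cohort

__all__ = [
    "AnalysisConfig",
    "SchemaError",
    "read_frame_table",
    "write_frame_table",
    "read_keypoint_table",
    "write_keypoint_table",
    "save_model",
    "load_model",
    "run_pipeline",
]

log = logging.getLogger("sylseq")

REQUIRED_COLUMNS = ("frame", "x_cm", "y_cm", "animal_id", "group")


class SchemaError(ValueError):
    pass


class ContinuityError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    output_dir: str = "results/run"
    input_path: str | None = None       # frame table CSV; None -> simulate
    groups: tuple[str, ...] = ("control", "lesion")
    control_group: str = "control"
    lesion_group: str = "lesion"
    usage_min: float = 0.005
    fdr_q: float = 0.05
    target_duration_ms: float = 400.0
    kappa_grid: tuple[float, ...] = (1e2, 1e3, 1e4, 1e5)
    alpha: float = 5.7
    gamma: float = 1e3
    max_states: int = 100
    n_iter: int = 200
    seed: int = 0
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.usage_min < 1 or not 0 < self.fdr_q < 1:
            raise ValueError("usage_min in [0,1) and fdr_q in (0,1) required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["kappa_grid"] = list(self.kappa_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if isinstance(sim.get("mean_duration_frames"), list):
                sim["mean_duration_frames"] = tuple(sim["mean_duration_frames"])
            d["sim"] = SimConfig(**sim)
        for k in ("groups", "kappa_grid"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hyperparams(self) -> ARHMMHyperparams:
        return ARHMMHyperparams(alpha=self.alpha, gamma=self.gamma,
                                max_states=self.max_states, n_iter=self.n_iter)


# ---------------------------------------------------------------------------
# frame tables


def write_frame_table(sessions: list[LabeledSession], path: str | Path) -> None:
    frames = []
    for s in sessions:
        df = pd.DataFrame({
            "frame": np.arange(s.n_frames),
            "x_cm": s.x,
            "y_cm": s.y,
            "syllable": s.labels if s.labels is not None else np.full(s.n_frames, -1),
            "animal_id": s.animal_id,
            "group": s.group,
        })
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_frame_table(
    path: str | Path, fps: float = 30.0, arena_side: float = 40.0, strict: bool = True
) -> list[LabeledSession]:
    """One LabeledSession per animal_id; validates schema and continuity."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    sessions = []
    for aid, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            msg = f"animal {aid}: frame indices not consecutive from 0"
            if strict:
                raise ContinuityError(msg)
            log.warning(msg)
        labels = None
        if "syllable" in sub.columns:
            lab = sub["syllable"].to_numpy()
            if not (pd.isna(lab).all() or (lab == -1).all()):
                labels = np.where(pd.isna(lab), -1, lab).astype(np.int64)
        sessions.append(LabeledSession(
            animal_id=str(aid), group=str(sub["group"].iloc[0]), fps=fps,
            x=sub["x_cm"].to_numpy(float), y=sub["y_cm"].to_numpy(float),
            labels=labels, arena_side=arena_side,
        ))
    return sessions


def write_keypoint_table(session: KeypointSession, path: str | Path) -> None:
    T, K, _ = session.keypoints.shape
    data = {"frame": np.arange(T), "animal_id": session.animal_id}
    for k in range(K):
        data[f"kp{k}_x"] = session.keypoints[:, k, 0]
        data[f"kp{k}_y"] = session.keypoints[:, k, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def read_keypoint_table(path: str | Path, fps: float = 30.0,
                        pixel_to_cm: float = 1.0) -> KeypointSession:
    df = pd.read_csv(path)
    ks = sorted(
        {int(c[2:-2]) for c in df.columns if c.startswith("kp") and c.endswith("_x")}
    )
    if len(ks) < 2:
        raise SchemaError("need kp{i}_x/kp{i}_y columns for >= 2 keypoints")
    kps = np.stack(
        [np.stack([df[f"kp{k}_x"], df[f"kp{k}_y"]], axis=-1) for k in ks], axis=1
    ).astype(float)
    aid = str(df["animal_id"].iloc[0]) if "animal_id" in df.columns else "unknown"
    return KeypointSession(animal_id=aid, fps=fps, keypoints=kps * pixel_to_cm,
                           pixel_to_cm=pixel_to_cm)


# ---------------------------------------------------------------------------
# model archive


def save_model(model: ARHMMModel, path: str | Path) -> None:
    np.savez(
        path,
        ar_coefs=model.ar_coefs, offsets=model.offsets,
        noise_covs=model.noise_covs, transitions=model.transitions,
        loglik_trace=model.loglik_trace, active_states=model.active_states,
        kappa=model.kappa, seed=model.seed,
        hyperparams=json.dumps(dataclasses.asdict(model.hyperparams)),
    )


def load_model(path: str | Path) -> ARHMMModel:
    z = np.load(path, allow_pickle=False)
    hp = ARHMMHyperparams(**json.loads(str(z["hyperparams"])))
    return ARHMMModel(
        ar_coefs=z["ar_coefs"], offsets=z["offsets"], noise_covs=z["noise_covs"],
        transitions=z["transitions"], kappa=float(z["kappa"]), hyperparams=hp,
        seed=int(z["seed"]), loglik_trace=z["loglik_trace"],
        active_states=z["active_states"],
    )


# ---------------------------------------------------------------------------
# pipeline


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: AnalysisConfig) -> dict:
    """simulate/load -> metrics -> transitions -> stats -> report.

    Deterministic given the master seed.  Returns a summary dict; all
    tables, the report, and a checksum manifest land in ``output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_path is None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort = simulate_cohort(sim, groups=config.groups)
        sessions = cohort.sessions
        log.info("simulated %d sessions in %d groups", len(sessions), len(config.groups))
        write_frame_table(sessions, out / "sessions.csv")
    else:
        sessions = read_frame_table(config.input_path, fps=config.sim.fps,
                                    arena_side=config.sim.arena_side)
        log.info("loaded %d sessions from %s", len(sessions), config.input_path)
    if any(s.labels is None for s in sessions):
        raise ValueError(
            "sessions lack syllable labels: run the 'segment' stage on keypoint "
            "data (or supply a 'syllable' column) before computing metrics"
        )

    # metrics
    stats_tbl = met.cohort_stats(sessions)
    stats_tbl.to_csv(out / "syllable_stats.csv", index=False)
    uf = met.filter_by_usage(stats_tbl, min_usage=config.usage_min)
    filtered = uf.apply(stats_tbl)
    speeds = {s.animal_id: met.session_speed(s) for s in sessions}
    group_of = {s.animal_id: s.group for s in sessions}

    # transitions (per-animal, on the usage-retained syllable set)
    models = {}
    for s in sessions:
        keep = np.isin(s.labels, uf.retained)
        models[s.animal_id] = tr.transition_model(
            np.asarray(s.labels)[keep], fps=s.fps
        )
    trans_rows = []
    for aid, m in models.items():
        for i, si in enumerate(m.syllables):
            for j, sj in enumerate(m.syllables):
                if m.A[i, j] > 0:
                    trans_rows.append({"animal_id": aid, "from": int(si),
                                       "to": int(sj), "prob": m.A[i, j]})
    pd.DataFrame(trans_rows).to_csv(out / "transition_matrices.csv", index=False)
    tsum = {
        aid: {"entropy": m.entropy, "row_entropy_sum": m.row_entropy_sum,
              "transition_frequency": m.transition_frequency,
              "group": group_of[aid]}
        for aid, m in models.items()
    }
    (out / "transition_summary.json").write_text(json.dumps(tsum, indent=1))

    g1, g2 = config.control_group, config.lesion_group
    have_pair = g1 in config.groups and g2 in config.groups
    if have_pair:
        _, diff = tr.group_transition_summary(models, group_of, pair=(g1, g2))
        pd.DataFrame(diff.edges, columns=["from", "to", "delta", "sign"]).to_csv(
            out / "transition_diff_edges.csv", index=False
        )

    # group statistics
    summary: dict = {"n_sessions": len(sessions), "retained_syllables": list(uf.retained)}
    cmp_frames = []
    for metric in ("velocity", "usage"):
        cmp = st.compare_metric(filtered, metric, q=config.fdr_q, groups=list(config.groups))
        cmp.to_csv(out / f"comparison_{metric}.csv", index=False)
        cmp_frames.append(cmp)
        summary[f"n_significant_{metric}"] = int(cmp["significant"].sum())
    if have_pair:
        vel = cmp_frames[0]
        for metric, cmp in zip(("velocity", "usage"), cmp_frames):
            reg = st.delta_regression(
                cmp[f"mean_{g1}"], cmp[f"mean_{g2}"], vel[f"mean_{g1}"], metric=metric
            )
            summary[f"delta_{metric}_slope"] = reg.slope
            summary[f"delta_{metric}_r2"] = reg.r_squared
            summary[f"delta_{metric}_p"] = reg.p_value
        for name, per_animal in (
            ("session_speed", speeds),
            ("transition_frequency",
             {a: m.transition_frequency for a, m in models.items()}),
            ("entropy", {a: m.entropy for a, m in models.items()}),
        ):
            va = [v for a, v in per_animal.items() if group_of[a] == g1]
            vb = [v for a, v in per_animal.items() if group_of[a] == g2]
            u, p = st.mann_whitney(va, vb)
            summary[f"{name}_{g1}_mean"] = float(np.mean(va))
            summary[f"{name}_{g2}_mean"] = float(np.mean(vb))
            summary[f"{name}_mwu_p"] = p
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    _write_report(out, config, uf, summary, cmp_frames)
    config.to_yaml(out / "config.yaml")
    manifest = {
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.name != "manifest.json" and p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary


def _write_report(out: Path, config: AnalysisConfig, uf, summary, cmp_frames) -> None:
    lines = [
        "# Syllable analysis report",
        "",
        f"Sessions: {summary['n_sessions']}; retained syllables "
        f"(group-mean usage > {config.usage_min:g} in >= 1 group): "
        f"{summary['retained_syllables']}",
        "",
        "Omnibus Kruskal-Wallis p-values are BH-adjusted across syllables "
        "within each metric; Dunn pairwise p-values are reported uncorrected.",
        "",
    ]
    for metric, cmp in zip(("velocity", "usage"), cmp_frames):
        sig = cmp.loc[cmp["significant"], "syllable"].tolist()
        lines.append(f"## {metric}: {len(sig)} significant syllables at q={config.fdr_q:g}")
        lines.append(f"syllables: {sig}")
        key = f"delta_{metric}_slope"
        if key in summary:
            lines.append(
                f"delta-{metric} vs control velocity: slope {summary[key]:.4f}, "
                f"R^2 {summary[f'delta_{metric}_r2']:.3f}, "
                f"p {summary[f'delta_{metric}_p']:.2e}"
            )
        lines.append("")
    for name in ("session_speed", "transition_frequency", "entropy"):
        k = f"{name}_mwu_p"
        if k in summary:
            g1, g2 = config.control_group, config.lesion_group
            lines.append(
                f"{name}: {g1} {summary[f'{name}_{g1}_mean']:.3f} vs "
                f"{g2} {summary[f'{name}_{g2}_mean']:.3f} (MWU p={summary[k]:.4g})"
            )
    (out / "report.md").write_text("\n".join(lines) + "\n")
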