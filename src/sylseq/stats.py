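"""Group-comparison layer: Kruskal-Wallis with Dunn's post-hoc,
Benjamini-Hochberg FDR across syllables, Mann-Whitney U for scalar
measures, delta-vs-velocity regressions, and mean +/- SEM summaries.

For small untied samples (combined n <= 10 for KW/Dunn, <= 12 for MWU)
exact enumeration over group assignments replaces the asymptotic
approximations, so p-values are exact where cohort sizes permit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import InvalidInputError

__all__ = [
    "kruskal_dunn",
    "bh_adjust",
    "mann_whitney",
    "delta_regression",
    "summarize",
    "compare_metric",
    "DeltaRegression",
    "KruskalDunnResult",
]

_EXACT_KW_N = 10
_EXACT_MWU_N = 12


@dataclass
class KruskalDunnResult:
    H: float
    p: float
    #: (group_i, group_j) -> (z, two-sided p); Dunn pairwise contrasts
    dunn: dict[tuple[int, int], tuple[float, float]]
    method: str     # "exact" or "asymptotic"


def _kw_h(ranks_by_group: list[np.ndarray], N: int, tie_term: float) -> float:
    s = sum(len(r) * np.mean(r) ** 2 for r in ranks_by_group)
    H = 12.0 / (N * (N + 1)) * s - 3 * (N + 1)
    return H / tie_term if tie_term > 0 else 0.0


def _dunn_z(ranks_by_group: list[np.ndarray], N: int, tie_corr: float) -> dict:
    out = {}
    for i, j in itertools.combinations(range(len(ranks_by_group)), 2):
        ri, rj = ranks_by_group[i], ranks_by_group[j]
        se = np.sqrt((N * (N + 1) / 12.0 - tie_corr) * (1.0 / len(ri) + 1.0 / len(rj)))
        z = (np.mean(ri) - np.mean(rj)) / se if se > 0 else 0.0
        out[(i, j)] = z
    return out


def _tie_stats(pooled: np.ndarray) -> tuple[float, float]:
    """(H tie-correction divisor, Dunn tie variance term)."""
    N = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    t3 = float(np.sum(counts**3 - counts))
    return 1.0 - t3 / (N**3 - N), t3 / (12.0 * (N - 1))


def kruskal_dunn(groups: list[np.ndarray], method: str = "auto") -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn pairwise contrasts.

    ``method='auto'`` uses exact enumeration over all group assignments
    when the combined untied sample has n <= 10, otherwise the chi-square
    approximation for H and two-sided normal p for Dunn z.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InvalidInputError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    N = pooled.size
    has_ties = np.unique(pooled).size < N
    exact = method == "exact" or (method == "auto" and N <= _EXACT_KW_N and not has_ties)

    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    by_group = [ranks[bounds[k]:bounds[k + 1]] for k in range(len(groups))]
    tie_div, tie_var = _tie_stats(pooled)
    H_obs = _kw_h(by_group, N, tie_div)
    z_obs = _dunn_z(by_group, N, tie_var)

    if exact:
        p, dunn_p = _enumerate_exact(sizes, N, H_obs, z_obs)
        dunn = {k: (z_obs[k], dunn_p[k]) for k in z_obs}
        return KruskalDunnResult(H=H_obs, p=p, dunn=dunn, method="exact")

    df = len(groups) - 1
    p = float(sps.chi2.sf(H_obs, df))
    if H_obs == 0.0:
        p = 1.0
    dunn = {k: (z, float(2 * sps.norm.sf(abs(z)))) for k, z in z_obs.items()}
    return KruskalDunnResult(H=H_obs, p=p, dunn=dunn, method="asymptotic")


def _enumerate_exact(sizes, N, H_obs, z_obs):
    """Exact permutation p for H and |z| over all distinct assignments of
    ranks 1..N to groups of the observed sizes (untied data only)."""
    all_ranks = np.arange(1, N + 1, dtype=float)
    n_ge = 0
    n_tot = 0
    z_ge = {k: 0 for k in z_obs}
    eps = 1e-12

    def assignments(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in assignments(rest, sizes_left[1:]):
                yield [np.array(combo, float)] + tail

    for groups_r in assignments(tuple(all_ranks), list(sizes)):
        n_tot += 1
        if _kw_h(groups_r, N, 1.0) >= H_obs - eps:
            n_ge += 1
        zs = _dunn_z(groups_r, N, 0.0)
        for k in z_obs:
            if abs(zs[k]) >= abs(z_obs[k]) - eps:
                z_ge[k] += 1
    p = n_ge / n_tot
    dunn_p = {k: z_ge[k] / n_tot for k in z_obs}
    return p, dunn_p


def bh_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, reject flags at FDR q)."""
    p = np.asarray(pvals, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    rej = np.zeros_like(p, dtype=bool)
    if ok.any():
        r, a, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adj[ok], rej[ok] = a, r
    return adj, rej


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (statistic of the first sample) and two-sided p.

    Exact null distribution for combined n <= 12 without ties; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_MWU_N and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DeltaRegression:
    """OLS of the group difference (control - lesion) on control velocity."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    metric: str = ""


def delta_regression(
    control_means, lesion_means, control_velocity, metric: str = "velocity"
) -> DeltaRegression:
    """Regress delta = control - lesion (per syllable) on control velocity."""
    x = np.asarray(control_velocity, float)
    y = np.asarray(control_means, float) - np.asarray(lesion_means, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InvalidInputError("need >= 3 syllables for the regression")
    if np.ptp(y[ok]) == 0.0:    # constant delta: slope 0 by convention
        return DeltaRegression(slope=0.0, intercept=float(y[ok][0]),
                               r_squared=0.0, p_value=1.0,
                               n=int(ok.sum()), metric=metric)
    res = sps.linregress(x[ok], y[ok])
    return DeltaRegression(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
        n=int(ok.sum()), metric=metric,
    )


def summarize(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """mean, SD, SEM = SD/sqrt(n), and n per group."""
    rows = []
    for g, v in values_by_group.items():
        v = np.asarray(v, float)
        if v.size == 0:
            raise InvalidInputError(f"group '{g}' is empty")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        rows.append({"group": g, "mean": float(np.mean(v)), "sd": sd,
                     "sem": sd / np.sqrt(v.size), "n": int(v.size)})
    return pd.DataFrame(rows)


def compare_metric(
    stats: pd.DataFrame,
    metric: str,
    q: float = 0.05,
    groups: list[str] | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-syllable group comparison of one metric with BH correction.

    For each syllable, animals' values are compared across groups by
    Kruskal-Wallis (Dunn pairwise z/p attached); omnibus p-values are
    BH-adjusted across syllables within this metric.  Syllables where
    any group has < 2 values are skipped with a warning column.
    """
    col = {"velocity": "velocity_cm_s", "usage": "usage"}.get(metric, metric)
    if groups is None:
        groups = sorted(stats["group"].unique())
    animals = {g: sorted(stats.loc[stats["group"] == g, "animal_id"].unique())
               for g in groups}
    rows = []
    for s in sorted(stats["syllable"].unique()):
        sub = stats[stats["syllable"] == s]
        vals = []
        for g in groups:
            # absent animal-syllable combinations are true zeros for usage,
            # undefined for velocity
            gv = sub[sub["group"] == g].set_index("animal_id")[col]
            if metric == "usage":
                v = np.array([float(gv.get(a, 0.0)) for a in animals[g]])
            else:
                v = gv.dropna().to_numpy(float)
            vals.append(v)
        row: dict = {"syllable": int(s), "metric": metric}
        for g, v in zip(groups, vals):
            sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
            row[f"mean_{g}"] = float(np.mean(v)) if v.size else np.nan
            row[f"sem_{g}"] = sd / np.sqrt(v.size) if v.size > 1 else np.nan
            row[f"n_{g}"] = int(v.size)
        if any(v.size < 2 for v in vals):
            row.update({"H": np.nan, "p_raw": np.nan, "skipped": True})
        else:
            kd = kruskal_dunn(vals, method=method)
            row.update({"H": kd.H, "p_raw": kd.p, "skipped": False})
            for (i, j), (z, pz) in kd.dunn.items():
                row[f"dunn_z_{groups[i]}_vs_{groups[j]}"] = z
                row[f"dunn_p_{groups[i]}_vs_{groups[j]}"] = pz
        rows.append(row)
    out = pd.DataFrame(rows)
    adj, rej = bh_adjust(out["p_raw"].to_numpy(), q=q)
    out["p_adj"] = adj
    out["significant"] = rej
    return out
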