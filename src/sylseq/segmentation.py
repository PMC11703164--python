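"""Pose-dynamics segmentation: egocentric alignment, PCA, and a sticky
autoregressive hidden Markov model (AR-HMM).

Keypoint series are first stripped of location and heading (egocentric
alignment), reduced to a small number of principal-component scores, and
then segmented by a sticky AR(1)-HMM fitted with blocked Gibbs sampling:
state-specific autoregressive dynamics + noise covariance are drawn from
their matrix-normal-inverse-Wishart conditionals, transition rows from
Dirichlet conditionals with an extra ``kappa`` mass on the diagonal (the
weak-limit sticky construction, truncated at ``max_states``), and the
state sequence by forward-filter backward-sampling.  Decoding uses the
Viterbi path, so downstream statistics are deterministic given a model.

The stickiness hyperparameter kappa controls syllable duration; the
kappa scan picks the value whose decoded median duration best matches a
target (default 400 ms, ~12 frames at 30 fps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.stats as sps
from numba import njit
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .metrics import InvalidInputError, run_length_encode
from .simulate import KeypointSession

__all__ = [
    "ARHMMHyperparams",
    "ARHMMModel",
    "PoseScores",
    "KappaScanResult",
    "egocentric_align",
    "fit_pca",
    "fit_arhmm",
    "decode_labels",
    "kappa_scan",
    "select_kappa",
    "match_labels",
]


class ScanFailedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# alignment


def egocentric_align(
    session: KeypointSession | np.ndarray,
    anterior: int = 0,
    posterior: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Remove location and heading from a keypoint series.

    Each frame is translated so the keypoint centroid sits at the origin
    and rotated so the posterior->anterior body axis points along +x.
    Returns (aligned (T,K,2), centroid (T,2), heading (T,), degenerate
    flags).  Frames where the two axis keypoints coincide have no
    defined heading: the previous frame's heading is carried forward and
    the frame is flagged.
    """
    kps = session.keypoints if isinstance(session, KeypointSession) else np.asarray(session, float)
    if kps.ndim != 3 or kps.shape[1] < 2:
        raise InvalidInputError("expected (T, K>=2, 2) keypoints")
    K = kps.shape[1]
    if anterior == posterior or not (0 <= anterior < K and 0 <= posterior < K):
        raise InvalidInputError("anterior/posterior indices must be valid and distinct")
    centroid = kps.mean(axis=1)
    centered = kps - centroid[:, None, :]
    axis = kps[:, anterior] - kps[:, posterior]
    norm = np.hypot(axis[:, 0], axis[:, 1])
    degenerate = norm < 1e-12
    heading = np.arctan2(axis[:, 1], axis[:, 0])
    last = 0.0
    for t in range(len(heading)):   # carry heading through degenerate frames
        if degenerate[t]:
            heading[t] = last
        else:
            last = heading[t]
    c, s = np.cos(heading), np.sin(heading)
    # rotate by -heading: body axis lands on +x
    rot = np.stack([np.stack([c, s], -1), np.stack([-s, c], -1)], -2)
    aligned = np.einsum("tij,tkj->tki", rot, centered)
    return aligned, centroid, heading, degenerate


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PoseScores:
    scores: np.ndarray                   # (T, D)
    loadings: np.ndarray                 # (D, n_features), orthonormal rows
    mean: np.ndarray                     # (n_features,)
    explained_variance_ratio: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def fit_pca(aligned: np.ndarray, n_components: int = 5) -> PoseScores:
    """Project flattened aligned poses onto their top principal components.

    Sign convention: each loading's largest-magnitude entry is made
    positive, so scores are reproducible across runs and platforms.
    """
    X = np.asarray(aligned, float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    if X.shape[0] < n_components:
        raise InvalidInputError("fewer frames than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            scores[:, i] *= -1
    return PoseScores(
        scores=scores, loadings=comps, mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# sticky AR(1)-HMM


@dataclass(frozen=True)
class ARHMMHyperparams:
    """Weak-limit sticky HMM hyperparameters.

    ``alpha`` spreads each transition row, ``kappa`` adds sticky mass on
    the diagonal, ``gamma`` is the top-level concentration of the
    truncated construction (inert under the uniform base measure used
    here, kept for fidelity to the construction), ``max_states`` the
    truncation level.
    """

    alpha: float = 5.7
    gamma: float = 1e3
    max_states: int = 100
    n_iter: int = 200
    #: MNIW prior: B | Sigma ~ MN([I 0], Sigma, (k0 I)^-1), Sigma ~ IW(nu0, s0 I)
    k0: float = 1e-2
    s0: float = 1e-2


@dataclass
class ARHMMModel:
    ar_coefs: np.ndarray        # (S, D, D) per-state AR(1) matrices
    offsets: np.ndarray         # (S, D)
    noise_covs: np.ndarray      # (S, D, D) SPD
    transitions: np.ndarray     # (S, S) frame-level, sticky diagonal
    kappa: float
    hyperparams: ARHMMHyperparams
    seed: int
    loglik_trace: np.ndarray    # per-iteration forward log marginal
    active_states: np.ndarray   # states visited by the final sample

    @property
    def n_states(self) -> int:
        return self.transitions.shape[0]

    @property
    def n_dims(self) -> int:
        return self.ar_coefs.shape[1]


@njit(cache=True)
def _ffbs(lik, P, u):  # pragma: no cover - numba
    """Forward filter, backward sample.  lik: (T,S) scaled likelihoods."""
    T, S = lik.shape
    alpha = np.empty((T, S))
    logZ = 0.0
    prev = np.full(S, 1.0 / S)
    for t in range(T):
        pred = prev @ P if t > 0 else prev
        a = pred * lik[t]
        tot = a.sum()
        if tot <= 0.0:
            a = pred.copy()
            tot = a.sum()
        alpha[t] = a / tot
        logZ += np.log(tot)
        prev = alpha[t]
    z = np.empty(T, np.int64)
    w = alpha[T - 1]
    z[T - 1] = _sample_cat(w, u[T - 1])
    for t in range(T - 2, -1, -1):
        w = alpha[t] * P[:, z[t + 1]]
        tot = w.sum()
        if tot <= 0.0:
            w = alpha[t]
            tot = w.sum()
        z[t] = _sample_cat(w / tot, u[t])
    return z, logZ


@njit(cache=True)
def _sample_cat(p, u):  # pragma: no cover - numba
    acc = 0.0
    for i in range(p.size):
        acc += p[i]
        if u < acc:
            return i
    return p.size - 1


@njit(cache=True)
def _viterbi(loglik, logP):  # pragma: no cover - numba
    T, S = loglik.shape
    delta = loglik[0] - np.log(S)
    back = np.zeros((T, S), np.int64)
    for t in range(1, T):
        new = np.empty(S)
        for j in range(S):
            best, arg = -1e300, 0
            for i in range(S):
                v = delta[i] + logP[i, j]
                if v > best:
                    best, arg = v, i
            back[t, j] = arg
            new[j] = best + loglik[t, j]
        delta = new
    z = np.empty(T, np.int64)
    z[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        z[t] = back[t + 1, z[t + 1]]
    return z


def _state_logliks(x: np.ndarray, model_params) -> np.ndarray:
    """(T-1, S) log density of x_t given x_{t-1} under each state."""
    A, b, Sig = model_params
    S = A.shape[0]
    T1 = x.shape[0] - 1
    D = x.shape[1]
    out = np.empty((T1, S))
    const = -0.5 * D * np.log(2 * np.pi)
    for k in range(S):
        resid = x[1:] - x[:-1] @ A[k].T - b[k]
        L = np.linalg.cholesky(Sig[k])
        y = sla.solve_triangular(L, resid.T, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = const - 0.5 * logdet - 0.5 * (y**2).sum(axis=0)
    return out


def _sample_state_params(x, z, S, hp: ARHMMHyperparams, rng):
    """Draw (A, b, Sigma) for every state from the MNIW conditional."""
    D = x.shape[1]
    P = D + 1
    M0 = np.hstack([np.eye(D), np.zeros((D, 1))])
    K0 = hp.k0 * np.eye(P)
    nu0 = D + 2
    S0 = hp.s0 * np.eye(D)
    A = np.empty((S, D, D))
    b = np.empty((S, D))
    Sig = np.empty((S, D, D))
    Xprev = np.hstack([x[:-1], np.ones((x.shape[0] - 1, 1))])
    Y = x[1:]
    for k in range(S):
        m = z == k
        Xk, Yk = Xprev[m], Y[m]
        Kn = K0 + Xk.T @ Xk
        Mn = np.linalg.solve(Kn.T, (M0 @ K0 + Yk.T @ Xk).T).T
        Sn = S0 + Yk.T @ Yk + M0 @ K0 @ M0.T - Mn @ Kn @ Mn.T
        Sn = 0.5 * (Sn + Sn.T) + 1e-9 * np.eye(D)
        nun = nu0 + int(m.sum())
        Sigk = sps.invwishart.rvs(df=nun, scale=Sn, random_state=rng)
        Sigk = np.atleast_2d(Sigk)
        Kinv = np.linalg.inv(Kn)
        Kinv = 0.5 * (Kinv + Kinv.T) + 1e-12 * np.eye(P)
        Lr = np.linalg.cholesky(Sigk)
        Lc = np.linalg.cholesky(Kinv)
        Bk = Mn + Lr @ rng.standard_normal((D, P)) @ Lc.T
        A[k], b[k] = Bk[:, :D], Bk[:, D]
        Sig[k] = Sigk
    return A, b, Sig


def _sample_transitions(z, S, alpha, kappa, max_states, rng):
    counts = np.zeros((S, S))
    np.add.at(counts, (z[:-1], z[1:]), 1.0)
    conc = counts + alpha / max_states + kappa * np.eye(S)
    g = rng.gamma(conc)
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)


def fit_arhmm(
    scores: PoseScores | np.ndarray,
    kappa: float,
    hyperparams: ARHMMHyperparams | None = None,
    n_iter: int | None = None,
    seed: int = 0,
    init: str = "kmeans",
) -> ARHMMModel:
    """Fit the sticky AR(1)-HMM by blocked Gibbs sampling.

    The state sequence is initialized by seeded k-means on the score
    vectors (``init='random'`` falls back to a uniform random start):
    step-wise constant pose data admit a degenerate mode in which a
    single identity-AR random-walk state absorbs every syllable, and an
    emission-informed start keeps the sampler out of it.

    The returned model is the final Gibbs sample; the trace of forward
    log marginal likelihoods is attached for convergence inspection.
    Identical seeds give identical models.
    """
    x = scores.scores if isinstance(scores, PoseScores) else np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("scores contain non-finite values")
    if x.shape[0] < 3:
        raise InvalidInputError("need at least 3 frames")
    hp = hyperparams or ARHMMHyperparams()
    n_iter = hp.n_iter if n_iter is None else n_iter
    if n_iter < 1:
        raise InvalidInputError("n_iter must be >= 1")
    if init not in ("kmeans", "random"):
        raise InvalidInputError("init must be 'kmeans' or 'random'")
    S = hp.max_states
    D = x.shape[1]
    rng = np.random.default_rng(seed)

    if np.allclose(x.var(axis=0), 0.0):
        warnings.warn("degenerate (constant) scores: returning single-state model")
        Sig = np.eye(D)[None] * max(hp.s0, 1e-6)
        return ARHMMModel(
            ar_coefs=np.eye(D)[None].copy(), offsets=np.zeros((1, D)),
            noise_covs=Sig, transitions=np.ones((1, 1)), kappa=kappa,
            hyperparams=hp, seed=seed, loglik_trace=np.zeros(0),
            active_states=np.array([0]),
        )

    if init == "kmeans":
        from sklearn.cluster import KMeans
        # cluster (x_t, x_{t-1}) pairs: separates regimes that differ in
        # location or in one-step dynamics
        feats = np.hstack([x[1:], x[:-1]])
        k = min(S, max(2, len(np.unique(feats.round(6), axis=0)) // 2),
                feats.shape[0])
        km = KMeans(n_clusters=k, n_init=3,
                    random_state=int(rng.integers(2**31)))
        z = km.fit_predict(feats)
    else:
        z = rng.integers(0, S, size=x.shape[0] - 1)
    trace = np.empty(n_iter)
    params = None
    P = None
    for it in range(n_iter):
        params = _sample_state_params(x, z, S, hp, rng)
        P = _sample_transitions(z, S, hp.alpha, kappa, hp.max_states, rng)
        ll = _state_logliks(x, params)
        shift = ll.max(axis=1, keepdims=True)
        lik = np.exp(ll - shift)
        z, logZ = _ffbs(lik, P, rng.random(ll.shape[0]))
        trace[it] = logZ + shift.sum()

    A, b, Sig = params
    return ARHMMModel(
        ar_coefs=A, offsets=b, noise_covs=Sig, transitions=P, kappa=kappa,
        hyperparams=hp, seed=seed, loglik_trace=trace,
        active_states=np.unique(z),
    )


def decode_labels(model: ARHMMModel, scores: PoseScores | np.ndarray) -> np.ndarray:
    """Most probable state sequence (Viterbi), one label per frame.

    States are defined on score transitions (frames 1..T-1); frame 0
    inherits the first decoded state so the output has length T.
    """
    x = scores.scores if isinstance(scores, PoseScores) else np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != model.n_dims:
        raise InvalidInputError(
            f"score dimension {x.shape[1]} != model dimension {model.n_dims}"
        )
    if model.n_states == 1:
        return np.zeros(x.shape[0], dtype=np.int64)
    ll = _state_logliks(x, (model.ar_coefs, model.offsets, model.noise_covs))
    with np.errstate(divide="ignore"):
        logP = np.log(np.maximum(model.transitions, 1e-300))
    z = _viterbi(ll, logP)
    return np.concatenate(([z[0]], z))


@dataclass
class KappaScanResult:
    kappas: np.ndarray
    median_duration_ms: np.ndarray
    mean_duration_ms: np.ndarray
    final_loglik: np.ndarray
    selected_kappa: float
    selected_index: int
    models: list[ARHMMModel] = field(default_factory=list)


def select_kappa(kappas: np.ndarray, median_duration_ms: np.ndarray,
                 target_duration_ms: float = 400.0) -> int:
    """Index of the kappa whose median decoded duration is nearest the target.

    Ties break toward larger kappa (longer, more stable syllables);
    failed fits (NaN medians) are never selected.
    """
    dist = np.abs(np.asarray(median_duration_ms, float) - target_duration_ms)
    dist = np.where(np.isnan(dist), np.inf, dist)
    return int(len(dist) - 1 - np.argmin(dist[::-1]))


def kappa_scan(
    scores: PoseScores | np.ndarray,
    kappa_grid,
    hyperparams: ARHMMHyperparams | None = None,
    target_duration_ms: float = 400.0,
    seed: int = 0,
    n_iter: int | None = None,
    fps: float = 30.0,
    keep_models: bool = True,
) -> KappaScanResult:
    """Fit one model per kappa and select by decoded median duration.

    The selected kappa minimizes |median decoded syllable duration -
    target| (default target 400 ms); ties break toward larger kappa
    (longer, more stable syllables).
    """
    grid = np.asarray(sorted(kappa_grid), float)
    if grid.size == 0:
        raise InvalidInputError("empty kappa grid")
    med = np.full(grid.size, np.nan)
    mean = np.full(grid.size, np.nan)
    fll = np.full(grid.size, np.nan)
    models: list[ARHMMModel] = []
    failures = []
    for i, k in enumerate(grid):
        try:
            m = fit_arhmm(scores, kappa=float(k), hyperparams=hyperparams,
                          n_iter=n_iter, seed=seed)
            z = decode_labels(m, scores)
            lens = np.array([ln for _, _, ln in run_length_encode(z)], float)
            med[i] = float(np.median(lens)) * 1000.0 / fps
            mean[i] = float(np.mean(lens)) * 1000.0 / fps
            fll[i] = m.loglik_trace[-1] if m.loglik_trace.size else np.nan
            models.append(m)
        except Exception as e:  # record and continue the scan
            failures.append((float(k), repr(e)))
            models.append(None)  # type: ignore[arg-type]
    if np.all(np.isnan(med)):
        raise ScanFailedError(f"all kappa fits failed: {failures}")
    best = select_kappa(grid, med, target_duration_ms)
    return KappaScanResult(
        kappas=grid, median_duration_ms=med, mean_duration_ms=mean,
        final_loglik=fll, selected_kappa=float(grid[best]), selected_index=best,
        models=models if keep_models else [],
    )


def match_labels(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> tuple[dict[int, int], float]:
    """Optimal one-to-one relabeling of predicted states and frame accuracy.

    Solves the assignment problem on the confusion matrix (maximizing
    agreement); returns the predicted->true mapping and the fraction of
    frames matching after relabeling.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise InvalidInputError("label sequences must have equal length")
    tids = np.unique(t)
    pids = np.unique(p)
    n = max(len(tids), len(pids))
    C = np.zeros((n, n))
    ti = {v: i for i, v in enumerate(tids)}
    pi_ = {v: i for i, v in enumerate(pids)}
    for a, b in zip(p, t):
        C[pi_[a], ti[b]] += 1
    rows, cols = linear_sum_assignment(-C)
    mapping = {
        int(pids[r]): int(tids[c]) for r, c in zip(rows, cols) if r < len(pids) and c < len(tids)
    }
    acc = C[rows, cols].sum() / t.size
    return mapping, float(acc)
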