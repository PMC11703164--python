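"""Alignment invariance, PCA contracts, sticky AR-HMM recovery, Viterbi
optimality, kappa selection, and label matching."""

import itertools

import numpy as np
import pytest

from sylseq import (
    ARHMMHyperparams, decode_labels, egocentric_align, fit_arhmm, fit_pca,
    kappa_scan, match_labels, select_kappa, simulate_keypoints,
)
from sylseq.metrics import InvalidInputError
from sylseq.segmentation import _state_logliks
from sylseq.simulate import SkeletonSpec


def rigid_transform(kps, angle, shift):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return kps @ R.T + shift


class TestEgocentricAlign:
    def test_invariant_to_rigid_motion(self):
        rng = np.random.default_rng(0)
        kps = rng.normal(size=(50, 5, 2))
        aligned, _, _, _ = egocentric_align(kps)
        moved = rigid_transform(kps, 1.234, np.array([12.0, -3.0]))
        aligned2, _, _, _ = egocentric_align(moved)
        np.testing.assert_allclose(aligned, aligned2, atol=1e-10)

    def test_centroid_at_origin_and_axis_along_x(self):
        rng = np.random.default_rng(1)
        kps = rng.normal(size=(20, 4, 2))
        aligned, _, _, _ = egocentric_align(kps, anterior=0, posterior=1)
        np.testing.assert_allclose(aligned.mean(axis=1), 0.0, atol=1e-10)
        axis = aligned[:, 0] - aligned[:, 1]
        np.testing.assert_allclose(axis[:, 1], 0.0, atol=1e-10)
        assert np.all(axis[:, 0] > 0)

    def test_template_recovered_from_simulated_keypoints(self, three_state_keypoints):
        session, skeleton, _ = three_state_keypoints
        noiseless = SkeletonSpec(templates=skeleton.templates, noise_sigma=0.0)
        ks = simulate_keypoints(session, noiseless)
        aligned, _, _, _ = egocentric_align(ks)
        for s in range(3):
            frames = np.flatnonzero(session.labels == s)
            np.testing.assert_allclose(
                aligned[frames],
                np.broadcast_to(skeleton.templates[s], (len(frames), 6, 2)),
                atol=1e-8,
            )

    def test_degenerate_frames_flagged_and_heading_carried(self):
        kps = np.zeros((3, 3, 2))
        kps[0] = [[1, 0], [-1, 0], [0, 1]]
        kps[1] = [[0, 0], [0, 0], [0, 1]]          # nose == tail
        kps[2] = kps[0]
        _, _, heading, flags = egocentric_align(kps)
        assert list(flags) == [False, True, False]
        assert heading[1] == heading[0]

    def test_bad_indices_rejected(self):
        with pytest.raises(InvalidInputError):
            egocentric_align(np.zeros((5, 3, 2)), anterior=1, posterior=1)


class TestPCA:
    def test_planar_data_has_two_nonzero_components(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(size=(2, 6))
        X = rng.normal(size=(100, 2)) @ basis
        scores = fit_pca(X, n_components=5)
        assert np.all(scores.explained_variance_ratio[2:] < 1e-10)

    def test_spectral_contract(self):
        rng = np.random.default_rng(3)
        scores = fit_pca(rng.normal(size=(60, 8)), n_components=5)
        evr = scores.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-12
        np.testing.assert_allclose(scores.loadings @ scores.loadings.T,
                                   np.eye(5), atol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        s = fit_pca(X, n_components=4)
        np.testing.assert_allclose(s.scores @ s.loadings + s.mean, X, atol=1e-8)

    def test_scores_match_svd_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        s = fit_pca(X, n_components=3)
        Xc = X - X.mean(axis=0)
        U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        oracle = U[:, :3] * sv[:3]
        for i in range(3):          # align oracle to the package sign rule
            j = np.argmax(np.abs(Vt[i]))
            if Vt[i, j] < 0:
                oracle[:, i] *= -1
        np.testing.assert_allclose(s.scores, oracle, atol=1e-8)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_pca(np.zeros((3, 8)), n_components=5)


def ar_series(rng, segments, coefs, offsets, noise=0.05, x0=(0.0, 0.0)):
    """Piecewise AR(1) series: segments is a list of (state, length)."""
    x = [np.asarray(x0, float)]
    labels = []
    for state, length in segments:
        for _ in range(length):
            x.append(coefs[state] @ x[-1] + offsets[state]
                     + rng.normal(0, noise, 2))
            labels.append(state)
    return np.array(x), np.array(labels)


COEFS = {0: 0.5 * np.eye(2), 1: -0.4 * np.eye(2), 2: np.zeros((2, 2))}
OFFSETS = {0: np.array([2.0, 0.0]), 1: np.array([-2.0, 1.0]),
           2: np.array([0.0, -3.0])}


class TestFitARHMM:
    def test_single_regime_collapses_to_one_state(self):
        rng = np.random.default_rng(6)
        x, _ = ar_series(rng, [(0, 800)], COEFS, OFFSETS)
        hp = ARHMMHyperparams(max_states=5, n_iter=40)
        m = fit_arhmm(x, kappa=1e4, hyperparams=hp, seed=1)
        z = decode_labels(m, x)
        _, counts = np.unique(z, return_counts=True)
        assert counts.max() / z.size >= 0.95

    def test_three_regimes_recovered(self):
        rng = np.random.default_rng(7)
        segs = [(s, 40) for s in np.tile([0, 1, 2], 10)]
        x, labels = ar_series(rng, segs, COEFS, OFFSETS)
        hp = ARHMMHyperparams(max_states=6, n_iter=60)
        m = fit_arhmm(x, kappa=1e3, hyperparams=hp, seed=2)
        z = decode_labels(m, x)
        _, acc = match_labels(np.concatenate(([labels[0]], labels)), z)
        assert acc >= 0.9

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        x, _ = ar_series(rng, [(0, 60), (1, 60)], COEFS, OFFSETS)
        hp = ARHMMHyperparams(max_states=4, n_iter=15)
        a = fit_arhmm(x, kappa=100.0, hyperparams=hp, seed=3)
        b = fit_arhmm(x, kappa=100.0, hyperparams=hp, seed=3)
        np.testing.assert_array_equal(a.transitions, b.transitions)
        np.testing.assert_array_equal(a.ar_coefs, b.ar_coefs)
        np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)

    def test_likelihood_trace_improves(self):
        rng = np.random.default_rng(9)
        segs = [(s, 30) for s in np.tile([0, 1], 12)]
        x, _ = ar_series(rng, segs, COEFS, OFFSETS)
        hp = ARHMMHyperparams(max_states=4, n_iter=40)
        m = fit_arhmm(x, kappa=500.0, hyperparams=hp, seed=4)
        assert np.all(np.isfinite(m.loglik_trace))
        assert m.loglik_trace[-10:].mean() >= m.loglik_trace[:10].mean()

    def test_transition_rows_stochastic(self):
        rng = np.random.default_rng(10)
        x, _ = ar_series(rng, [(0, 50), (2, 50)], COEFS, OFFSETS)
        m = fit_arhmm(x, kappa=10.0,
                      hyperparams=ARHMMHyperparams(max_states=3, n_iter=10), seed=5)
        np.testing.assert_allclose(m.transitions.sum(axis=1), 1.0, atol=1e-9)
        for S in m.noise_covs:
            np.testing.assert_allclose(S, S.T)
            assert np.all(np.linalg.eigvalsh(S) > 0)

    def test_constant_scores_yield_single_state_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_arhmm(np.ones((100, 2)), kappa=10.0, seed=0)
        assert m.n_states == 1

    def test_nonfinite_scores_rejected(self):
        x = np.zeros((50, 2))
        x[10, 0] = np.nan
        with pytest.raises(InvalidInputError):
            fit_arhmm(x, kappa=10.0, seed=0)


class TestDecode:
    def test_decoding_is_deterministic(self):
        rng = np.random.default_rng(11)
        x, _ = ar_series(rng, [(0, 40), (1, 40)], COEFS, OFFSETS)
        m = fit_arhmm(x, kappa=100.0,
                      hyperparams=ARHMMHyperparams(max_states=3, n_iter=10), seed=6)
        np.testing.assert_array_equal(decode_labels(m, x), decode_labels(m, x))

    def test_noise_free_boundaries_recovered_exactly(self):
        # two pure rotation regimes: dynamics differ at every frame, so in
        # the noise-free limit the decoded boundaries are exact
        def rot(theta):
            c, s = np.cos(theta), np.sin(theta)
            return np.array([[c, -s], [s, c]])

        coefs = {0: rot(0.7), 1: rot(-1.2)}
        offsets = {0: np.zeros(2), 1: np.zeros(2)}
        rng = np.random.default_rng(12)
        x, labels = ar_series(rng, [(0, 50), (1, 50), (0, 50)], coefs, offsets,
                              noise=1e-6, x0=(1.0, 1.0))
        hp = ARHMMHyperparams(max_states=4, n_iter=40)
        m = fit_arhmm(x, kappa=100.0, hyperparams=hp, seed=7)
        z = decode_labels(m, x)
        _, acc = match_labels(np.concatenate(([labels[0]], labels)), z)
        assert acc == pytest.approx(1.0, abs=1e-3)

    def test_viterbi_beats_every_path_on_toy_series(self):
        # brute-force oracle: enumerate all state sequences of a 9-step toy
        rng = np.random.default_rng(13)
        x, _ = ar_series(rng, [(0, 5), (1, 5)], COEFS, OFFSETS)
        x = x[:10]
        m = fit_arhmm(x, kappa=5.0,
                      hyperparams=ARHMMHyperparams(max_states=2, n_iter=10), seed=8)
        ll = _state_logliks(x, (m.ar_coefs, m.offsets, m.noise_covs))
        logP = np.log(m.transitions)
        T = ll.shape[0]

        def path_score(path):
            score = -np.log(m.n_states) + ll[0, path[0]]
            for t in range(1, T):
                score += logP[path[t - 1], path[t]] + ll[t, path[t]]
            return score

        z = decode_labels(m, x)[1:]
        best = max(path_score(p) for p in itertools.product(range(2), repeat=T))
        assert path_score(z) == pytest.approx(best, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        x, _ = ar_series(rng, [(0, 30)], COEFS, OFFSETS)
        m = fit_arhmm(x, kappa=10.0,
                      hyperparams=ARHMMHyperparams(max_states=2, n_iter=5), seed=9)
        with pytest.raises(InvalidInputError):
            decode_labels(m, np.zeros((20, 5)))

    def test_viterbi_matches_hmmlearn_for_static_emissions(self):
        # zero AR coefficients reduce the model to a Gaussian HMM, for
        # which hmmlearn's decoder is an independent oracle
        from hmmlearn.hmm import GaussianHMM
        rng = np.random.default_rng(15)
        means = np.array([[0.0, 0.0], [4.0, 4.0]])
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        states = [0]
        for _ in range(199):
            states.append(rng.choice(2, p=P[states[-1]]))
        obs = means[states] + rng.normal(0, 0.8, (200, 2))

        from sylseq.segmentation import ARHMMModel
        m = ARHMMModel(
            ar_coefs=np.zeros((2, 2, 2)), offsets=means,
            noise_covs=np.stack([0.64 * np.eye(2)] * 2), transitions=P,
            kappa=0.0, hyperparams=ARHMMHyperparams(max_states=2),
            seed=0, loglik_trace=np.zeros(0), active_states=np.arange(2),
        )
        z = decode_labels(m, obs)[1:]

        gh = GaussianHMM(n_components=2, covariance_type="full", init_params="")
        gh.startprob_ = np.full(2, 0.5)
        gh.transmat_ = P
        gh.means_ = means
        gh.covars_ = np.stack([0.64 * np.eye(2)] * 2)
        _, z_ref = gh.decode(obs[1:], algorithm="viterbi")
        assert (z == z_ref).mean() > 0.99


class TestKappaSelection:
    def test_nearest_to_target_selected(self):
        idx = select_kappa(np.array([1e2, 1e3, 1e4]),
                           np.array([200.0, 390.0, 800.0]), 400.0)
        assert idx == 1

    def test_equidistant_tie_goes_to_larger_kappa(self):
        idx = select_kappa(np.array([1e2, 1e3]), np.array([300.0, 500.0]), 400.0)
        assert idx == 1

    def test_failed_fits_never_selected(self):
        idx = select_kappa(np.array([1e2, 1e3]), np.array([np.nan, 800.0]), 400.0)
        assert idx == 1

    def test_scan_results_are_consistent(self):
        rng = np.random.default_rng(16)
        segs = [(s, 12) for s in np.tile([0, 1, 2], 12)]
        x, _ = ar_series(rng, segs, COEFS, OFFSETS)
        hp = ARHMMHyperparams(max_states=5, n_iter=25)
        res = kappa_scan(x, [1e2, 1e4], hyperparams=hp, seed=10, n_iter=25)
        assert res.selected_kappa in res.kappas
        assert np.nanmin(res.median_duration_ms) > 0
        assert res.selected_index == select_kappa(res.kappas,
                                                  res.median_duration_ms, 400.0)


class TestMatchLabels:
    def test_identical_sequences(self):
        z = np.array([0, 1, 1, 2, 0])
        mapping, acc = match_labels(z, z)
        assert acc == 1.0 and mapping == {0: 0, 1: 1, 2: 2}

    def test_permuted_labels_still_perfect(self):
        t = np.array([0, 0, 1, 1, 2, 2])
        p = np.array([2, 2, 0, 0, 1, 1])
        mapping, acc = match_labels(t, p)
        assert acc == 1.0 and mapping == {2: 0, 0: 1, 1: 2}

    def test_matches_exhaustive_permutation_maximum(self):
        rng = np.random.default_rng(17)
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        _, acc = match_labels(t, p)
        best = max(
            np.mean(np.array([perm[v] for v in p]) == t)
            for perm in itertools.permutations(range(4))
        )
        assert acc == pytest.approx(best, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            match_labels(np.array([0, 1]), np.array([0, 1, 2]))
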