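# Methods

## The synthetic behavior generator

The generator produces labeled open-field sessions from an explicit
forward model, so every downstream estimator can be checked against the
parameters that generated its input.

**Syllable chain.** Behavior is an inter-syllable Markov chain: a
row-stochastic transition matrix A with zero diagonal (rows drawn from
a Dirichlet with concentration `transition_concentration`, default 5;
an infinite concentration gives uniform rows) and per-syllable dwell
times. Dwells are geometric by default — the memoryless law implied by
an HMM — with per-syllable means drawn uniformly from
`mean_duration_frames` (default 12–18 frames, i.e. 400–600 ms at
30 fps, bracketing the usual sub-second syllable scale). Because a
geometric dwell with mean 12 frames has median ≈ 8 frames, a second
law `dwell_law="fixed"` (every instance lasts its syllable's rounded
mean) is available for experiments that need durations concentrated at
the mean. The expected frame-share of syllable s is the dwell-weighted
stationary law u_s = π_s d_s / Σ_r π_r d_r.

**Kinematics.** Syllables carry characteristic speeds, log-spaced from
`v_min` = 3 to `v_max` = 17 cm/s (freezing-like to run-like; log
spacing concentrates syllables at the slow end, as slow modules
outnumber fast ones). The step into frame t has length
N(v_{s(t)}/fps, σ_step) clipped at zero (σ_step default 0.02 cm ≈ 0.6
cm/s of frame-to-frame tracking jitter; at 5σ from zero the clipping
is immaterial, so no truncation correction is applied). Heading follows
a persistent random walk (per-frame increment sd 0.35 rad). Steps that
would leave the 40×40 cm arena are reflected as vectors — the heading
flips at the wall and the step length is preserved exactly, so
noiseless sessions reproduce syllable speeds to float precision;
folding positions back into the arena would shorten wall-crossing
steps and bias velocities. Each animal carries a lognormal speed
multiplier (sd 0.05) for between-animal variability.

**Lesion effects.** Three parameters encode the dopamine-depletion
phenotype:

- `velocity_slope_beta`: each syllable loses the fraction β of its
  speed in excess of v_min, v′ = v − β(v − v_min). The loss ramps
  from zero for the slowest syllable up the speed profile, and the
  per-syllable Δv = β(v − v_min) is exactly linear in control speed
  with slope β — so the downstream Δ-velocity regression has a known
  target with R² = 1 on noiseless profiles. (A ramp linear in speed
  *rank* was considered and rejected: with a log-spaced profile it
  makes Δv visibly nonlinear in v and leaves the regression slope
  without a closed form.)
- `usage_shift_delta`: the fraction δ of every row's transition
  probability into fastest-tercile syllables is re-routed to
  slowest-tercile targets (proportionally to their existing mass),
  shifting time-share from fast to slow modules while keeping rows
  stochastic.
- `transition_damping`: dwell means are divided by this factor
  (≤ 1), so a damping of 0.8 lengthens dwells by 25% and reduces
  transition frequency accordingly without touching the embedded
  chain.

A third group, `lesion_treated`, models symptomatic treatment:
control speeds with lesion usage/transition structure, reflecting the
observation that dopaminergic medication restores movement speed but
not sequencing.

**Keypoints.** For segmentation experiments, per-syllable rigid
postural templates (nose and tail-base on the body axis, other
keypoints syllable-specific) are rotated to the frame heading,
translated to the centroid, and jittered with isotropic noise. The
keypoint centroid therefore equals the session centroid up to noise,
and egocentric alignment recovers the template exactly in the
noise-free limit.

**Seeding.** Per-animal seeds are SHA-256 hashes of
(master seed, group, animal index) reduced below 2³¹: reproducible,
collision-resistant, and independent of group order. Identical
configurations produce bit-identical cohorts.

**What the generator does not emulate.** Real pose tracking has
heavy-tailed, keypoint-correlated errors and identity swaps; real
syllables have non-geometric dwell structure, grooming micro-structure,
thigmotaxis, and postural dynamics *within* syllables (the templates
are static, so within-syllable score dynamics are pure noise around a
set point). Passing tests demonstrate correct recovery of the stated
Markov-plus-kinematics structure, not performance on real videos.

## Segmentation

**Egocentric alignment** removes location and heading: each frame is
translated so the keypoint centroid is at the origin and rotated so
the posterior→anterior axis lies along +x. Frames where the two axis
keypoints coincide have no defined heading; the previous heading is
carried forward and the frame is flagged rather than dropped.

**PCA** (scikit-learn, full SVD) reduces flattened aligned poses to 5
scores. Loading signs are fixed by making each component's
largest-magnitude entry positive, so scores are byte-stable across
runs.

**Sticky AR(1)-HMM.** State k has dynamics x_t = A_k x_{t−1} + b_k +
ε, ε ~ N(0, Σ_k), on the score space. The prior on ([A_k b_k], Σ_k) is
matrix-normal-inverse-Wishart centered on identity dynamics
(M₀ = [I 0], column precision 10⁻² I, Σ ~ IW(D+2, 10⁻² I)) — weak
enough that a few dozen frames dominate it. Transition rows take the
weak-limit sticky construction: row i ~ Dirichlet(α/S · 1 + κ e_i)
with α = 5.7 and truncation S = `max_states` (default 100); κ adds
self-transition mass and thereby sets syllable durations. The
top-level concentration γ (default 10³) belongs to the hierarchical
construction this truncates; with the uniform base measure used here
it does not enter the conditionals and is stored for fidelity only.

Fitting is blocked Gibbs: state parameters from their MNIW
conditionals, transition rows from Dirichlet conditionals with
observed bigram counts, and the state sequence by forward-filter
backward-sampling (scaled, numba-compiled). The forward-pass log
marginal likelihood is recorded per iteration; the returned model is
the final sample (default 200 iterations). Identical seeds give
identical models.

The state sequence is initialized by seeded k-means on concatenated
(x_t, x_{t−1}) pairs rather than uniformly at random. Step-wise
constant pose data admit a degenerate mode in which a single
identity-AR random-walk state (A = I, b = 0) explains every syllable's
plateau and absorbs most frames; random starts fall into it often, and
once established it is stable over hundreds of sweeps. Clustering on
lagged pairs starts the sampler with emission-aligned states (and
separates regimes that differ in dynamics rather than location);
`init="random"` remains available.

**Decoding** uses the Viterbi path (log-space, numba) rather than a
posterior sample: downstream statistics are then deterministic given
the model. States live on score transitions (frames 1..T−1); frame 0
inherits the first decoded state.

**Kappa scan.** One model per κ in the grid; the selected κ minimizes
|median decoded duration − target| with a 400 ms default target
(≈ 12 frames at 30 fps) and ties broken toward larger κ (longer, more
stable syllables). Failed fits are recorded and skipped; the scan
errors only if every fit fails.

**Evaluation.** Decoded labelings are compared to ground truth through
the optimal one-to-one state matching (assignment problem on the
confusion matrix), reporting matched-frame accuracy.

## Syllable metrics

Velocity of syllable s is the mean Euclidean frame-to-frame centroid
displacement over frames assigned to s, times fps. The step into frame
t belongs to the syllable active at t; the first frame has no
displacement and contributes only to usage. Frames with missing
coordinates are excluded step-wise and counted in a QC report, never
interpolated. Session speed is total distance over session duration.
Usage is the fraction of frames (time share, not instance share,
matching the "% of time" convention); durations come from run-length
encoding. The usage filter retains syllables whose *group-mean* usage
exceeds the threshold (default 0.5%) in at least one group, with
absent animal-syllable combinations counted as zeros so single-animal
syllables cannot pass. Ranking is by descending control-group mean
velocity with ties broken by syllable id.

## Transition structure

Transitions are counted between consecutive *distinct* syllables
(run-length-encoded sequence): the matrix has a zero diagonal and is
independent of dwell times, which are analyzed separately. Rows with
no outgoing transitions (syllables never exited in-sample) are kept as
zero rows, flagged, excluded from the recurrent class, and contribute
nothing to the entropy rate.

The steady state is computed on the largest closed communicating class
(networkx strong components; zero-out-degree singletons excluded) by
damped power iteration p ← p(I + A)/2 — the averaging handles periodic
chains — to a stationarity residual ‖πA − π‖∞ < 10⁻¹², capped at 10⁶
iterations. The entropy rate H = −Σ πᵢ Aᵢⱼ ln Aᵢⱼ (0 ln 0 := 0) is
reported in nats with a base-2 option; the unweighted sum of row
entropies is computed alongside it because aggregate "transition
entropy" is sometimes reported per-syllable-summed rather than
π-weighted, and the two are not interchangeable. Transition frequency
is label change-points per second; it satisfies the exact identity
frequency × duration = instances − 1. Entropy and frequency are
computed per animal and compared with rank statistics; group-mean
matrices are used only for display and difference graphs (ΔP =
mean(group 2) − mean(group 1), antisymmetric under group swap, edges
below a display threshold suppressed).

## Group statistics

Per-syllable velocity and usage are compared across groups by
Kruskal–Wallis (tie-corrected H) with Dunn's post-hoc z from pooled
rank means and tie-corrected variance. For combined untied samples of
n ≤ 10, both p-values come from exact enumeration over all group
assignments instead of the χ²/normal approximations; typical cohort
sizes (6–11 per group) sit just above this, so pipelines normally use
the asymptotic path. Omnibus p-values are BH-adjusted across syllables
within one metric and one comparison (adjusted p = step-up minimum of
m·p(k)/k, rejection at FDR q = 0.05); Dunn pairwise p-values are
reported uncorrected, which the analysis report states in its header.
Mann–Whitney U (scalar measures: session speed, transition frequency,
entropy) is exact for combined n ≤ 12 without ties, otherwise the
tie-corrected normal approximation. Δ regressions are ordinary least
squares of the per-syllable group difference (control − lesion) on
control velocity; a constant Δ is reported as slope 0 with R² = 0
rather than NaN. Summaries are mean ± SEM with SEM = SD/√n (ddof 1).
For usage comparisons, animals not expressing a syllable enter as true
zeros; for velocity they are undefined and dropped, and syllables
where any group has fewer than two values are skipped with a flag.

## Numerical and interface choices

- Frame tables are plain CSV (comma, UTF-8, '.' decimal, mandatory
  header), coordinates in cm from the arena's lower-left corner,
  0-based consecutive frame indices per animal; strict mode errors on
  gaps, permissive mode warns. Missing syllable labels read as "no
  labels" rather than a sentinel syllable.
- Pipeline runs write a manifest (seed, config snapshot, SHA-256 per
  output); reruns with the same seed reproduce checksums byte-exact.
- AR-HMM covariance updates add 10⁻⁹ jitter before Cholesky;
  transition sampling floors gamma draws at 10⁻³⁰⁰ to avoid zero rows.
- AR order is fixed at 1; higher orders would multiply parameters
  without being identifiable from static-template synthetic poses.

## Problem sizes

Tests and the acceptance script use cohorts of 8 animals/group with
20-minute sessions (36,000 frames) for metrics/transition/statistics
checks, 100 replicate cohorts for null calibration of the FDR
procedure, and 2-minute (3,600-frame) 3-syllable sessions with
8-state truncation and 60 Gibbs sweeps for segmentation recovery —
sizes at which every recovery target in the suite is met with margin
on a single CPU.

## Known limitations

The sticky AR-HMM is a reduced surrogate for full keypoint-based
motion sequencing: it has no explicit location/heading noise model, no
keypoint-level uncertainty, and uses the last Gibbs sample rather than
a posterior summary. The k-means initialization targets
emission-separable regimes; heavily overlapping states with purely
spectral differences may still need several restarts. Entropy-rate
comparisons assume a common syllable inventory across animals;
syllables absent in one animal enter its matrix as zero rows.
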