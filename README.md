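# sylseq

Sub-second behavioral syllable analysis for open-field locomotion.

Unsupervised segmentation methods (motion sequencing) decompose rodent
locomotor behavior into brief stereotyped modules — "syllables" such as
runs, pauses, turns, and grooming bouts, typically a few hundred
milliseconds long. Comparing how syllable kinematics, expression, and
sequencing change between groups (for example control mice versus
dopamine-depleted Parkinsonian models, with or without symptomatic
treatment) requires a chain of steps that this package implements as a
reusable library:

1. **Segmentation** (`sylseq.segmentation`): egocentric alignment of
   keypoint series (translation and heading removed), PCA to a small
   score space (5 components), and a sticky autoregressive hidden
   Markov model (AR(1)-HMM) fitted by blocked Gibbs sampling. The
   stickiness hyperparameter κ controls syllable duration and is chosen
   by scanning against a 400 ms target median duration. Frame labels
   come from the Viterbi path, so downstream statistics are
   deterministic given a model.
2. **Syllable metrics** (`sylseq.metrics`): per-animal syllable
   velocity (mean frame-to-frame centroid displacement of a syllable's
   frames, in cm/s), usage (fraction of session time), durations,
   session speed, and a usage filter (default: group-mean usage > 0.5%
   in at least one group).
3. **Transition structure** (`sylseq.transitions`): per-animal
   transition matrices over consecutive distinct syllables, steady
   state π (πA = π), entropy rate H = −Σᵢⱼ πᵢ Aᵢⱼ ln Aᵢⱼ, transition
   frequency (change-points/s), group-averaged matrices and
   difference graphs.
4. **Group statistics** (`sylseq.stats`): per-syllable Kruskal–Wallis
   with Dunn's post-hoc and Benjamini–Hochberg correction across
   syllables (FDR 0.05), Mann–Whitney U for scalar measures,
   Δ-vs-velocity regressions, mean ± SEM summaries. Small untied
   samples use exact enumeration instead of asymptotics.
5. **Synthetic cohorts** (`sylseq.simulate`): a seeded generator of
   labeled open-field sessions (Markov syllable chain, speed-dependent
   bounded random walk in a 40×40 cm arena at 30 fps) with
   parameterized lesion effects — proportional velocity loss on faster
   syllables, usage shift from fast to slow modules, damped transition
   rates — so every stage can be validated against known ground truth.

## Worked example

The `analysis/` scripts run the full study on a synthetic three-group
cohort (control; lesion with velocity slope β = 0.4, usage shift
δ = 0.3, transition damping 0.8; lesion with speed-restoring
treatment), 8 animals per group, 20-minute sessions:

```bash
cd analysis
python 01_simulate_cohorts.py
python 03_syllable_metrics.py
python 05_group_statistics.py
```

prints, among other lines:

```
session speed control         8.11 +/- 0.10 cm/s (n=8)
session speed lesion          5.49 +/- 0.08 cm/s (n=8)
session speed lesion_treated  7.27 +/- 0.18 cm/s (n=8)
delta-velocity vs control velocity: slope 0.406 (generator beta 0.4), R^2 1.000, p 3.74e-46
session speed control 8.11 vs lesion 5.49 cm/s (MWU p=0.0009)
```

The Δ-velocity regression (per-syllable control-minus-lesion velocity
against control velocity) recovers the generating slope β = 0.4: faster
syllables lose proportionally more speed, while the slowest are
untouched — the hypokinetic signature the generator encodes. The
treated group recovers session speed through restored syllable
kinematics while its transition frequency stays at the lesion level
(`04_transitions.py`). `02_segmentation_demo.py` runs the
align → PCA → AR-HMM chain on synthetic keypoints with known labels and
reports the κ scan and matched-frame accuracy.

The same pipeline runs on real frame tables (CSV with columns `frame,
x_cm, y_cm, syllable, animal_id, group`) via the CLI:

```bash
sylseq all --out results/run --seed 1          # simulate + full pipeline
sylseq stats --input sessions.csv --out results/run
sylseq segment keypoints.csv --out results/seg # label keypoint data
```

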