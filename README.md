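# crossformat

Analysis of how cortical populations encode actions across *formats* — when
an action is internally generated or executed (**intention**) versus
passively viewed (**observation**) — as studied with chronically implanted
microelectrode arrays in human motor cortex (MC) and superior parietal
lobule (SPL). The package implements the complete analysis chain for such
experiments and, because such recordings are not publicly distributable, a
synthetic session generator with plantable ground-truth coding structure so
every stage is testable end to end.

## What it computes

For a session of per-unit spike times (and optionally 1 kHz LFP) with a
trial table from a fully crossed 2 (hand) × 3 (action) × 2 (direction) × 2
(format) design:

- **Responsiveness & latency** — per condition, paired t-tests of 200 ms
  windows (100 ms step) against the −500–0 ms baseline, Bonferroni-corrected
  (α/29 windows); a unit is responsive given ≥3 consecutive significant
  windows, and its latency is the center of the first window of the earliest
  run. Format overlap counts (intention-only / observation-only / both) and
  one-way ANOVAs of latency across regions.
- **Tuning timecourses** — type-II factorial ANOVA per 500 ms bin (main
  effects and all interactions), with the count of tuned units per effect
  over time.
- **Unit taxonomy** — each unit's trial-level responses, averaged over the
  1–2 s window, are fit by ten linear models over (action, hand, direction,
  format): `null`, `invariant`, `action3`, `hand`, `direction`, `action6`
  (action × direction), `mixed`, `idiosyncratic` (separate coefficients per
  format), and `single_intention` / `single_observation`. Assignment is by
  highest cross-validated R² (repeated stratified 5-fold), gated by
  cv R² > 0.01, trial-shuffle permutation p < 0.05 after Benjamini–Hochberg
  FDR (q = 0.05), and best ≠ null.
- **Representational similarity** — split-half cross-validated RSA within
  and across formats; the structure statistic mean(diag) − mean(off-diag)
  with label-shuffle permutation p, plus time-window and all-units controls.
- **Decoding** — time-resolved PCA + LDA (95% variance, ≤50 components,
  10-fold stratified CV) within format; cross-time generalization matrices;
  cross-format decoding (train on one format, test on the other) with
  per-cell permutation p and Bonferroni correction; session-wise stability.
- **High-gamma LFP** — line-noise suppression, zero-phase 2 Hz high-pass,
  artifact-trial rejection, 7-cycle Morlet power normalized to baseline,
  and the unified high-gamma envelope (8 log-spaced Gaussian bands on
  73–144 Hz, analytic amplitude, 100 Hz resampling, z-score, tanh
  compression, per-channel SVD), feeding channel-level statistics and
  decoding.
- **Population geometry** — condition-averaged trajectories in a shared
  3-PC space, cross-format Procrustes alignment distances d ∈ [0, 1], and
  joint UMAP embeddings with per-condition covariance ellipses.
- **Dissociation tasks** — 2 (action) × 2 (hand) × 4 (conflict) designs in
  which the instructed action and the displayed video can disagree: video
  labels derived from the conflict type, instructed vs. video tuning and
  decoding, 16-way and conflict decoding, and the incongruent-only control.

The synthetic generator plants unit *archetypes* (unselective, invariant,
shared action/hand/direction, action×direction, mixed, idiosyncratic,
single-format, relevance-gated observer) as inhomogeneous Poisson processes,
and LFP channels as 1/f noise + 60 Hz line + a condition-modulated
high-gamma carrier, with the ground truth stored beside the session.

## Worked example

```bash
python examples/02_rsa_and_cross_format_decoding.py
```

```
shared/mirror-like   RSA structure = +1.250 (p = 0.0050); cross-format peak accuracy = 1.00, significant train x test cells = 80/225
idiosyncratic        RSA structure = +0.020 (p = 0.2050); cross-format peak accuracy = 0.46, significant train x test cells = 0/225
```

Both populations are strongly tuned within each format, but only the
population whose units carry the *same* action code in intention and
observation shows positive cross-format RSA structure at the minimum
attainable permutation p and Bonferroni-significant cross-format decoding;
the idiosyncratic population — same units, same strength, but unrelated
codes per format — shows neither. That contrast is the package's core
inference. The other examples cover taxonomy recovery
(`01_simulate_and_classify.py`), the high-gamma pipeline
(`03_highgamma_pipeline.py`), and the dissociation tasks
(`04_dissociation_task.py`).

A thin CLI mirrors the library for shell use:

```bash
crossformat simulate session.h5 --units 60 --reps 12 --seed 7
crossformat classify-units session.h5 --q 0.05 --seed 1
crossformat decode session.h5 --label action --train-format intention --test-format observation
crossformat report session.h5 --out report/
```

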