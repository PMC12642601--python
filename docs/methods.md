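# Methods

This note documents the models, the synthetic data the package is validated
on, the numerical choices, and the known limitations. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Task and time conventions

All times are seconds relative to trial onset (the hand cue). The canonical
main-task timeline is hand cue 0 s, symbolic action/direction cue 0.5 s, go
cue 1.5 s, video end 2.5 s; the trial window is [−0.5, 3.0) s. The go-cue
time is a `TaskDesign` field because published descriptions of this paradigm
are not fully consistent about it; nothing downstream depends on it. Bins
are half-open `[left, right)` and reported by their centers. The baseline is
[−0.5, 0) s and every binned rate is *net*: in-bin rate minus that trial's
mean baseline rate. Excluded trials are flagged once, in the trial table's
`included` column, and honored by every stage.

## Synthetic sessions

The generator reproduces the statistical structure the analyses assume, not
biophysics. Spiking is inhomogeneous Poisson with

```
rate(t) = baseline + effect · boxcar(latency, duration) · format_gain · condition_indicator
```

where the condition indicator implements the unit's archetype: shared
action/hand/direction (and action×direction) indicators identical in both
formats; `invariant` an additive mix of all three factors; `mixed` random
condition weights shared across formats; `idiosyncratic` independent random
weights per format; single-format units active in one format only;
`unselective` an identical response on every trial of both formats (a true
null for condition structure that is still "responsive"); and
`gated_observer` an indicator on the *video's* action multiplied by a
per-trial behavioral-relevance flag (true in observation blocks and
throughout the probe variant). A boxcar is used rather than a smooth PSTH
because it is the simplest shape that exercises the latency, 3-consecutive-
window, and analysis-window logic exactly.

Defaults: baseline 10 spikes/s; effect 15 spikes/s — about 2.7 times the
trial-to-trial SD of the 1–2 s window-mean net rate at that baseline
(√(10/1 + 10/0.5) ≈ 5.5 spikes/s); onset 0.6 s and duration 1.4 s so the
response covers the whole 1–2 s model window; `observation_gain = 0.5` for
shared archetypes, reflecting that observation responses are typically
weaker than intention responses. Where an analysis needs exactly shared
coefficients across formats (taxonomy-recovery experiments), the gain is set
to 1.0 explicitly: with gain < 1 a strongly tuned "shared" unit is, strictly,
format-specific in amplitude and the idiosyncratic model is then its correct
description. `archetype_population` can draw per-unit latencies and
durations from uniform ranges; the geometry analyses use this because a
population in which every unit shares one boxcar produces degenerate
(one-dimensional, trivially alignable) trajectories, whereas real
populations carry heterogeneous temporal profiles.

LFP channels are 1/f^β noise plus a 60 Hz sinusoid plus a band-limited
[73, 144] Hz carrier whose envelope is 1 at baseline and 1 + depth inside
the response window on trials matching the channel's preferred condition.

What the generator does **not** emulate — and hence what green tests do not
establish about real recordings: refractoriness and spike-sorting artifacts,
firing-rate drift and serial dependence across trials, correlated noise
between units, non-Poisson count dispersion, realistic PSTH shapes, eye
movements, and any coupling between spikes and LFP.

## Statistical machinery and numerical choices

**Responsiveness.** The paired comparison of each 200 ms window against the
per-trial baseline reduces, on net rates, to a one-sample t-test against
zero. The test is two-sided by default (a one-sided "greater" option
exists). The Bonferroni divisor is the number of full windows in [0, 3) at
100 ms step (29); partial windows at the end are dropped. Zero-variance
windows are treated as non-significant.

**Tuning ANOVA.** Type-II sums of squares (robust to mild imbalance),
computed from precomputed orthonormal design bases so thousands of
(unit, bin) cells reduce to matrix products; equality with statsmodels'
`anova_lm` is asserted in the tests. The Bonferroni divisor is the number of
units/channels tested, as is conventional for these tuning profiles, with
per-bin and uncorrected options. A unit counts under a main effect only if
no interaction involving that factor is significant; any significant
interaction places it in the interaction category.

**Model taxonomy.** Shared models carry a single intercept and no format
term, so an untuned but format-modulated unit falls to the null model rather
than being absorbed as "selective"; single-format and idiosyncratic models
carry per-format intercepts. Dummy coding uses the first level as reference
(fits and R² are invariant to full-rank coding). Cross-validation is
stratified over the 24 condition×format cells; the held-out R² pools
residual and total sums of squares over folds, with totals taken about the
training-fold mean, and may be negative. The fold assignment is redrawn 10
times and the sums pooled over repeats (`n_repeats`): a single 5-fold
assignment makes selection among *nested* models unstable — a superset model
wins on fold luck in ~20% of strongly tuned units — while repeated CV
stabilizes selection without changing what is estimated. Ties in cv R² go
to the model with fewer parameters. The permutation gate shuffles the
response across trials with the design fixed and, by default, re-scores only
the winning model (the literal published procedure); this null ignores the
selection step and is therefore mildly anti-conservative at the unit level —
the Benjamini–Hochberg gate across units is what keeps all-null populations
clean (measured in the tests). A `perm_refit_all` option re-fits the whole
family per shuffle for a selection-aware null. Note that BH controls the
false-discovery *rate*: in a mixed population the expected number of false
selective labels is q times the number of discoveries, not q times the
number of null units.

**RSA.** Trials are split in half within each condition (odd counts put the
extra trial on side A); condition-averaged vectors concatenate the 100 ms
bins of the analysis window across units. Within-format matrices correlate
the two halves of the same format; the cross-format matrix correlates half
A of intention with half B of observation, so noise levels match the
within-format case. Matrices average over 500 splits by default (any split
count gives identical matrices on noiseless data). The permutation null
shuffles condition labels independently within each format before
splitting. A caveat the tests quantify: for populations with strong
format-*idiosyncratic* structure, a finite random population carries real
chance cross-format alignment (the centered action marginals have two
degrees of freedom), and the label-shuffle null — which destroys all
structure — then rejects for ~13–15% of such populations at α = 0.05,
independent of population size. This is a property of the procedure, not an
implementation artifact; it is calibrated (≈5%) for unstructured
populations.

**Decoding.** PCA is fit within each training fold on trials stacked across
all time windows; the component count is the smallest capturing 95%
variance, capped at 50 (fixed 50 for cross-format, fit on the full
training-format data). LDA uses the scikit-learn SVD solver, which handles
rank deficiency. Folds are stratified by class and seed-controlled; the
cross-time diagonal equals the standard timecourse exactly because both
come from the same per-window classifiers. Cross-format permutation applies
one map-wide shuffle of the test labels per iteration; p = (1 + x)/(1 + n)
so p is never zero. Consequence: with 1000 permutations over a 30×30 bin
map the Bonferroni threshold (0.05/900) is below the smallest attainable p,
so significance is only decidable with coarser maps or more permutations —
the validation runs use 200 ms windows (15×15 cells) with 4999 permutations.
Accuracy ties also make the per-cell permutation p conservative (measured
rejection ≈3% at nominal 5%), never anti-conservative.

**High gamma.** Band centers are 73·(144/73)^(i/7) Hz, i = 0…7; each filter
is a frequency-domain Gaussian with FWHM = 20% of its center, applied with
negative frequencies zeroed so the inverse transform's magnitude is the
band's analytic amplitude in one pass. Envelopes are polyphase-resampled to
100 Hz, z-scored per band over all trials and timepoints, soft-clipped with
3·tanh(z/3), and reduced per channel to the first left singular vector
across the eight bands (sign fixed to a positive mean band loading); the
unified envelope is then z-scored per channel. Degenerate (zero-variance)
bands become zeros with a warning. Line noise is removed by spectrum
interpolation at 60 Hz and harmonics (magnitudes replaced by flanking-band
means, phases kept); the published source cites a combined spectral–spatial
method whose details are external, so the spatial step is not reproduced.
Artifact rejection flags trials whose channel-mean broadband RMS exceeds
two SDs of the session mean. Morlet power uses MNE's implementation
(7 cycles, 2 Hz grid on 60–120 Hz), with 100 ms edge trims and per-trial
baseline normalization per frequency.

**Geometry.** The shared PC basis comes from the SVD of the stacked
(condition × format × time) mean matrix; component signs are fixed so each
component's largest-magnitude loading is positive. Procrustes distances use
the standardized formulation (both trajectories centered and scaled to unit
Frobenius norm), so d = 1 − (Σ singular values)² ∈ [0, 1], symmetric, zero
exactly for identical inputs, and identical to `scipy.spatial.procrustes`'
disparity (asserted in tests); reflections are allowed by default with a
toggle. Constant trajectories raise, since the scaling is undefined. UMAP
uses cosine distance, 15 neighbors, min-dist 0.1, and a fixed seed.

**Dissociation.** Video labels derive deterministically from the conflict
type (action flips under action/both incongruence, hand under hand/both);
the derivation is an involution. The probe period (>2.5 s) is excluded from
decoding windows by default to avoid the saccade report. The incongruent-
only rerun removes congruent trials before decoding video labels, so video
decoding cannot be inherited from instructed-label information.

## Validation problem sizes

The acceptance-style tests and `scripts/acceptance.py` use scaled problem
sizes chosen to estimate each property precisely enough while keeping a full
run on one CPU short: taxonomy recovery on 240-unit populations (40 per
archetype, 12 reps, effects 3× trial SD, 1000 permutations; pooled over 2–3
populations), null calibration on 40–60 populations of 50 null units
(99 permutations, 3 CV repeats) plus 60–100 RSA runs (19 permutations) and
15–25 cross-format maps (99 permutations), RSA orderings with 12–24-unit
populations and 10–50 splits, and cross-format significance maps at 200 ms
resolution with 4999 permutations. Library defaults remain the canonical
analysis values (500 RSA splits, 1000 permutations, 10-fold decoding).

## Known limitations

- The spike and LFP generators are statistically minimal (see above); real-
  data idiosyncrasies (drift, correlated noise, non-Poisson dispersion) are
  out of scope, so calibration results transfer to real recordings only to
  the extent those idiosyncrasies are negligible.
- The winning-model permutation gate is anti-conservative per unit (selection
  bias); rely on the FDR gate or use `perm_refit_all=True`.
- The cross-format RSA permutation test over-rejects for finite populations
  with strong format-idiosyncratic structure (chance alignment is real
  structure); interpret borderline p-values on small populations with care.
- Session stores are single-machine HDF5 + CSV; vendor formats (NSx/NEV,
  NWB) and spike sorting are out of scope, and unit quality factors are
  carried as metadata only.
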