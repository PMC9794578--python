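# Methods

This note documents the models, algorithms and numerical choices behind
`averp`, in the order data flows through the package.

## Experimental design being emulated

The target experiment is an audiovisual oddball task run in two blocks, one
per stimulus intensity (high, low). Each block holds 450 trials — 150 per
modality (visual, auditory, audiovisual), of which 30 are targets requiring
a button press and 120 are standards — presented in random order for 800 ms
with a uniform 1200–1500 ms interstimulus interval after a 2000 ms fixation.
EEG is recorded from a 32-channel montage at 250 Hz. Two age groups are
compared, with default cohort sizes of 18 older and 20 younger adults.
Only standard trials enter the ERP analysis; targets drive the behavioral
measures.

## Synthetic data generator

`averp.synth` is a generative stand-in for the recordings such an
experiment produces. It is deliberately a *statistical* emulation: it
reproduces the moments and dependence structure the analysis is sensitive
to, not the biophysics.

**Signal.** Each unimodal condition is a sum of Gaussian-windowed
components (FWHM parameterization) with per-channel scalp weights — the
defaults give a posterior visual P1/N1 and a fronto-central auditory N1/P2,
with low-intensity amplitudes scaled by 0.6. The AV signal is constructed
as exactly `A + V` (the additive null holds by construction), plus any
configured integration effects.

**Integration effects.** An effect is a Gaussian bump confined to a latency
window and a set of ROI channels, applied only to AV trials of the matching
group × intensity cells. Its SD is half the window length (FWHM ≈ 1.18 ×
window), wide enough that a detectable effect sustains a significance run of
the detector's required length — the kind of effect the running-t-test
analysis reports. The amplitude is calibrated so the bump's *mean over the
window's samples* equals `amplitude_uv`; a closed-interval window-mean
readout therefore recovers the injected value without shape-factor
corrections, and recovery tests compare like with like.

**Noise.** Per-trial noise is white Gaussian (SD 5 µV) plus 1/f-power
"pink" noise (SD 10 µV) made by spectral shaping with the DC bin zeroed —
single-trial RMS ≈ 11 µV, leaving ≈ 1 µV residual noise in a 120-trial
average, which is the scale seen in practice. Channels are independent,
which real EEG is not: spatial averaging over an ROI reduces noise more
here (≈ √3 for three electrodes) than it would in data with correlated
neighbors, so absolute power levels should be read as generator-specific.
Between-subject variability enters as unit-mean Gaussian scale factors on
component amplitudes (SD 0.15) and on integration amplitudes (SD 0.2).
Blinks are Poisson-scheduled (4/min) 300 ms raised-cosine deflections of
150 µV on the frontal channels, sized to trip the ±100 µV rejection rule.

**Behavior.** Targets are answered with probability `hit_p` and standards
with probability `fa_p`; response times are ex-Gaussian per cell. Default
cell parameters reproduce the canonical pattern — AV fastest, then V, then
A; older slower; low intensity slower — with the printed mean/SD pairs
matched by setting τ = 0.6 SD, σ = 0.8 SD, µ = mean − τ. A per-subject
speed intercept (Gaussian, SD 60 ms) supplies the across-subject RT spread
that group summaries show; without it between-subject F statistics are
implausibly large.

**Two generation paths.** `simulate_subject` builds continuous recordings
(trial sequence placed on a timeline, noise spanning the recording, blinks)
for exercising the full preprocessing chain. For cohort-scale simulation
studies, `simulate_subject_erps` produces subject condition averages
directly using the fact that the mean of n i.i.d. Gaussian-noise epochs is
distributed as one noise epoch scaled by 1/√n; this variance-equivalent
fast path is exact for the Gaussian noise model (it cannot, by design, show
artifact-rejection effects, and it must not be used to *test* 1/√n
averaging behavior — the trial-level path exists for that). Everything is
a pure function of `(SimConfig, subject index)` via seeded substreams, so
whole cohorts are byte-reproducible.

## Preprocessing

The canonical order is re-reference → continuous band-pass → epoch →
baseline → reject → average → average band-pass → grand average; each step
records itself in the object's history, and steps refuse to run out of
order (`strict=False` lifts the check for externally preprocessed data).

* Re-referencing subtracts the mean of TP9/TP10 sample-wise.
* Filters are 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase; the filter family and order are not
  dictated by the analysis definition, so the most common choice is used.
  The 0.01–60 Hz pass is applied to continuous data (filtering short
  epochs at a 0.01 Hz corner is numerically meaningless).
* Epochs are −100…400 ms *closed intervals* — both endpoint samples
  included, 126 samples at 250 Hz, t = 0 at the marker sample. Epochs
  crossing a recording edge are dropped and logged.
* Baseline correction subtracts the per-trial, per-channel mean over
  −100…0 ms (inclusive); it is idempotent.
* Artifact rejection drops trials whose absolute amplitude *strictly*
  exceeds 100 µV on any EEG channel (mastoids/EOG excluded); a value of
  exactly 100.0 µV is retained. Manual drop lists are supported; automated
  trial-by-trial visual inspection is out of scope.
* Subject averages with fewer than 30 surviving epochs are flagged
  excluded and skipped downstream. Grand averages are unweighted across
  included subjects.
* The 0.1–30 Hz post-average filter is followed by re-baselining: a 0.1 Hz
  high-pass is ill-conditioned on a 0.5 s segment and leaves edge ringing
  that re-anchoring on the baseline removes (window-mean noise SD returns
  to within ~6% of its pre-filter value; unanchored it roughly doubles).

## Integration statistics

Difference waves are formed per subject and intensity from included
condition averages. Pointwise one-sample t-tests (two-sided, df = n − 1)
run over the closed 0–400 ms window; zero-variance samples take the
degenerate rule p = 0 (nonzero mean) / p = 1 (zero mean) and are logged.
The detector reports maximal runs of ≥ 12 consecutive samples with
p < .05 (strict); the run length is specified in *samples* — at 250 Hz
that spans 44 ms — and runs separated by even one nonsignificant sample
stay separate. No further multiple-comparison correction is applied beyond
the run-length criterion; the null calibration below quantifies what that
criterion buys. ROI averages are arithmetic means over each cluster's
electrodes; window amplitudes are closed-interval sample means with
nearest-sample endpoint rounding. Tests run per group × intensity ×
electrode (or ROI); pooling is the caller's choice.

## Mixed ANOVA engine

For a design with between factors (subjects nested in their between cell)
and fully-crossed within factors, each within effect is represented by an
orthonormal contrast matrix (Kronecker products of per-factor Helmert-
orthonormalized contrasts; the uninvolved factors contribute their
normalized mean vector). Subject-level contrast scores reduce each stratum
to a between-subjects linear model:

* Sums of squares are Type III via model comparison on an effect-coded
  (sum-to-zero) design matrix, so the unbalanced 18/20 groups are handled
  by unweighted-means logic for every effect — matching SPSS/`car::Anova`
  conventions (verified numerically against `car` during development).
* Each within stratum has its own error term (effect × subjects within
  groups); df are the closed forms, e.g. (2, 72) and (4, 144) at n = 38.
* Greenhouse–Geisser ε = tr(S)²/(q·tr(S²)) is computed from the pooled
  within-group residual covariance S of that stratum's contrast scores,
  clamped to [1/q, 1], and applied to both numerator and denominator df;
  ε ≡ 1 for 2-level factors. A singular covariance falls back to the lower
  bound.
* Partial η² = SS_effect / (SS_effect + SS_error-of-stratum).
* Degenerate strata (zero error variance) report F as missing with the
  limiting p rather than infinities.

Simple effects re-run the engine on the conditioned subset, retaining all
non-conditioning factors — the separate-error-term approach, chosen for
robustness to variance heterogeneity across conditioning levels. Pairwise
comparisons are paired or two-sample t-tests, uncorrected by default
(LSD-style) with Bonferroni/Holm available.

## Behavioral measures

Hit rate = responded targets / targets; false alarm = responded standards /
standards; both per subject × intensity × modality cell, order-invariant.
RTs come from target trials only and are trimmed in a *single pass* to the
cell's untrimmed mean ± 3 SD with inclusive bounds (trimming scope and
non-iteration are stated here because they are not derivable from the
measure's definition); retention fractions are recorded. On Gaussian data
the trim keeps ≈ 99.7%, comfortably above the 97.5% working threshold.

## Pipeline

A run directory holds TSV/JSON artifacts per stage with a provenance log
(parameters, stage timings, SHA-256 of every artifact); identical config +
seed reproduces identical bytes. Simulated EEG is regenerated
deterministically from the stored config rather than serialized (trial
-level epochs would be gigabytes of text); subject condition averages are
the on-disk boundary between data production and analysis. The ERP ANOVA
stage runs the 2 (age) × 2 (intensity) × 5 (ROI) model per analysis
window and adds age-by-intensity simple effects where that interaction is
significant.

## Problem sizes used in the test suite

Simulation-based checks run at the design's native scale where that is
cheap (38 subjects for ANOVA calibration; 100 seeded cohorts for recovery
power) and at reduced scale where the full design adds nothing to the
property under test (e.g. 6-subject trial-level cohorts for the 1/√trials
shrinkage check, 2 + 2 subjects for end-to-end pipeline determinism).

## What passing tests do and do not show

The generator's Gaussian components, channel-independent noise and
stationary blink model make the analysis chain's *statistical* behavior
testable: additive-null calibration, run-length false-positive
suppression, injected-effect recovery, ANOVA type-I rates. They do not
establish performance on real EEG, where spatially correlated noise,
non-stationarities, ocular topographies and reference choice matter.
Conclusions about the real experiment require the real-data path
(BrainVision input) and its own diagnostics.

## Known limitations

* BrainVision support is the multiplexed INT_16 / IEEE_FLOAT_32 subset;
  no EDF/BDF/FIF, no vendor writing (a fixture writer lives in the tests).
* No ICA/regression ocular correction, channel interpolation or
  resampling; rejection is amplitude-only plus manual lists.
* Huynh–Feldt correction and cluster-based permutation statistics are not
  implemented.
* The trigger-code dictionary and montage are config inputs — no vendor
  defaults are assumed.
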