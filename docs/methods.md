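# Methods

## Signal model and harmonic estimation

A steady-state trial is modelled as a voltage series sampled at rate
`sr` containing phase-locked components at the flicker frequency *f* (1F)
and its double (2F), plus noise. The complex amplitude at harmonic *k* is
estimated by ordinary least squares: the windowed trace is regressed on
`sin(2π k f t)`, `cos(2π k f t)` and an intercept, with time referenced to
trial onset. The coefficient `a + ib` has modulus equal to the amplitude
of a pure sinusoid (a trace `A sin(2π k f t + φ)` returns modulus `A`,
argument `φ`) and the estimator is linear in the data.

Why projection rather than an FFT bin read-out: when the window holds an
integer number of cycles the two are identical (asserted in the test
suite to 1e-9), but sweep designs analyse 1 s bins at 5.12 Hz — 5.12
cycles per window — where the nearest FFT bin is biased and the exact
projection is not. No taper is applied (rectangular window), the
steady-state convention: the frequency of interest is projected exactly,
so leakage from the stimulus line itself does not arise. The intercept
column guards against residual drift/DC in short windows.

Analysis windows: fixed-contrast trials discard the first second of each
11 s trial (onset transient) and analyse the remaining 10 s; sweep trials
analyse the central nine 1 s bins between prelude and postlude. Phases of
sweep bins share the trial clock, so bin coefficients are coherent with
one another.

A zero-phase band-pass (4th-order Butterworth, applied forward-backward)
is available for preprocessing; passband harmonic amplitudes are preserved
within ~2%. It is optional for synthetic data, which contain no drift or
line noise by construction.

## Averaging and artifact rejection

Within subject × contrast × harmonic, repetitions are averaged
**coherently**: the complex coefficients are averaged as vectors, the
amplitude is the modulus of that mean. This suppresses non-phase-locked
noise by √(reps) and means phase-inconsistent repetitions cancel rather
than add (the coherent amplitude can never exceed the scalar mean of
per-repetition amplitudes). Across subjects, group means are **scalar** —
arithmetic means of amplitudes with phase discarded — because anatomical
phase differs across subjects.

Artifact rejection acts on per-repetition harmonic amplitudes before
coherent averaging. Within each group × contrast × harmonic cell the mean
and SD (n−1 denominator) are computed over all repetitions of all
subjects; a repetition is removed iff it deviates from the cell mean by
more than 4 SD. The rule is **single-pass** (statistics are not recomputed
after removal — the conservative reading), cells with fewer than three
repetitions warn and reject nothing, and an SD of exactly zero rejects
nothing. With n = 10 repetitions in a cell the studentized deviation is
bounded by (n−1)/√n ≈ 2.85, so the 4-SD rule cannot fire on small clean
cells; it targets the gross outliers produced by blinks and movement.

## Contrast-response fitting

Group contrast-response functions use the Naka–Rushton (hyperbolic ratio)
form `R(C) = baseline + Rmax·Cⁿ/(Cⁿ + C50ⁿ)` with all four parameters
free, fit by trust-region least squares from a fixed 5×4 multi-start grid
over (C50, n) with bounds Rmax ∈ [0, 10·max amplitude], C50 ∈ (0, 200],
n ∈ (0, 5], baseline ∈ [0, max amplitude]. Fits are deterministic; ties in
residual are broken toward the lower C50. The fitted curve is monotone
non-decreasing by construction (non-negative Rmax), and the fit is
scale-equivariant: scaling the amplitudes scales Rmax and baseline and
leaves C50 and n unchanged. Group CRFs are fit to scalar group means, the
quantity usually plotted; per-subject response tables remain available.

The parameter-recovery study mirrors this use: 100 simulated cohorts of
12 subjects whose per-subject amplitudes carry noise at SNR 10 (SD = one
tenth of the saturating amplitude), each fit on the scalar group mean.
Median relative errors are ~4–5% for both C50 and Rmax. A single fit to
one subject's 7-point data at SNR 10 is a much harder problem — the free
exponent trades off against C50 and the median C50 error is ~15% — which
is why the pipeline fits group means.

## Supra-baseline selection and the frequency-ratio index

For each nonzero contrast, subjects' 1F amplitudes are compared to their
own 0%-contrast amplitudes with a one-sided paired t-test; contrasts with
p < 0.05 (uncorrected) form the supra-baseline set, computed once per
dataset with subjects pooled across groups. Restricting the ratio to
these conditions keeps noise-floor measurements (where the ratio is
meaningless) out of the index. Uncorrected α is deliberate — the selection
is liberal, and a spurious extra condition occasionally enters at the
noise boundary.

The per-subject index is the arithmetic mean of `(1F−2F)/(1F+2F)` over the
selected conditions. It is antisymmetric under harmonic exchange, bounded
in [−1, 1], and invariant to any common scaling of a subject's amplitudes
— the formal sense in which it controls for overall responsiveness.
Subjects missing a selected condition are averaged over what they have,
with a warning. For display, group ratio values may be shifted by the
grand mean of group means (`baseline_ratios`); differences are unchanged.

## Statistical battery

* **Mixed (split-plot) ANOVA** — harmonic as a 2-level within-subject
  factor, group between; classical univariate sums-of-squares
  decomposition, between effects tested against subject-within-group
  variation, within and interaction effects against the subject×harmonic
  residual. With two levels sphericity is trivially satisfied. The
  implementation is closed-form NumPy (fast enough for thousands of
  calibration replicates) and is checked in the tests against both a
  brute-force decomposition and `pingouin.mixed_anova`, on balanced and
  unbalanced groups.
* **One-way ANOVA with simple planned contrasts** — omnibus F, then each
  experimental group vs the control using the pooled omnibus mean-square
  error (t with the omnibus error dof); two-tailed, uncorrected.
* **Independent t-tests** — classic pooled-variance Student form,
  dof N−2, two-tailed.
* **Trait regression** — simple OLS of the ratio index on a per-subject
  trait score; reports multiple R (positive root of R²) and F with
  (1, N−2) dof. A median-split utility is provided for display grouping,
  but the regression uses raw scores.

Type-I calibration of the interaction test and the ratio t-test under a
null cohort (equal groups, subject random intercepts) is asserted at
0.05 ± 0.015 over 2000 seeded replicates.

## Synthetic cohort generator

Each repetition is `a₁(C)·sin(2πft+φ₁+ε) + a₂(C)·sin(2π·2f·t+φ₂+ε′) +
pink + white + artifact`, with `a_h(C) = gain_h·Cⁿ/(Cⁿ+C50ⁿ)` — the same
hyperbolic form the analysis fits, enabling closed-loop recovery. Per
subject: fixed uniform phases; a unit-median log-normal responsiveness
factor (`subject_gain_sd`) multiplying both harmonics (cancels in the
ratio); and an independent log-normal factor per harmonic
(`harmonic_gain_sd`) modelling biological spread in the
sustained/transient balance — this is what gives groups realistic
between-subject ratio variance. Per repetition: i.i.d. normal phase
jitter (creating the coherent-vs-scalar averaging gap), white noise, 1/f
noise (white noise spectrally shaped by 1/√f, rescaled to an exact
time-domain SD), and with probability `artifact_rate` a 0.2 s boxcar of
`artifact_amplitude` µV mimicking a blink/movement transient. Identical
config + seed reproduces a cohort bit-for-bit; all draws are recorded in
a `GroundTruth` object.

Sweep trials hold the first/last bin contrast during the prelude/postlude
(1.5 s each around the nine 1 s bins of a 12 s trial) and step the
amplitude envelope at bin boundaries with carrier phase continuous. Note
one estimator-independent limitation: with 5.12 cycles per 1 s bin the
amplitude steps leak ~1% into neighbouring bins, so per-bin ground-truth
recovery is leakage-limited (asserted at that tolerance), not at machine
precision.

### Preset study conditions

| preset | groups × n | gain 1F / 2F (µV) | C50, n | scatter (subj/harm) | jitter | noise w/p (µV) |
|---|---|---|---|---|---|---|
| fly (old) | 3 × 12 | 10 / 5; mutants 2F ×0.6 | 20%, 2 | 0.3 / 0.15 | 0.2 | 2 / 2 |
| fly (young) | 3 × 12 | mutants both ×0.75 | 20%, 2 | 0.3 / 0.15 | 0.2 | 2 / 2 |
| adult | 2 × 12 | 4 / 2; exp. 2F ×0.6 | 25%, 2 | 0.3 / 0.2 | 0.5 | 10 / 15 |
| child sweep | 17 + 13 | 6 / 3; exp. 1F ×0.7, 2F ×0.8 | 15%, 2 | 0.3 / 0.25 | 0.5 | 26 / 13 |

Amplitude units are arbitrary µV (insect ERGs and human EEG differ by
orders of magnitude in reality; only ratios and relative effects matter
here). The noise SDs were derived, before any end-to-end runs, from the
single-frequency noise floor they imply (`estimate_coefficient_noise`):
they place the floor so that the supra-baseline rule selects all six
nonzero fly contrasts, the adult 8–64% conditions (four), and the child
8.5–50% bins (five) — the condition sets these designs are meant to
produce. The mature-cohort transient effect (×0.6) is the generator's
canonical group effect; the young-fly preset scales both harmonics
equally, leaving the ratio unchanged, and the child preset reduces the
sustained gain with a milder, statistically unreliable transient
reduction at n = 30.

The trait-score cohort draws integer scores from N(15, 7) clipped to
[2, 42] and multiplies each subject's 2F gain by `clip(1 − 0.2·z, 0.4,
1.6)` (z the score's standard score), so trait severity selectively
scales the transient gain; the induced regression is stronger than is
typical of human questionnaire data, which limits quantitative comparison
of the regression R to real studies.

The amplitude-domain draw (`draw_subject_amplitudes`) shortcuts waveform
synthesis for large power/calibration studies by sampling the
coherent-average amplitude distribution directly (true amplitude with
phase jitter, averaged over repetitions, plus complex Gaussian
coefficient noise); its agreement with the waveform pipeline is asserted
in the tests. At the adult preset conditions the harmonic×group
interaction at the top contrast is detected in ≈ 90% of 200 cohorts of
50 subjects per group.

### What the generator does not emulate

No multi-channel/topographic structure, eye movements, alpha rhythm or
other structured EEG, non-stationary noise, adaptation across the trial,
response saturation beyond the CRF, or harmonic content above 2F. Passing
tests show the *pipeline* is correct and well-calibrated under the stated
generative model; they do not validate the model against real recordings.

## Problem sizes and numerical choices

Simulated studies use the preset cohort sizes (36 flies per age, 24 or
100 adults, 30 children); the end-to-end ratio-recovery study uses a
250 Hz variant of the adult design with the white-noise SD chosen to
preserve the preset coefficient noise floor, and power/calibration studies
use the amplitude-domain draw (200–2000 replicates). Least-squares fits
use xtol = ftol = gtol = 1e-12; rejection SDs use the n−1 denominator;
degenerate inputs (zero amplitudes in the ratio, zero-variance t-tests,
empty supra sets) return NaN-with-warning, t = 0, or a stage-tagged
pipeline error respectively.

## Known limitations

* The supra-baseline α is uncorrected by design; at the noise boundary a
  spurious condition occasionally enters the set.
* The split-plot ANOVA assumes homogeneous between-subject variance
  across groups; no Welch-type correction is offered (the pooled form is
  what integer N−2 dof imply).
* Single-channel data only; multi-channel input is rejected, not
  averaged.
* CSV round-trips store voltages as decimal text; reading back is exact
  to ~1e-12 relative, not bit-exact.
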