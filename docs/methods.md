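# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Behavioral model: race architecture and Miller's bound

Responses to a redundant audio–visual stimulus are compared with the
prediction of independent parallel unimodal channels. If A and V
processing race independently, the redundant-signal CDF satisfies
P_AV(t) ≤ P_A(t) + P_V(t) − P_A(t)P_V(t) for every t, with equality under
exact independence. Exceeding the bound implies cross-modal integration.

Conventions, all deliberate and switchable only where noted:

- **RT filter**: the closed interval [200, 1700] ms is kept; values
  strictly outside are excluded, and no further outlier rule is applied.
- **CDF grid**: right edges of 10-ms bins over 0–1700 ms (170 points),
  matching the filter ceiling. All subjects and conditions share the grid.
- **Misses** count in the CDF denominator (default, switchable via
  `misses_in_denominator`): a non-response plateaus the CDF below 1
  rather than silently renormalizing. No kill-the-slowest correction.
- **Violation test**: per-bin one-sample two-tailed t at α = .05 with a
  positive-mean requirement, uncorrected across bins; maximal runs of
  significant bins are reported as window intervals, including
  single-bin runs.
- **Peak benefit / latency** come from the across-subject mean difference
  curve; individual peak latencies come from each subject's own curve and
  feed the between-group latency t-test.
- **Positive AUC** is the plain bin-sum of the positive part of the mean
  curve (unitless). An area in probability × ms would be 10× larger; the
  bin-sum convention keeps values on the order of a few units.

### Calibration of the per-bin t-test

The per-bin t-test is calibrated only where the subject difference values
are approximately continuous, i.e. where the CDFs are mid-scale. In the
far tails of the RT range the per-subject differences are discrete
multiples of 1/n_trials with strong skew (the product term P̂_A·P̂_V
creates many tiny positive deviations balanced by rare large negative
ones), and the t-test there is anti-conservative despite the unbiased
difference. The Monte-Carlo calibration in the acceptance suite therefore
measures the positive-significant rate over the 260–700 ms bins, where the
generator's CDFs lie mid-scale and the empirical rate matches the nominal
α/2; the same tail pathology exists in any pointwise race-bound test on
binned CDFs and is worth remembering when reading empirical integration
windows that start very early or very late.

With the generator's default 5% miss rate the AV miss probability exceeds
the race prediction (a race of two channels misses only when both do), so
late-bin differences acquire a negative bias — conservative with respect
to Miller violations. The exact-equality null used for calibration sets
the miss rate to zero.

## EEG connectivity

### Windowed Fourier phase

Phase is extracted by a direct sliding-window complex inner product: at
each output sample t and integer frequency f ∈ {1, …, 50} Hz,

    C(t, f) = Σₖ x[t + k − W/2] · h[k] · exp(−i2πf(k − W/2)/fs),

with h a 50-sample (200-ms) Hamming window. A direct product rather than
FFT bins because a 50-sample FFT has 5-Hz resolution while the analysis
needs 1-Hz steps. Demodulating relative to the window center makes
arg C(t, f) track the signal phase at sample t itself; on a noiseless
sinusoid the extracted phase matches θ + 2πft to a few thousandths of a
radian mid-epoch (measured by the acceptance script). Samples closer than
half a window to an epoch edge use the zero-padded remainder of the
window; they are discarded by the trimming step, which removes 600 ms at
the start and 1400 ms at the end — both larger than the 100-ms half-width.

### PLI

PLI(t, f) = |mean over trials of sign(Δφ)| with Δφ wrapped to (−π, π] and
sign(0) = 0, so exactly-zero lags — the signature of volume conduction —
contribute nothing. The absolute value makes the statistic a magnitude in
[0, 1], which the mean-weight network aggregation requires; a signed
variant would additionally need a fixed channel ordering (the
implementation fixes Δφ = φ_row − φ_col for that purpose). Per-frequency
PLI is averaged over inclusive integer band ranges (theta 4–7, alpha 8–13,
beta 14–30, gamma 31–50 Hz). The streaming implementation (`band_pli`)
processes one frequency at a time and is verified in the tests to equal
the composed `wft_phase → pli_matrix → band_average` path.

Two practical PLI properties the synthetic suite exercises:

- **Volume-conduction immunity is one-sided.** A common zero-lag signal
  creates no spurious PLI, and a moderate one leaves the PLI of a rigid
  mid-range lag untouched (the sign of the phase difference has margin).
  A common signal much stronger than the lagged source, however, drags
  both phases toward its own and *dilutes* genuine coupling.
- **Spectral leakage couples bands.** A 200-ms window has a main lobe
  several Hz wide, so a strongly phase-coupled narrowband source is
  visible to the PLI of neighboring-band frequencies. In the synthetic
  group-difference experiments the non-target bands therefore carry
  background coupling that is identical across groups; without it, a
  theta-only group difference leaks a detectable alpha-band difference,
  which is physics, not a bug.

### Preprocessing

EOG channels are dropped, the mean of TP9/TP10 is subtracted and the
mastoids removed (32 → 28 channels), a 4th-order Butterworth band-pass
1–50 Hz is applied forward–backward (zero phase, because phase is the
analyte), an artifact-removal hook is applied (identity by default — the
synthetic data are artifact-free), and the prestimulus mean is subtracted
per channel and trial. For synthetic data that is already referenced,
re-referencing can be skipped (`mastoids=None`).

## Group statistics

- **Pointwise tests**: independent two-sample t at each of the 200
  analysis samples, one-tailed in a direction that must be stated
  explicitly per band (the package defaults encode elderly-greater theta
  and younger-greater alpha/beta/gamma), uncorrected across time.
  Contiguous significant samples are reported as windows, single-sample
  runs included.
- **Window averaging**: arithmetic mean over the closed ms interval; the
  band defaults (theta 52–348, alpha 108–328, beta 108–240, gamma 0–200
  ms) are the pooled significant ranges used for window-averaged PLI.
- **Mixed ANOVA**: the 2 × 2 × 3 split-plot design is computed from
  orthonormal within-subject contrasts (Helmert bases, Kronecker products
  for the interaction). For each within effect the projected subject
  scores give the effect, group-interaction and subject-error sums of
  squares; the Greenhouse–Geisser epsilon is tr(S)²/(d·tr(S²)) of the
  pooled within-group covariance of the same projections, applied to both
  degrees of freedom wherever the effect has more than one numerator df.
  Partial η² uses each effect's own error term. The implementation was
  cross-checked against R's `car::Anova` (type III, sum-to-zero
  contrasts) during development and is tested against an independent
  brute-force cell-means computation. No installed Python package covers
  this design (one between plus two within factors with GG correction),
  which is why it is implemented here.
- **Post hocs**: all pairwise t-tests (paired within, independent
  between), Bonferroni-adjusted over the emitted family, optionally
  stratified by another factor.

## Synthetic generators

The generators define the study conditions for every Monte-Carlo result in
the tests and the acceptance script.

**Reaction times.** Unimodal RTs are ex-Gaussian (normal μ, σ plus
exponential τ) — the standard unimodal RT phenomenology. Defaults:
μ_A = 500 ms, μ_V = 450 ms (auditory slower, so AV > V > A in speed),
σ = 60 ms, τ = 120 ms, 30 trials per stimulus type, 5% misses, an 80-ms
additive shift for the elderly group, and a per-subject mean shift with
SD 40 ms so between-subject statistics have realistic variance (the
source task characterizes neither the RT distribution family nor
inter-subject variability; these are package conventions). AV responses
are (1 − g)·min(A′, V′) over fresh unimodal draws: g = 0 is a pure race
that satisfies Miller's bound in expectation at every bin, and a single
gain parameter g produces monotone, controllable violations. Misses are
uninformative (trial dropped with no RT). An optional additive
low-intensity slowing supports inverse-effectiveness-style contrasts.

**EEG.** Band-limited cosine sources with a uniform random phase per
trial; each involved channel oscillates at the reference phase plus a
fixed lag plus von Mises jitter of concentration κ (κ = 0: uniform, no
coupling; κ ≥ 10⁶: rigid lag, implemented jitter-free). Sources are
active over an onset–offset window with 20-ms raised-cosine ramps (so
switching a source on does not splatter broadband energy), on top of
i.i.d. Gaussian sample noise, plus an optional zero-lag component added
identically to all channels to exercise volume-conduction immunity.
Geometry defaults mirror the acquisition: 28 channels, 250 Hz,
−800…+2000 ms (700 samples).

All randomness in both generators flows from a single integer seed
through `numpy.random.SeedSequence` spawning, one child stream per
subject; fixed seeds give bit-identical datasets.

What the generators do **not** emulate: head-model mixing beyond the
single global zero-lag component, 1/f background spectra, artifacts
(blinks, muscle, line noise), non-stationary coupling beyond rectangular
activation windows, RT–EEG coupling within subject, or realistic spatial
correlation structure across 28 channels. Passing tests demonstrate that
the analysis recovers known structure under its own assumptions, not that
it is robust to everything real data contain.

## Problem sizes

The Monte-Carlo suites run at the sizes the behavioral design prescribes
(20 subjects, 30 trials per type) with 150–500 replicates per estimate;
the EEG group experiments use 10 subjects per group, 6 channels and 30
trials with the full four-band frequency set, and the full-geometry
checks (28 channels, 700 samples) run on single datasets. These sizes
give stable estimates (binomial SE ≤ ~0.01 on rates) while keeping a full
run on one CPU in the minutes range; the pipeline demo config is smaller
still (3 subjects per group, 4 channels) and completes in seconds.

## Known limitations

- The ANOVA requires a balanced, complete design with one observation per
  cell; unbalanced groups are rejected rather than approximated.
- Pointwise tests carry no correction across bins or samples, faithfully
  mirroring the analysis they implement; interpret window edges
  accordingly.
- The per-bin race test's tail-bin anti-conservatism (above) means very
  early/late empirical windows deserve skepticism.
- `wft_phase` materializes a channels × samples × freqs × trials array
  and is intended for exploratory use at modest sizes; the band pipeline
  streams per frequency instead.
- Only the unweighted PLI is implemented — no weighted/debiased variants,
  no source-space connectivity, no graph metrics beyond the mean weight.
- Readers for vendor EEG formats are out of scope; the documented HDF5
  epoch container is the interchange point.
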