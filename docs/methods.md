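# Methods

## Pipeline overview

`erpfuse` consumes epoched two-condition (rare / frequent) oddball EEG —
either simulated, read from its HDF5 epoch container, or cut from a
continuous EDF recording plus an events table — and runs three stages:

1. **Feature extraction** per participant: average ERP waveforms, complex
   Morlet wavelet coefficients (amplitude = "TF power", angle = phase),
   and the cross-trial phase-synchronization statistic.
2. **Dataset construction** in one of two modes: *trial-average* (one
   24-trial rare average and one 24-trial frequent average per
   participant) or *single-trial* (every epoch a sample).
3. **Classification**: single-feature perceptrons and transfer-initialized
   composites, trained by SGD on cross-entropy, iterated over repeated
   random draws/splits and aggregated into mean ± SEM accuracies.

The package assumes cleaned data: filtering, artifact rejection and ICA
are upstream concerns of recording-specific toolchains and are
deliberately out of scope.

## Conventions and numerical choices

**Time axis.** Sample `k` of an epoch sits at `t_start + k·1000/srate` ms
and epochs include both endpoints, so `[−1000, 2000]` ms at 150 Hz has 451
samples.  Whether such a window should contain 450 or 451 samples is a
genuine convention choice; the inclusive convention is used consistently
everywhere (epoching, feature tensors, baselining).  The baseline window
`[−200, 0]` ms includes the sample at t = 0, matching its closed-interval
notation.  Units are microvolts throughout; EDF import converts from the
reader's SI volts.

**Morlet parameterization.** "Time-decay parameter 0.5" does not pin down
a unique Morlet convention (it could be a bandwidth in s², an envelope SD,
or a cycle count).  We adopt the bandwidth convention, in which a single
named parameter controls the envelope: mother wavelet
`ψ(t) = (π·fb)^(−1/2) · exp(−t²/fb) · exp(i·2π·fc·t)` with `fb = 0.5` s²
and `fc = 1` Hz, dilated by scale `a = fc/f` so that `1/a ∝ f`.  The
choice is isolated behind `WaveletSpec`; changing conventions means
changing one dataclass.

**CWT evaluation and calibration.** Coefficients
`W(a,b) = a^(−1/2) Σ_t S(t) ψ*((t−b)/a) Δt` are evaluated by FFT
convolution (the Morlet kernel equals its conjugate time-reverse) and
multiplied by `2/√a` so that a unit-amplitude sinusoid at the analysis
frequency yields modulus ≈ 1 in the epoch interior.  Absolute units of
wavelet amplitude are arbitrary; only baselined differences matter
downstream, and this calibration makes the maps readable in "equivalent
sinusoid microvolts".  A brute-force Riemann-sum implementation
(`cwt_direct`) serves as the test oracle; the two agree to ~1e−14 on small
epochs.  Kernels are truncated where the Gaussian envelope falls below
1e−5 of its peak.

**Edges.** Coefficients within one kernel half-length of an epoch edge are
computed against implicit zero-padding and flagged
(`SpectralDecomposition.valid_mask`).  Classifier features are cropped to
`[−500, 1500]` ms by default, which excludes the flagged region for every
frequency ≥ 4 Hz at the default geometry.

**Phase-synchronization statistic.** At each (channel, frequency, time)
point the trial phases are assigned to 10 half-open bins
`(−π+(i−1)·2π/10, −π+i·2π/10]` (exact −π goes to bin 1), and the statistic
is `sqrt(Σ(p_i − 0.1)²/10)`.  Closed forms used as test anchors: all
phases in one bin give 0.3; an exactly uniform histogram gives 0; for n
i.i.d. uniform phases `E[stat²] = 0.09/n` (0.00375 at n = 24).  The
statistic is invariant to rotating all phases by whole bin widths but not
to arbitrary rotations — a cluster sitting on a bin edge can split and
lower the raw value (e.g. a perfect two-cluster bimodal pattern reads
0.208 mid-bin but ~0.14 on an edge).  This discretization noise is
inherent to the histogram construction and far smaller than the contrasts
of interest.

**Single-trial phase feature.** Phase synchronization is a cross-trial
concept, so single-trial mode feeds the classifier the raw wavelet angle
in `(−π, π]`, unbaselined (angles are not additive offsets).  The ±π wrap
makes this representation discontinuous; an optional `(cos, sin)`
encoding is available (`tf_phase(..., encoding="cos_sin")`) but off by
default, keeping the default feature the simplest possible phase readout.

**Classifier.** Per feature: flatten → linear `(d×2)` → per-logit batch
normalization (ε = 1e−5, running-statistics momentum 0.1; batch statistics
in training, running statistics at evaluation); composites concatenate the
normalized logit pairs into a fusion linear map `(2k×2)`.  Normalizing
each logit separately is the standard choice; normalizing the pair
jointly would only change the shared scale, which softmax ignores.
Weights initialize uniform in `±1/√d`; the fusion map initializes to
block-averaging (each output logit = mean of the per-feature logits,
bias 0), so a transfer-initialized composite starts exactly at the
ensemble of its trained parts — consistent with the rationale that
starting near a good solution helps; a small-random fusion init is
available.  Labels map frequent → 0, rare → 1; prediction ties break
toward frequent.  Gradients are hand-derived (softmax + cross-entropy
backpropagates `q − p`; batchnorm uses the batch-statistics backward
pass) and verified against central finite differences to ~1e−8 relative.

**Training and iteration protocol.** SGD with learning rate 1e−4 and
momentum 0.9; cross-entropy loss; data reshuffled every epoch from the
run seed.  Trial-average mode: batch 50, 200 epochs, test fraction 0.25
re-split every iteration; frequent 24-trial subsets are fixed per cohort
(shuffle once, chunk consecutively — guaranteeing non-overlap) while the
choice among them is redrawn per iteration.  Single-trial mode: batch
1920, 50 epochs, all rare trials plus an equal per-participant random
draw of frequent trials; the train/test split proportion is not dictated
by anything at the single-trial level, so the average-mode fraction
(0.25) is reused.  The per-iteration summary score is the final epoch's
held-out accuracy in average mode and the mean of the last 20 epochs in
single-trial mode; SEM is `sd/√n_iterations`.  Splits are sample-level
(a participant's rare and frequent samples may straddle train and test),
which mirrors common practice for this protocol; a grouped-by-participant
split is available for leakage-safe analyses.

**Determinism.** Cohorts are pure functions of `(config, seed)`:
per-participant and per-source streams come from
`numpy.random.SeedSequence(entropy=seed, spawn_key=(participant, k))`, so
adding a source never perturbs the draws of the others (superposition is
testable exactly).  Iteration, split, initialization and shuffling seeds
are folded from the plan seed with a `SeedSequence`-based
`derive_seed`; the CLI derives per-stage seeds by hashing the stage name,
so stages can be rerun independently.

## The synthetic cohorts

The simulator emulates the *geometry* and qualitative response taxonomy
of a visual oddball study — 24 rare / 135 frequent trials per participant,
32 channels at 150 Hz (or scaled-down presets), epochs of
`[−1000, 2000]` ms — not any particular recording.  Three source
archetypes ride on background noise:

- **Background**: Gaussian noise spectrally shaped to `1/f^α` (α = 1),
  independent per channel and trial, RMS 10 µV — a broadband EEG floor
  without claimed physiological detail.  At the analysis frequencies this
  floor corresponds to ~4 µV of narrowband wavelet amplitude, which is
  what oscillation amplitudes should be judged against.
- **Additive transient** (ERP-type response): a Gaussian bump
  parameterized by peak latency (300 ms), FWHM (250 ms), amplitude and
  sign, with Normal latency jitter (SD 40 ms) and log-normal
  (positive-support, mean-1) amplitude variability (CV 0.3).  Scenario
  amplitudes of 10 µV (rare) vs 4 µV (frequent) follow typical
  target-vs-standard P3 magnitudes at centro-parietal sites.
- **Ongoing oscillations**: single-frequency sinusoids with log-normal
  per-trial amplitude and uniform pre-stimulus phase.  Power effects
  multiply the amplitude after onset through a 200 ms raised-cosine ramp
  (scenarios use a 12 µV, 10 Hz posterior source with post-stimulus gain
  0.4 vs 0.8 — alpha suppression, stronger for rare).  Phase resets slide
  the phase smoothly (700 ms raised-cosine interpolation along the
  shortest path) to a target that is either fixed (`reset_unimodal`) or a
  fair coin between φ and φ+π (`reset_bimodal`, scenarios: 10 µV at
  8 Hz).  The slide keeps the amplitude envelope exactly constant by
  construction — the idealized "phase reset without amplitude change" —
  at the cost of a brief, small instantaneous-frequency excursion
  (≤ ~1 Hz), whose leakage into measured TF amplitude stays at or below
  the sampling-noise floor of the scaled cohorts.  Single-frequency
  sinusoids with smooth envelopes keep the time-frequency ground truth
  interpretable.

The **scenarios** place the condition effect selectively: `erp_only`
(transient amplitude), `tfpower_only` (free-phase gain change — invisible
to the ERP by phase averaging and to phase statistics by uniformity),
`phase_only` (bimodal reset vs free phase — invisible to the ERP by
symmetry and to TF amplitude by construction), `combined` (all three on
distinct topographies), and `null` (no difference).  These are probes of
the analysis pipeline, not models of any real effect.

What the simulator does **not** emulate: volume conduction / forward-model
channel correlations (topographies are independent per-source gain
profiles), ocular or muscle artifacts, inter-participant variability in
effect topography or latency, multi-component ERP morphology, broadband
or multi-peak oscillations, and non-stationary background statistics.
Passing the dissociation and fusion suites therefore demonstrates that
the *pipeline* extracts and combines exactly the information placed in
each channel — it does not certify performance on real recordings.

## Problem sizes used by tests and the acceptance run

Protocol counts are exercised feature-free at the full 200-participant
geometry.  Classification suites run scaled cohorts chosen to finish in
minutes on one CPU while leaving clear statistical margins: 12
participants, 8 channels, 6 analysis frequencies (4–14 Hz), 8 procedure
iterations for the dissociation and fusion checks; three independent
24-participant cohorts (4 iterations each) for the null calibration —
independent cohorts matter there because iterations within one cohort
reuse the same 12 rare averages, so a chance separation would persist
across iterations and the binomial reference would be wrong; and 3
single-trial iterations (1152 samples each).  Full-scale settings remain
available through the configs.

## Known limitations

- The perceptron stack is linear per feature; it quantifies linearly
  decodable, low-order information only, by design.
- With 24 samples per scaled trial-average iteration, held-out sets are
  tiny (6 samples); stability comes from iterating, and per-iteration
  accuracies are strongly quantized.
- The sample-level split lets a participant straddle train and test; for
  cohorts with strong participant-specific structure the grouped split
  should be preferred, at the cost of deviating from the reference
  protocol.
- Baselining the phase-synchronization maps subtracts a pre-stimulus mean
  whose own sampling noise (E[stat] ≈ 0.06 at n = 24 under uniform
  phases) is non-negligible at small trial counts.
- The HDF5 feature bank holds all candidate averages in memory (float32);
  at the full 200-participant, 29-frequency geometry this is several GB
  and is intended for batch machines, not laptops.
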