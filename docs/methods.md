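# Methods

This note documents the models, the signal conventions, the synthetic
recording generator, and the numerical choices behind `engdecode`.

## Problem setting

After a lower-limb amputation the severed sciatic nerve still carries
efferent motor traffic when the person attempts to move the phantom limb.
Transversal intrafascicular multichannel electrodes (4 implants x 14
active sites = 56 channels) record this traffic as a multichannel
electroneurogram (ENG) at 30 kHz.  The package decodes which of six
movements (knee / ankle / toes x flexion / extension) was attempted from
100 ms windows of signal, and maps which channels are movement-modulated.

The experimental protocol assumed throughout: each movement class is
randomised within 3 blocks and repeated 10 times per block; a trial is 2 s
of movement (1 s flexion immediately followed by 1 s extension) then 2 s
of rest.  Times are seconds from recording start; intervals are half-open
`[start, end)`; the sample of time `t` is `floor(t*fs)`.

## Preprocessing

Powerline interference is removed by a cascade of IIR notch biquads at
every multiple of 50 Hz up to 10 kHz, quality factor Q = 100 (centre /
bandwidth).  Band content is then selected by a 4th-order Butterworth
band-pass: `eng` 250–7500 Hz (default), `imemg` 50–350 Hz, `eng_only`
350–7500 Hz, `hybrid` 50–7500 Hz.  Both filters are applied zero-phase
(forward–backward), which preserves spike timing across bands; the
effective roll-off is therefore that of an 8th-order filter.  The notch is
applied before the band-pass in every variant.  Note that at Q = 100 a
notch rings for ~0.6 s; short segments should be filtered as part of the
whole recording, not in isolation.

Channel quality control replaces the manual corrupted-file triage of
typical offline workflows with an automated gate: a channel is excluded
when more than 1% of its samples are non-finite or the trace is constant.
Ground contacts are carried in metadata but never enter decoding.

## Multi-unit spike detection and motor maps

Spikes are detected per channel where the rectified filtered signal
crosses `k x SD` from below (k = 3.5 or 4 depending on subject; SD over
the full trace), with a 1 ms dead time.  Firing rates use non-overlapping
100 ms bins.  For each channel and (joint, direction) condition the
modulation score is

    z = (mean action rate − mean rest rate) / SD(rest rate)

with action rates from the direction's 1 s phase windows of that joint's
trials, rest rates pooled over all 2 s rest windows.  A channel is
*responsive* for the condition when z > 0.5.  A zero rest-rate SD makes z
undefined; the implementation returns +inf when the action mean exceeds
the rest mean and 0 otherwise, with a warning, so downstream significance
logic stays monotone.  No multiple-testing correction is applied; the
Friedman test (scipy backend) is exposed separately for comparing rate
distributions across movements with channels as repeated measures.

Selectivity matrices partition the 56 channels per joint into
flexion-only / extension-only / both / silent; motor–sensory overlap
relates responsive channels to the anatomical region of electrically
evoked sensations (knee→knee/calf, ankle→ankle/heel, toes→foot/toes).
Structural similarity between neural activation and muscular involvement
uses the Herdin correlation-matrix distance

    d(R1, R2) = 1 − tr(R1 R2) / (||R1||_F ||R2||_F)  in [0, 1],

zero for matrices equal up to scale, one for trace-orthogonal ones.  Set
families (responsive channels per joint; involved muscles per movement)
are turned into symmetric Jaccard-overlap matrices before applying the
distance; the normalisation is a package choice and is configurable in
the sense that any correlation-like matrices may be passed directly.  The
shipped muscle table lists below-knee, sciatic-innervated muscles (7 on
the flexor side, 4 on the extensor side) with anatomy-based binary
involvement per movement; it is a package default, replaceable by a user
CSV.

## Event encoders

**Threshold encoding** bins the detected multi-unit crossings into 2.5 ms
windows (40 steps per 100 ms sample).

**LIF encoding** drives one leaky integrate-and-fire membrane per channel
with the full-wave-rectified, z-score-normalised signal:

    tau dU/dt = U_drive − U,   tau = 10 ms,

spiking when U ≥ 350 mV, resetting to 0 mV, with a 1 ms refractory
period.  Integration is forward Euler at the native sampling step (1/fs),
and the emitted events are binned at 2.5 ms.  Integrating at 2.5 ms
directly would make the 1 ms refractory meaningless, hence the
full-resolution simulation.  The drive gain — how many millivolts one
unit of normalised signal contributes — is not a physical constant of the
recording chain and must be set by design: a rectified z-scored Gaussian
trace has mean ≈ 0.8, so the default gain of 400 mV/unit places the
resting drive (~320 mV) just below threshold.  In this regime the event
rate rises steeply with signal power, which is what makes the encoder
informative; at much larger gains it saturates near the refractory limit
and carries almost no class information.  Normalisation statistics are
computed once per channel over the whole recording (`lif_events_recording`)
so that movement and rest amplitudes remain comparable; the segment-level
`lif_encode` normalises over the segment and is intended for unit-level
analysis.

**Double encoding** concatenates threshold then LIF channels, widening 56
inputs to 112.

## Spiking classifier

A single dense layer of second-order leaky integrate-and-fire output
neurons (6 or 4, one per class):

    I_syn[t] = alpha * I_syn[t−1] + W x[t]
    U[t]     = beta * U[t−1] + I_syn[t] − S[t−1] * U_thr
    S[t]     = 1 if U[t] ≥ U_thr else 0

with alpha = 0.95 (synaptic-current decay), beta = 0.98 (membrane decay),
U_thr = 0.5, and soft reset by threshold subtraction.  The predicted class
is the output neuron with the largest spike count over the 40 steps; ties
break to the lowest class index and are flagged.

Training minimises the MSE spike-count loss: the correct neuron's firing
fraction is pushed toward 0.8, all others toward 0.001.  Gradients flow
through the spike step via a fast-sigmoid surrogate derivative
`1/(slope*|U−U_thr|+1)^2` with slope 25; backpropagation through time is
implemented directly in numpy, including the reset pathway, and both the
weights and the per-neuron thresholds are trained with Adam (lr 1e-3,
batch 70, 500 epochs by default).  A cross-entropy loss on time-summed
membrane potentials is available behind `loss="ce_membrane"`.

Numerical choices:

- *Weight initialisation*: uniform in ±`init_scale`/√n_inputs with
  `init_scale = 0.3`, seed-controlled.  Under sustained event-rate input
  the layer's DC gain is 1/((1−alpha)(1−beta)) = 1000, so unit-scale
  initial weights drive the membrane hundreds of thresholds away from
  U_thr, where the surrogate derivative vanishes and learning stalls; the
  smaller scale keeps initial membrane excursions near threshold.
- *Thresholds* are clipped to stay positive during optimisation.
- *Folds*: stratified per class by round-robin after a seeded shuffle;
  the same fold array is reused byte-identically across the spiking and
  conventional decoders so comparisons share one split.
- *Electrode subsets*: groups of 14 channels per implanted electrode; all
  C(4,k) channel subsets are evaluated per size k (4, 6, 4, 1 models),
  and Pearson's R is computed between electrode count and per-combination
  accuracy.  For double-encoded data the matching LIF columns are sliced
  together with the threshold columns (widths 28/56/84/112).

## Conventional baselines

Per 100 ms sample and channel, two non-overlapping 50 ms sub-windows are
summarised by RMS, mean power (= RMS², asserted as an identity in the
tests) or threshold-crossing spike rate, concatenated channel-major into
112-dimensional vectors.  Decoders: linear SVM (C = 1) and an MLP with
one hidden layer of 236 units (210% of the input width, 500 iterations to
mirror the spiking budget, no early stopping).  Features are standardised
inside each training fold only (sklearn pipeline), structurally
preventing test-fold leakage.  An RBF-kernel SVM exists behind a flag but
is excluded from headline comparisons.

## Synthetic recording generator

The generator emulates the study protocol and provides ground truth; it
backs every end-to-end test.  Per channel it sums

- Gaussian broadband noise (SD 1 by convention),
- powerline sinusoids at 50/100/150 Hz (amplitudes 0.5/0.25/0.15 noise
  SD, per-channel random phase),
- an inhomogeneous-Poisson multi-unit train rendered with a fixed
  biphasic template (0.3 ms positive, 0.7 ms negative lobe; amplitude a
  configurable multiple of the noise SD; 1 ms minimum gap), whose rate is
  the 8 Hz baseline everywhere except the phases of the classes the
  channel is tuned to, where it is gain-multiplied,
- optionally an amplitude-modulated 50–350 Hz band component standing in
  for residual inter-muscular EMG.

Baseline and modulated firing rates default to the 7–40 Hz range typical
of intraneural multi-unit recordings.  What the generator does *not*
emulate: spike-waveform diversity and overlap, electrode impedance drift,
movement artifacts, correlated (shared) noise across channels, and
session-to-session nonstationarity.  Passing the recovery tests therefore
shows that the pipeline is correct and sensitive under the stated noise
model, not that the real-data accuracies are reproduced.

Presets:

- `high-snr-separable` — site s of every 14-site electrode group is tuned
  to class `s mod 6` with an 8x rate gain and 8-SD spike amplitude, so
  every electrode carries information about every class and the classes
  are cleanly decodable; this is the positive control for pipeline
  recovery.
- `low-snr` — 2x gain, 4-SD amplitude.
- `null` — no tuning anywhere; the negative control, decoding must sit at
  chance.
- `s2-like` — four classes (knee excluded), flexion-dominant gains.
- `rate-coded` — 5x rate gain but spike amplitude held constant at 1.5
  noise SD and a 30 Hz baseline: individual crossings are buried in the
  noise so threshold-based spike-rate features degrade, while the
  aggregate power that the LIF membrane encoder transduces still carries
  the classes.  This preset isolates the regime where event-based power
  encoding beats threshold counting.

## Problem sizes used in the test battery

End-to-end checks run a reduced protocol — 6 classes x 1 block x 10
repetitions (240 s of 56-channel signal at 30 kHz) for decoding recovery
and electrode subsets, 5 repetitions for the decoder-ordering comparison,
and 2-channel sessions for the 50-replicate modulation-recovery check —
with 100 training epochs (40 for the electrode-subset sweep).  The full
3-block, 500-epoch configuration is the library default.  The decoding
pipeline applies the powerline notch only when requested
(`notch=True`, the default for real recordings); the synthetic recovery
runs skip it because the generator's 50–150 Hz interference lies entirely
below the 250 Hz band edge, where the band-pass already removes it.

## Known limitations

- The spike detector assumes stationary noise; SD over the full trace is
  biased upward on channels with dense high-amplitude spiking.
- The LIF encoder's gain is a design constant, not estimated from data;
  recordings with very different dynamic ranges may need a different
  value (`EncoderParams.gain_mv`).
- Per-sample classification only; no trial-level aggregation or online
  decoding.
- No spike sorting: all threshold crossings are pooled multi-unit
  activity.
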