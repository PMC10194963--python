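# Methods

This note documents the models, estimators, parameter choices and known
limitations of `okninfo`. It is written for users who need to judge what
the package computes and what its passing tests do — and do not — imply
about real data.

## Scientific setting

A bistable stimulus (an ambiguous moving plaid) is perceived either as one
integrated object (INT) or as two differentiated objects (DIF), and
perception alternates spontaneously with gamma-distributed dominance
durations. The slow phase of the optokinetic nystagmus (OKN) follows the
*perceived* motion direction, so the sign of slow-phase eye velocity is a
report-free index of the current percept and its zero-crossings mark
perceptual switches. The package quantifies, around these switches, three
EEG-derived quantities: directed information between anterior and
posterior regions (information integration), compression complexity of
single-region signals (information differentiation), and Morlet
time-frequency power — each compared between to-INT and to-DIF switches
with cluster-based permutation statistics.

## OKN slow-phase velocity and switch detection

The raw eye-position trace is processed as:

1. **Fast-phase stitching.** OKN is a sawtooth: slow-phase drift
   interrupted by resetting saccades. Using the annotated saccade
   intervals (padded 10 ms), the position jump across each interval —
   estimated from 50-ms sample averages on either side so single-sample
   noise does not leak in — is subtracted from all later samples, leaving
   the cumulative slow-phase position. Stitching runs on the raw trace:
   a zero-phase filter would smear the resets, and a blink bridged across
   an unstitched sawtooth acquires an arbitrary slope.
2. **Blink interpolation** from 150 ms before to 150 ms after each blink
   (linear between boundary samples; boundary blinks hold the nearest
   valid value, with a warning).
3. **Low-pass filtering**: third-order Butterworth at 10 Hz, applied
   forward–backward (zero-phase) so crossing times are not biased by
   filter latency.
4. Optional **event-response deconvolution**: blink/saccade-locked mean
   responses estimated by least squares on a shifted-indicator design
   matrix (default window 0–6 s, solved sparsely with LSQR) and regressed
   out. Identifiability requires irregular event spacing; perfectly
   periodic overlapping events determine the kernel only up to a shifted
   combination.
5. Optional **percent-signal-change** scaling around the block mean.
6. **Velocity**: Gaussian smoothing, first difference of neighbouring
   samples, second Gaussian smoothing. "100-ms kernel" is interpreted as
   full width at half maximum (SD = 100/2.355 ms, truncated at ±3 SD);
   a flag switches to the SD interpretation. Output length equals input
   length (the first difference sample is duplicated); the first/last
   kernel width is unreliable.

**Switch detection** takes debounced zero-crossings of the velocity:
crossings are accepted only when they flip the current sign state, when
|velocity| exceeds a hysteresis threshold (default 10% of the velocity SD)
before the next crossing, and when they are at least `min_separation`
(default 0.5 s) from the previous accepted crossing — a back-crossing
inside the debounce window *reverts* the previous acceptance, which
prevents a noise blip from deadlocking the alternation state. With the
default polarity, a positive-to-negative crossing is a switch to INT (the
slow phase drifts negative during the integrated percept); the polarity is
a flag because the stimulus drift direction alternates across runs.
Crossings that fall inside blink-interpolated spans are re-estimated by
fitting a parabola to the clean position samples within ±0.8 s and taking
its vertex (the apex of the slow-phase reversal); the fit is iterated
three times. This recovers most switch times that a blink would otherwise
displace by up to the bridge length.

## CNN decoder

`OKNConvNet` classifies single slow-phase-velocity epochs (default 625
samples = 1.25 s at 500 Hz, symmetric around the crossing) as to-INT vs
to-DIF. Architecture: conv 8 filters 1×25 (ReLU, stride 1) → max-pool 1×5
stride 2 → conv 16 filters 2×50 (ReLU) → max-pool 1×5 stride 2 → conv 32
filters 2×75 (ReLU) → dense 2 with softmax. The 2×k kernels are
dimensionally ambiguous on a one-channel signal; here the 8 feature maps
from the first convolution are stacked as a second spatial axis, the 2×50
convolution runs as a single-channel 2-D convolution over (map, time), and
the 2×75 convolution as an ordinary 16-channel 2-D convolution. A 1-D
variant (kernels 50 and 75 over time only) is available via
`conv1d=True`. Valid padding throughout; layer lengths follow
`floor((L−k)/s)+1`.

Training: cross-entropy loss, SGD with momentum 0.9, mini-batches of 128,
30 epochs, the training set reshuffled every epoch, validation accuracy logged
every 10 mini-batches. The learning rate (not part of the printed regime)
defaults to 0.01. Inputs are scaled by the global training SD (no mean
subtraction, so an all-zero input stays at even odds with zero-initialised
biases). He-normal initialisation; everything is driven by one
`random_state`, making fits bit-reproducible. No early stopping, padding,
or augmentation. The implementation is plain numpy (im2col convolutions,
per-kernel-offset GEMMs for the input gradient).

## Directed information (dir-INFO)

For sender X and receiver Y (ROI-averaged, switch-locked epochs) and each
grid point (t, τ):

    dir-INFO(t, τ) = I(Y_t ; X_{t−τ} | Y_{t−τ})

estimated *across epochs*: each of the three variables is rank-transformed
to standard-normal margins (Gaussian copula, ranks → Φ⁻¹((r−0.5)/n), ties
broken stably with a warning), then the conditional mutual information is
computed in closed form from covariance determinants,
`I = ½·log2(|Σxz||Σyz| / (|Σz||Σxyz|))`, in bits. The estimator is
invariant under monotone amplitude transforms of either signal. τ = 0 is
identically zero (conditioning on Y_t itself) and is returned as such;
grid entries with t−τ before the epoch start are NaN and excluded from
statistics rather than zero-filled. An optional small-sample bias
correction (digamma-based, off by default) subtracts the expected
entropy bias. Delays default to 0–500 ms in 4-ms steps (the 250-Hz sample
period); delays must be sample multiples. The across-epoch estimator
requires at least 16 epochs per condition; group pipelines here use ~35–40.

## Information differentiation (diff-INFO)

Each 100-ms window (25 samples at 250 Hz, 4-ms step) is discretised into
32 equal-width amplitude bins spanning the window's own range (making the
measure locally affine-invariant; per-epoch binning is available via the
`symbolize` building blocks), one byte per symbol, and compressed with raw
DEFLATE at fixed level 6 with header bytes excluded, so ratios are
comparable across platforms. The compression ratio (compressed/original
bytes) is an upper-bound proxy for Kolmogorov complexity: constant <
oscillatory < white noise. At the 25-byte window size the measure has
coarse resolution (DEFLATE overhead dominates), so single-window values
hover near 1 and condition differences emerge only after averaging over
many windows and epochs — a property of the published parameterisation,
not of this implementation.

## Spectral analysis

Complex Morlet wavelets (Gaussian-windowed complex exponentials,
SD = cycles/(2πf)) at 13 linearly spaced frequencies 2–26 Hz with cycle
counts log-spaced 3→12 in frequency order; convolution via FFT; power =
squared magnitude, averaged over epochs. Wavelets are normalised to unit
gain for a matched sinusoid (the normalisation cancels in dB). dB
normalisation divides each frequency row by its mean power over the
baseline window — by stated convention the *entire* trial (−2000 to
+500 ms), including post-event time — and takes 10·log10. Half a wavelet
length at each edge is flagged unreliable (`n_edge`), not trimmed.

## Cluster-based permutation statistics

Subject-wise condition averages are compared point-wise with
dependent-samples t tests; points with p < 0.01 are clustered under
adjacency (1-D neighbours; 4-connectivity on 2-D grids) and each
cluster's mass is its summed t. The null distribution records, per
permutation (default 1000; the calibration studies here use 199), the
largest |cluster mass| after randomly exchanging condition labels within
subjects (equivalently sign-flipping the difference maps); observed
clusters get Monte-Carlo p = (1 + #{perm ≥ observed})/(n_perm + 1).
Positive and negative clusters form separate families. Zero-variance
points with nonzero mean get a large finite stand-in t (not ±inf) so
cluster sums stay ordered. Interaction (double-subtraction) contrasts
test per-subject (A1−A2)−(B1−B2) against zero with the one-sample
sign-flip analogue.

## EEG preprocessing and epoching

Resample to 250 Hz (polyphase), band-pass 1–100 Hz (4th-order zero-phase
Butterworth), 50-Hz notch, average reference — in that order. Channels
whose variance deviates more than ±2 SD from the mean channel variance
are flagged for dropping (interpolation is delegated to established EEG
tooling; ICA-based artifact removal is likewise out of scope — the
pipeline accepts already-cleaned signals). Epochs span −2000 to +500 ms
around the lock event (half-open sample windows, 0-based indexing);
rejection on amplitude (any |sample| > 150 µV) and on drift ("slope"
read as the magnitude of the least-squares linear fit's total rise over
the epoch, threshold 60 µV). Trial exclusion removes switches whose
predecessor occurred < 2 s earlier, same-direction repetitions, and
events whose epoch window contains another response; counts are
first-rule attributed and conserved. ROI montages (front, back, left and
right temporal; six channels each, disjoint) ship as an editable,
synthetic reconstruction of canonical 10–20 clusters — the published
electrode sets exist only as a figure.

## Synthetic-data generator

The generator encodes the study conditions the analyses are tested under:

* **Percept schedule**: gamma(shape 3, scale 2 s) dominance durations —
  conventional values for rivalry, not taken from any dataset — with
  strictly alternating INT/DIF labels.
* **OKN trace** (500 Hz): slow-phase slope ±1 unit/s (negative during
  INT), logistic slope transitions with 400-ms 10–90% width, Poisson fast
  phases (2 Hz) that reset position to the running baseline, Poisson
  blinks (0.25 Hz, 100–300 ms, NaN sentinel), Gaussian tracker noise
  (SD 0.03 units — "clean" tracking; tests of graceful degradation sweep
  this up to 2). Fast phases are suppressed inside blink gaps: a tracker
  cannot annotate a saccade while the eye is closed, and an unannotated
  reset would be unrecoverable by any downstream method.
* **EEG** (250 Hz, 24 channels by default): per-channel 1/f background
  (SD 1). Anterior channels share a *white* latent source A(t); in the
  600 ms before each switch they additionally carry a 4-Hz oscillation
  whose amplitude depends on the upcoming percept (2 before INT, 0 before
  DIF). Posterior channels receive g·A(t − 100 ms), with g = 1 before
  to-INT switches, 0 before to-DIF, 0 at baseline. A is white so that its
  autocorrelation is a delta: the anterior→posterior cross-correlation and
  the dir-INFO map then peak exactly at the injected delay, and no
  spurious reverse-direction information leaks through source
  autocorrelation. Consequently the dir-INFO effect is sharp in the delay
  axis — delay grids must include the true lag (the default 4-ms step
  does).
* **Button events**: normally distributed report latencies, mean 0.5 s
  after to-INT and 0.4 s after to-DIF switches (SD 0.1 s), emulating the
  slower report of integration.

What the generator does **not** emulate: volume conduction and realistic
topographies, non-stationary artifacts (drifts, EMG), oscillatory
structure beyond the injected 4-Hz burst, nonlinear coupling, or
perception–eye interactions beyond the slope sign. Passing tests
therefore show the estimators and statistics behave correctly under the
assumed signal structure — not that real recordings satisfy it.

## Problem sizes used in the calibration studies

All simulation studies are sized for a single CPU: group
directed-information studies use 12 subjects × 480-s sessions (≈35–40
epochs per condition), delay grid 0–200 ms in 4-ms steps, epoch window
−800 to +100 ms; null-calibration studies use 100 replicates of 40
subjects × 320-s sessions with 199 permutations, an 8-ms delay step for
the dir-INFO null and a 20-ms complexity step; decoder property sweeps
(chance level on shuffled labels, noise monotonicity) use 448-sample
inputs, 128 training epochs and 10 training passes, while the headline
accuracy run uses the full 625-sample architecture with a 500-epoch
dataset and the complete 70/15/15 split and 30-pass regime. These sizes
are the package's defaults for its own validation studies; every
underlying routine accepts the full-scale parameters.

## Numerical choices and degenerate inputs

* Copula transform requires ≥ 2 samples and non-constant input; ties warn.
* CMI: conditioning variables that numerically determine x or y return 0
  (the information is zero by definition) instead of raising; a truly
  singular covariance raises.
* `fit_gamma` rejects constant durations (the MLE diverges) and requires
  n ≥ 20.
* Degenerate zero-variance paired differences map to a large finite t.
* All filters are zero-phase; all seeds flow through
  `numpy.random.default_rng`; identical configurations reproduce outputs
  bit-exactly.

## Known limitations

* The deconvolution step assumes a shared, time-invariant event kernel;
  sign-varying fast-phase jumps are handled by stitching, not
  deconvolution.
* Blink bridges destroy the data inside them; the parabola refinement
  recovers the switch apex only when the surrounding ±0.8 s is largely
  clean, so switch recall saturates near (not at) 100% under blinking.
* The across-epoch CMI estimator is biased upward at small epoch counts;
  comparisons are within-design (same n per condition), and the optional
  bias correction is available for absolute values.
* BDF/EDF reading is a thin wrapper over mne and is exercised only
  against synthetic in-memory recordings in the test suite.
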