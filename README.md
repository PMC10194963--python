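# okninfo

Information dynamics of bistable perception, with and without report.

When observers view an ambiguous moving-plaid stimulus, perception
alternates spontaneously between one *integrated* object (INT) and two
*differentiated* objects (DIF). Because the slow phase of the optokinetic
nystagmus (OKN) follows the perceived motion direction, the sign of
slow-phase eye velocity tracks the current percept — so perceptual
switches can be read out from the eyes alone, without button presses.
`okninfo` implements the full analysis pipeline around this idea, for
researchers in cognitive neuroscience who want to relate EEG information
dynamics to perceptual switches in report and no-report conditions:

* **OKN processing** (`okninfo.okn`) — blink interpolation, fast-phase
  stitching, zero-phase 10 Hz Butterworth filtering, event-response
  deconvolution, slow-phase velocity (twice-smoothed 100-ms-Gaussian first
  difference), debounced zero-crossing switch detection, gamma fits of
  dominance durations, and OKN-to-button-press delays.
* **CNN decoder** (`okninfo.decoder`) — a scikit-learn-style
  convolutional classifier (`OKNConvNet`) of perceptual state from single
  1.25-s velocity epochs: conv(8, 1×25) → pool(1×5, s2) → conv(16, 2×50)
  → pool(1×5, s2) → conv(32, 2×75) → dense(2, softmax), trained with
  SGD-momentum (0.9), batches of 128, 30 epochs, stratified 70/15/15
  splits. Forward and backward passes are plain numpy.
* **Information dynamics** (`okninfo.infodyn`) —
  *directed information* (transfer entropy at lag τ),
  `dir-INFO(t, τ) = I(Y_t ; X_{t−τ} | Y_{t−τ})`, estimated across epochs
  with the Gaussian-copula method on a (delay × time) grid (delays
  0–500 ms in 4-ms steps); and *information differentiation*
  (K complexity), the DEFLATE compression ratio of 32-symbol amplitude
  discretisations in 100-ms sliding windows (4-ms step).
* **Spectral analysis** (`okninfo.spectral`) — complex Morlet
  time–frequency power (2–26 Hz in 2-Hz bins, 3–12 log-spaced cycles) with
  `dB = 10·log10(power/baseline)` normalization.
* **Cluster statistics** (`okninfo.stats`) — dependent-samples t maps,
  cluster-based permutation tests (point α = 0.01, summed-t cluster mass,
  sign-flip null of the largest cluster), and double-subtraction
  interaction contrasts.
* **Synthetic sessions** (`okninfo.syndata`) — a ground-truthed generator
  producing gamma-distributed percept schedules, OKN traces with
  blinks/fast phases, and multichannel EEG with switch-dependent
  anterior→posterior lagged coupling and anterior low-frequency
  modulation, so the entire pipeline is testable end to end.
* **I/O and preprocessing** (`okninfo.core_io`) — 250-Hz resampling,
  1–100 Hz band-pass, 50-Hz notch, average reference, ±150 µV amplitude
  and 60 µV/epoch slope rejection, the 2-s trial-exclusion rule, ROI
  definitions, and HDF5/TSV containers.

## Worked example

```python
import numpy as np
from okninfo import SimConfig, simulate_session, okn, core_io, infodyn

sess = simulate_session(SimConfig(seed=1), session_length=240.0)

# eyes: slow-phase velocity and report-free switch detection
vel = okn.slow_phase_pipeline(sess.okn)
events = okn.detect_switches(vel)
true_t = np.array([e.time for e in sess.switch_events])
det_t = np.array([e.time for e in events])
recall = np.mean([np.min(np.abs(det_t - t)) <= 0.1 for t in true_t])
print(f"detected {len(events)} switches, recall@100ms = {recall:.3f}")

# brain: directed information front -> back before to-INT switches
kept, _ = core_io.filter_switch_events(sess.switch_events)
eps = core_io.epoch_and_reject(sess.eeg, kept,
                               core_io.EpochCriteria(window=(-1.0, 0.1)))
front = core_io.roi_average(eps, "front", condition="to_INT")
back = core_io.roi_average(eps, "back", condition="to_INT")
m = infodyn.directed_information(front, back, delays=np.arange(0, 204, 4.0))
i, j = np.unravel_index(np.nanargmax(np.nan_to_num(m.values)), m.values.shape)
print(f"dir-INFO peak {np.nanmax(m.values):.2f} bits "
      f"at delay {m.delays[i]:.0f} ms, t = {m.times[j]:.0f} ms")
```

Output:

```
detected 44 switches, recall@100ms = 0.955
dir-INFO peak 1.42 bits at delay 100 ms, t = -564 ms
```

The detector recovers nearly all scheduled switches within ±100 ms, and
the directed-information map peaks at the generator's injected 100-ms
anterior→posterior coupling delay, inside the 600-ms pre-switch window in
which the coupling is active.

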