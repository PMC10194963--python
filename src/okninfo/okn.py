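"""Optokinetic-nystagmus (OKN) signal processing.

During bistable viewing of an ambiguous plaid the slow phase of the OKN
tracks the currently perceived motion direction, so the sign of slow-phase
velocity is a report-free marker of the dominant percept and its
zero-crossings mark perceptual switches.  This module turns a raw
oculomotor trace into slow-phase velocity, detects switches as debounced
zero-crossings, and summarises dominance durations (gamma fits) and the
delay between oculomotor and button-press reports.

Preprocessing follows the standard pupil/OKN chain: linear interpolation
across blinks (padded 150 ms), zero-phase 3rd-order Butterworth low-pass at
10 Hz, least-squares deconvolution of blink/saccade-locked responses, and
conversion to percent signal change around the block mean.  Slow-phase
velocity is the twice-smoothed (100-ms Gaussian kernel) first difference of
the trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal, sparse, stats
from scipy.sparse.linalg import lsqr

__all__ = [
    "OculomotorTrace",
    "SlowPhaseVelocity",
    "SwitchEvent",
    "DelayResult",
    "interpolate_blinks",
    "remove_fast_phases",
    "slow_phase_pipeline",
    "lowpass_filter",
    "remove_event_responses",
    "to_percent_signal_change",
    "slow_phase_velocity",
    "extract_velocity_epochs",
    "detect_switches",
    "fit_gamma",
    "okn_report_delay",
    "paired_delay_ttest",
]

#: 100-ms Gaussian kernel width interpreted as full width at half maximum.
FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class OculomotorTrace:
    """Continuous eye-position signal with blink/saccade annotations.

    Parameters
    ----------
    samples : ndarray
        Eye-position samples (arbitrary units).  Missing samples (blinks)
        are NaN.
    rate : float
        Sampling rate in Hz (eye tracker default 500 Hz).
    start_time : float
        Time of the first sample, seconds.
    blink_events, saccade_events : list of (onset, offset)
        Event intervals in seconds.
    """

    samples: np.ndarray
    rate: float = 500.0
    start_time: float = 0.0
    blink_events: list = field(default_factory=list)
    saccade_events: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class SlowPhaseVelocity:
    """Slow-phase OKN velocity (arbitrary units per sample step)."""

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    provenance: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate


@dataclass(frozen=True)
class SwitchEvent:
    """A perceptual transition.

    ``direction`` is ``"to_INT"`` (switch to the integrated percept) or
    ``"to_DIF"`` (switch to the differentiated percept); ``source`` records
    whether the event comes from a button press, an OKN zero-crossing, or
    the simulator's ground truth.
    """

    time: float
    direction: str
    source: str = "okn_crossing"

    def __post_init__(self):
        if self.direction not in ("to_INT", "to_DIF"):
            raise ValueError(f"invalid direction {self.direction!r}")


def _event_to_slice(onset: float, offset: float, trace: OculomotorTrace) -> tuple[int, int]:
    """Half-open sample interval [i0, i1) covering [onset, offset)."""
    i0 = int(np.floor((onset - trace.start_time) * trace.rate))
    i1 = int(np.ceil((offset - trace.start_time) * trace.rate))
    return max(i0, 0), min(i1, trace.samples.size)


def interpolate_blinks(trace: OculomotorTrace, pad: float = 150.0) -> OculomotorTrace:
    """Replace blink intervals (padded by ``pad`` ms on each side) by linear
    interpolation between the boundary samples.

    A blink touching the trace boundary is filled by holding the nearest
    valid sample (with a warning).  Any NaN samples not covered by an
    annotated blink are interpolated as well so no missing values remain.
    """
    x = trace.samples.copy()
    n = x.size
    pad_s = pad / 1000.0
    missing = np.isnan(x)
    for onset, offset in trace.blink_events:
        i0, i1 = _event_to_slice(onset - pad_s, offset + pad_s, trace)
        missing[i0:i1] = True
    if not missing.any():
        return replace(trace, samples=x)
    valid = ~missing
    if not valid.any():
        raise ValueError("no valid samples left after blink padding")
    if missing[0] or missing[-1]:
        warnings.warn("blink touches trace boundary; holding nearest valid value")
    idx = np.arange(n)
    x[missing] = np.interp(idx[missing], idx[valid], x[valid])
    return replace(trace, samples=x)


def remove_fast_phases(
    trace: OculomotorTrace,
    saccade_events: list | None = None,
    pad: float = 10.0,
) -> OculomotorTrace:
    """Stitch fast-phase resets out of the position trace (cumulative
    slow-phase, the "integrated OKN").

    For each annotated saccade interval (padded by ``pad`` ms) the position
    jump across the interval — estimated from 50-ms sample averages on
    either side, so single-sample noise does not leak into the estimate —
    is subtracted from everything after it and the interval itself is
    linearly interpolated, leaving the continuous slow-phase drift whose
    derivative is the slow-phase velocity.  Apply to the raw, unfiltered
    trace *before* blink interpolation: a zero-phase filter smears the
    resets over tens of milliseconds, and a blink bridged across an
    unstitched sawtooth acquires an arbitrary slope.  Blink NaNs are
    tolerated (nan-aware side averages); a reset with no valid samples on
    either side is skipped.
    """
    x = trace.samples.copy()
    n = x.size
    pad_s = pad / 1000.0
    k = max(int(round(0.05 * trace.rate)), 1)
    events = trace.saccade_events if saccade_events is None else saccade_events
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # nanmean of all-NaN
        for onset, offset in sorted(events):
            i0, i1 = _event_to_slice(onset - pad_s, offset + pad_s, trace)
            if i0 - k < 0 or i1 + k > n:
                continue
            after = np.nanmean(x[i1 : i1 + k])
            before = np.nanmean(x[i0 - k : i0])
            if not (np.isfinite(after) and np.isfinite(before)):
                continue
            x[i1:] -= after - before
            if np.isfinite(x[i0 - 1]) and np.isfinite(x[i1]):
                x[i0:i1] = np.linspace(x[i0 - 1], x[i1], i1 - i0 + 2)[1:-1]
    return replace(trace, samples=x, saccade_events=list(events))


def slow_phase_pipeline(
    trace: OculomotorTrace,
    cutoff: float = 10.0,
    percent_change: bool = False,
    deconvolve_events: bool = False,
    kernel_ms: float = 100.0,
) -> SlowPhaseVelocity:
    """Standard chain from raw trace to slow-phase velocity: blink
    interpolation, fast-phase stitching, 10 Hz low-pass, optional
    deconvolution of residual blink/saccade-locked responses, optional
    percent-signal-change scaling, then the smoothed-difference velocity."""
    t = remove_fast_phases(trace)
    t = interpolate_blinks(t)
    t = lowpass_filter(t, cutoff=cutoff)
    if deconvolve_events:
        t = remove_event_responses(t, t.blink_events, t.saccade_events)
    if percent_change:
        t = to_percent_signal_change(t)
    vel = slow_phase_velocity(t, kernel_ms=kernel_ms)
    # carry the cleaned position and the interpolated spans so crossing
    # times inside blink bridges can be refined by slope intersection
    pad_s = 0.150
    vel.provenance["position"] = t.samples
    vel.provenance["interp_spans"] = [(on - pad_s, off + pad_s) for on, off in t.blink_events]
    return vel


def lowpass_filter(trace: OculomotorTrace, cutoff: float = 10.0, order: int = 3) -> OculomotorTrace:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    if cutoff >= trace.rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({trace.rate / 2} Hz)")
    if np.isnan(trace.samples).any():
        raise ValueError("interpolate blinks before filtering")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.rate, output="sos")
    return replace(trace, samples=signal.sosfiltfilt(sos, trace.samples))


def remove_event_responses(
    trace: OculomotorTrace,
    blink_events: list | None = None,
    saccade_events: list | None = None,
    window: tuple[float, float] = (0.0, 6.0),
) -> OculomotorTrace:
    """Estimate and remove event-locked responses by deconvolution.

    A design matrix of shifted event indicators over ``window`` (seconds
    relative to event onset) is regressed onto the trace by least squares;
    this recovers each event type's mean impulse response even when events
    overlap (unlike event-locked averaging).  The fitted predictors are then
    subtracted from the trace.  Recovered kernels are stored under
    ``provenance``-like attributes on the returned trace via the
    ``blink_events``/``saccade_events`` fields being preserved; kernels are
    returned through :func:`estimate_event_kernels` if needed.
    """
    trace_out, _ = _deconvolve(trace, blink_events, saccade_events, window)
    return trace_out


def estimate_event_kernels(
    trace: OculomotorTrace,
    blink_events: list | None = None,
    saccade_events: list | None = None,
    window: tuple[float, float] = (0.0, 6.0),
) -> dict[str, np.ndarray]:
    """Return the deconvolved event-locked kernels without removing them."""
    _, kernels = _deconvolve(trace, blink_events, saccade_events, window)
    return kernels


def _deconvolve(trace, blink_events, saccade_events, window):
    x = trace.samples
    n = x.size
    if np.isnan(x).any():
        raise ValueError("interpolate blinks before deconvolution")
    w0, w1 = window
    k = int(round((w1 - w0) * trace.rate))
    if k <= 0:
        raise ValueError("window must have positive length")
    if k > n:
        raise ValueError("deconvolution window longer than trace")
    streams = {}
    if blink_events:
        streams["blink"] = [on for on, _ in blink_events]
    if saccade_events:
        streams["saccade"] = [on for on, _ in saccade_events]
    if not streams:
        return replace(trace, samples=x.copy()), {}

    cols, rows, vals = [], [], []
    col0 = {}
    ncol = 0
    for name, onsets in streams.items():
        col0[name] = ncol
        for on in onsets:
            i = int(round((on + w0 - trace.start_time) * trace.rate))
            lags = np.arange(k)
            ridx = i + lags
            keep = (ridx >= 0) & (ridx < n)
            rows.append(ridx[keep])
            cols.append(ncol + lags[keep])
            vals.append(np.ones(keep.sum()))
        ncol += k
    X = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, ncol),
    )
    mu = x.mean()
    beta = lsqr(X, x - mu, atol=1e-10, btol=1e-10, iter_lim=4 * ncol)[0]
    fitted = X @ beta
    kernels = {name: beta[c0 : c0 + k].copy() for name, c0 in col0.items()}
    return replace(trace, samples=x - fitted), kernels


def to_percent_signal_change(trace: OculomotorTrace, block_mean: float | None = None) -> OculomotorTrace:
    """Convert to percent signal change around the (block) mean:
    ``100 * (x - mean) / mean``."""
    mean = float(np.nanmean(trace.samples)) if block_mean is None else float(block_mean)
    if mean == 0:
        raise ValueError("block mean is zero; percent signal change undefined")
    return replace(trace, samples=100.0 * (trace.samples - mean) / mean)


def gaussian_kernel_sd_samples(rate: float, width_ms: float = 100.0, fwhm: bool = True) -> float:
    """SD in samples of the smoothing kernel; ``width_ms`` is interpreted as
    FWHM by default (SD = width / 2.355), or directly as the SD."""
    width_samp = width_ms / 1000.0 * rate
    return width_samp / FWHM_TO_SD if fwhm else width_samp


def slow_phase_velocity(
    trace: OculomotorTrace, kernel_ms: float = 100.0, kernel_is_fwhm: bool = True
) -> SlowPhaseVelocity:
    """Slow-phase OKN velocity: Gaussian smoothing, first difference between
    neighbouring samples, second Gaussian smoothing.

    Output has the same length as the input; the first sample of the
    difference is duplicated (edge policy) and the first/last kernel width
    is unreliable.  Units are amplitude-units per sample step (2 ms at
    500 Hz).
    """
    x = trace.samples
    if np.isnan(x).any():
        raise ValueError("interpolate blinks before computing velocity")
    sd = gaussian_kernel_sd_samples(trace.rate, kernel_ms, kernel_is_fwhm)
    if x.size < int(6 * sd) + 2:
        raise ValueError("trace shorter than smoothing kernel")
    sm = ndimage.gaussian_filter1d(x, sd, mode="nearest", truncate=3.0)
    vel = np.diff(sm)
    vel = np.concatenate([vel[:1], vel])  # keep length; edge sample duplicated
    vel = ndimage.gaussian_filter1d(vel, sd, mode="nearest", truncate=3.0)
    return SlowPhaseVelocity(
        values=vel,
        rate=trace.rate,
        start_time=trace.start_time,
        provenance={"kernel_ms": kernel_ms, "kernel_is_fwhm": kernel_is_fwhm, "sd_samples": sd},
    )


def detect_switches(
    vel: SlowPhaseVelocity,
    min_separation: float = 0.5,
    hysteresis: float | None = None,
    positive_to: str = "to_DIF",
) -> list[SwitchEvent]:
    """Detect perceptual switches as debounced zero-crossings of slow-phase
    velocity.

    A negative-to-positive crossing maps to ``positive_to`` (default
    ``"to_DIF"``: during the integrated percept the slow phase drifts
    negative, so crossing into positive velocity marks a switch to the
    differentiated percept) and the opposite crossing to the other
    direction.  The polarity flag exists because the stimulus drift
    direction alternates across runs.

    Crossings closer than ``min_separation`` seconds to the previously
    accepted crossing are discarded, as are crossings after which |velocity|
    never exceeds ``hysteresis`` (default: 10% of the velocity SD) before
    the next crossing.  Accepted directions strictly alternate.
    """
    v = vel.values
    if hysteresis is None:
        hysteresis = 0.1 * float(np.std(v))
    if not np.any(v != 0):
        warnings.warn("all-zero velocity; no switches detected")
        return []
    if positive_to not in ("to_DIF", "to_INT"):
        raise ValueError("positive_to must be 'to_DIF' or 'to_INT'")
    negative_to = "to_INT" if positive_to == "to_DIF" else "to_DIF"

    sgn = np.sign(v)
    # carry last nonzero sign through exact zeros
    nz = sgn != 0
    if not nz[0]:
        first = np.argmax(nz)
        sgn[:first] = sgn[first]
        nz[:first] = True
    idx_nz = np.where(nz)[0]
    filled = sgn[idx_nz][np.searchsorted(idx_nz, np.arange(v.size), side="right") - 1]
    cross = np.where(np.diff(filled) != 0)[0] + 1

    events: list[SwitchEvent] = []
    state = filled[0]
    bounds = list(cross) + [v.size]
    for j, i in enumerate(cross):
        new_sign = filled[i]
        if new_sign == state:
            continue  # enforced alternation after a discarded crossing
        t = vel.start_time + i / vel.rate
        if events and t - events[-1].time < min_separation:
            # chatter: the trace crossed back within the debounce window, so
            # the previous acceptance was a blip — revert it instead of
            # deadlocking the alternation state
            events.pop()
            state = new_sign
            continue
        seg = np.abs(v[i : bounds[j + 1]])
        if seg.size == 0 or seg.max() < hysteresis:
            continue
        direction = positive_to if new_sign > 0 else negative_to
        events.append(SwitchEvent(time=t, direction=direction, source="okn_crossing"))
        state = new_sign
    return _refine_bridged_crossings(vel, events)


def _refine_bridged_crossings(
    vel: SlowPhaseVelocity,
    events: list[SwitchEvent],
    half: float = 0.8,
    n_iter: int = 3,
) -> list[SwitchEvent]:
    """Re-estimate crossing times that fall in or near blink-interpolated
    spans.

    Inside an interpolated bridge the position trace is a straight line, so
    the velocity zero-crossing lands near a bridge edge rather than at the
    true switch.  Around a switch the cleaned position is a smooth apex
    (the slow phase reverses sign); fitting a parabola to the clean samples
    within ``half`` seconds of the crossing and taking its vertex recovers
    the reversal time.  The fit is iterated, re-centering on the vertex.
    """
    pos = vel.provenance.get("position")
    spans = vel.provenance.get("interp_spans")
    if pos is None or not spans:
        return events
    clean = np.ones(pos.size, dtype=bool)
    for s0, s1 in spans:
        i0 = max(int(round((s0 - vel.start_time) * vel.rate)), 0)
        i1 = min(int(round((s1 - vel.start_time) * vel.rate)), pos.size)
        clean[i0:i1] = False

    out = []
    for ev in events:
        t_new = ev.time
        if any(s0 - 0.3 <= ev.time <= s1 + 0.3 for s0, s1 in spans):
            t = ev.time
            for _ in range(n_iter):
                c = int(round((t - vel.start_time) * vel.rate))
                lo = max(c - int(half * vel.rate), 0)
                hi = min(c + int(half * vel.rate), pos.size)
                idx = np.where(clean[lo:hi])[0] + lo
                if idx.size < int(0.25 * vel.rate):
                    break
                coef = np.polyfit(idx, pos[idx], 2)
                if coef[0] == 0:
                    break
                vtx = -coef[1] / (2.0 * coef[0])
                if not (lo <= vtx <= hi):
                    break
                t = vel.start_time + vtx / vel.rate
            t_new = t
        out.append(replace(ev, time=t_new) if t_new != ev.time else ev)
    return out


def extract_velocity_epochs(
    vel: SlowPhaseVelocity,
    lock_times,
    window: tuple[float, float] = (-0.625, 0.625),
) -> tuple[np.ndarray, np.ndarray]:
    """Cut fixed-length velocity epochs around lock times.

    Returns ``(X, kept)``: an (n_epochs x n_samples) matrix (625 samples for
    the default symmetric 1.25-s window at 500 Hz) and the indices of lock
    times that fit inside the trace.
    """
    i0_rel = int(round(window[0] * vel.rate))
    n_samp = int(round((window[1] - window[0]) * vel.rate))
    rows, kept = [], []
    for j, t in enumerate(np.asarray(lock_times, dtype=float)):
        c = int(round((t - vel.start_time) * vel.rate))
        i0 = c + i0_rel
        if i0 < 0 or i0 + n_samp > vel.values.size:
            continue
        rows.append(vel.values[i0 : i0 + n_samp])
        kept.append(j)
    X = np.vstack(rows) if rows else np.empty((0, n_samp))
    return X, np.array(kept, dtype=int)


def fit_gamma(durations) -> tuple[float, float, float]:
    """Maximum-likelihood gamma fit of dominance durations.

    Returns ``(shape, scale, gof_p)`` where ``gof_p`` is the p-value of a
    Kolmogorov-Smirnov test against the fitted distribution (large p: the
    gamma model is adequate).  Raises on nonpositive durations and on
    degenerate (constant) input, for which the MLE diverges.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 20:
        raise ValueError("need at least 20 durations")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    if np.ptp(d) == 0:
        raise ValueError("constant durations: gamma MLE degenerate")
    shape, _, scale = stats.gamma.fit(d, floc=0)
    gof_p = stats.kstest(d, "gamma", args=(shape, 0, scale)).pvalue
    return float(shape), float(scale), float(gof_p)


@dataclass
class DelayResult:
    """OKN-crossing-to-button-press delays for one subject/session."""

    delays: dict  # direction -> list of delays (s)
    n_unpaired: int

    def mean(self, direction: str) -> float:
        return float(np.mean(self.delays[direction]))


def okn_report_delay(
    okn_events: list[SwitchEvent],
    button_events: list[SwitchEvent],
    max_pairing: float = 2.0,
) -> DelayResult:
    """Pair each button press with the nearest preceding same-direction OKN
    crossing within ``max_pairing`` seconds; return per-direction delay
    lists and the count of unpaired presses."""
    if not okn_events or not button_events:
        raise ValueError("both event streams are required")
    delays: dict[str, list[float]] = {"to_INT": [], "to_DIF": []}
    n_unpaired = 0
    by_dir = {
        d: np.array(sorted(e.time for e in okn_events if e.direction == d))
        for d in ("to_INT", "to_DIF")
    }
    for press in sorted(button_events, key=lambda e: e.time):
        times = by_dir[press.direction]
        pos = np.searchsorted(times, press.time, side="right") - 1
        if pos < 0 or press.time - times[pos] > max_pairing:
            n_unpaired += 1
            continue
        delays[press.direction].append(press.time - times[pos])
    return DelayResult(delays=delays, n_unpaired=n_unpaired)


def paired_delay_ttest(results: list[DelayResult]) -> tuple[float, float]:
    """Paired t-test on subject-mean delays, to-INT vs to-DIF."""
    a = np.array([r.mean("to_INT") for r in results])
    b = np.array([r.mean("to_DIF") for r in results])
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
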