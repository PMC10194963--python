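"""Ground-truthed synthetic sessions of bistable perception.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline is testable without real data:

* **Percept schedule** — dominance durations drawn from a gamma
  distribution (the canonical empirical model for rivalry), alternating
  between the integrated (INT) and differentiated (DIF) percept.
* **Oculomotor trace** — an OKN-like position signal whose slow-phase
  slope is negative during INT and positive during DIF, with smooth
  sigmoidal sign transitions around switches, Poisson fast-phase resets,
  Gaussian noise, and blink gaps marked NaN.
* **Multichannel EEG** — per-channel 1/f background noise; anterior-ROI
  channels share a white latent source A(t); posterior-ROI channels
  receive g * A(t - delay), where the coupling gain g rises inside a
  pre-switch window and depends on the upcoming percept (stronger before
  a switch to INT, emulating stronger feedback directed information).
  Anterior channels additionally carry a low-frequency (default 4 Hz)
  oscillation in the same windows, with a condition-dependent amplitude;
  more low-frequency power makes the anterior signal more redundant,
  which lowers its compression complexity (the differentiation measure).
* **Button events** — each switch is reported with a direction-dependent
  normally distributed reaction delay.

The latent source A(t) is white so that its autocorrelation is a delta:
the anterior-to-posterior coupling then produces a cross-correlation and
directed-information peak exactly at the injected delay, and no spurious
reverse-direction information leaks through source autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ROI_CHANNELS, Recording
from .okn import OculomotorTrace, SwitchEvent

__all__ = [
    "PerceptSchedule",
    "SimConfig",
    "GroundTruth",
    "Session",
    "sample_dominance_durations",
    "build_schedule",
    "synth_okn",
    "synth_eeg",
    "simulate_session",
]

#: Slow-phase velocity sign per percept: negative while the integrated
#: percept dominates (so a positive-to-negative zero-crossing is a switch
#: to INT), positive while differentiated.
PERCEPT_SIGN = {"INT": -1.0, "DIF": +1.0}


@dataclass
class PerceptSchedule:
    """Alternating percept intervals: ``percepts[i]`` holds between
    ``switch_times[i-1]`` and ``switch_times[i]`` (session bounds at the
    ends), so ``len(percepts) == len(switch_times) + 1``."""

    switch_times: np.ndarray
    percepts: list[str]
    session_length: float

    def __post_init__(self):
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        if np.any(np.diff(self.switch_times) <= 0):
            raise ValueError("switch_times must be strictly increasing")
        if self.switch_times.size and (
            self.switch_times[0] < 0 or self.switch_times[-1] > self.session_length
        ):
            raise ValueError("switch_times must lie within [0, session_length]")
        if len(self.percepts) != self.switch_times.size + 1:
            raise ValueError("need one percept label per inter-switch interval")
        for a, b in zip(self.percepts, self.percepts[1:]):
            if a == b or a not in PERCEPT_SIGN or b not in PERCEPT_SIGN:
                raise ValueError("percept labels must alternate between INT and DIF")

    def percept_at(self, t: np.ndarray) -> np.ndarray:
        """Index into ``percepts`` for each time point."""
        return np.searchsorted(self.switch_times, np.asarray(t), side="right")

    def switch_events(self, source: str = "ground_truth") -> list[SwitchEvent]:
        return [
            SwitchEvent(time=float(t), direction=f"to_{self.percepts[i + 1]}", source=source)
            for i, t in enumerate(self.switch_times)
        ]

    def durations(self) -> np.ndarray:
        """Complete dominance durations (between consecutive switches)."""
        return np.diff(self.switch_times)


@dataclass
class SimConfig:
    """Parameters of the synthetic session generator.

    Rates are Hz, times seconds unless suffixed ``_ms``; amplitudes are in
    the arbitrary units of the corresponding signal.  The defaults encode
    the study conditions the analyses are tested under: gamma(3, 2 s)
    dominance durations, 500 Hz eye tracking, 250 Hz EEG, a 100 ms
    anterior-to-posterior coupling delay active in the 600 ms before a
    switch, stronger coupling before INT, and more 4 Hz anterior power
    before INT (hence lower anterior complexity before INT than DIF).
    """

    gamma_shape: float = 3.0
    gamma_scale: float = 2.0  # s
    okn_slow_speed: float = 1.0  # amplitude-units / s
    fast_phase_rate: float = 2.0  # Hz
    blink_rate: float = 0.25  # Hz
    okn_rate: float = 500.0  # Hz
    transition_width: float = 0.4  # s, 10-90% width of the slope flip
    eeg_channels: int = 24
    eeg_rate: float = 250.0  # Hz
    coupling_delay: float = 100.0  # ms, anterior -> posterior lag
    coupling_gain_int: float = 1.0
    coupling_gain_dif: float = 0.0
    baseline_gain: float = 0.0
    lowfreq_hz: float = 4.0
    lowfreq_amp_int: float = 2.0
    lowfreq_amp_dif: float = 0.0
    premod_window: float = 600.0  # ms before a switch
    noise_sd: float = 1.0  # EEG background SD (units of the latent source)
    okn_noise_sd: float = 0.03  # tracker noise, units of 1 s of slow-phase drift
    button_delay_int: float = 0.5  # s, mean report latency after a to-INT switch
    button_delay_dif: float = 0.4  # s
    button_delay_sd: float = 0.1  # s
    seed: int = 0

    def __post_init__(self):
        for name in ("gamma_shape", "gamma_scale", "okn_slow_speed", "okn_rate",
                     "eeg_rate", "transition_width", "premod_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fast_phase_rate", "blink_rate", "noise_sd", "okn_noise_sd", "baseline_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.eeg_channels < 1:
            raise ValueError("eeg_channels must be >= 1")
        lag = self.coupling_delay / 1000.0 * self.eeg_rate
        if abs(lag - round(lag)) > 1e-9:
            raise ValueError("coupling_delay must be a multiple of the EEG sample period")


@dataclass
class GroundTruth:
    schedule: PerceptSchedule
    coupling_delay_ms: float = 0.0
    premod_windows: list = field(default_factory=list)  # (start_s, end_s, direction)
    gains: dict = field(default_factory=dict)
    lowfreq_amps: dict = field(default_factory=dict)


@dataclass
class Session:
    okn: OculomotorTrace
    eeg: Recording
    switch_events: list
    button_events: list
    ground_truth: GroundTruth


def sample_dominance_durations(shape: float, scale: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` independent gamma(shape, scale) dominance durations
    (seconds); reproducible given ``seed``."""
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape, scale, size=int(n))


def build_schedule(durations, session_length: float, initial_percept: str = "INT") -> PerceptSchedule:
    """Turn a sequence of dominance durations into a percept schedule.

    Cumulative sums become switch times, truncated at ``session_length``;
    percept labels alternate starting from ``initial_percept``.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("durations must be non-empty")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    if initial_percept not in PERCEPT_SIGN:
        raise ValueError("initial_percept must be 'INT' or 'DIF'")
    times = np.cumsum(d)
    times = times[times < session_length]
    other = "DIF" if initial_percept == "INT" else "INT"
    percepts = [initial_percept if i % 2 == 0 else other for i in range(times.size + 1)]
    return PerceptSchedule(switch_times=times, percepts=percepts, session_length=session_length)


def _slope_profile(t: np.ndarray, schedule: PerceptSchedule, width: float) -> np.ndarray:
    """Signed slope profile in [-1, 1] with logistic transitions at
    switches; ``width`` is the 10-90% transition width in seconds."""
    from scipy.special import expit

    scale = width / (2.0 * np.log(9.0))
    prof = np.full(t.size, PERCEPT_SIGN[schedule.percepts[0]])
    for i, ts in enumerate(schedule.switch_times):
        before = PERCEPT_SIGN[schedule.percepts[i]]
        after = PERCEPT_SIGN[schedule.percepts[i + 1]]
        prof = prof + (after - before) * expit((t - ts) / scale)
    return prof


def synth_okn(schedule: PerceptSchedule, cfg: SimConfig, rng: np.random.Generator | None = None) -> OculomotorTrace:
    """Synthesise an OKN-like position trace for a percept schedule.

    The slow-phase slope is ``-okn_slow_speed`` during INT and ``+`` during
    DIF with sigmoidal transitions; fast phases reset the position to its
    running baseline at Poisson rate ``fast_phase_rate``; blinks (Poisson
    rate ``blink_rate``, 100-300 ms) blank samples to NaN; Gaussian noise
    of SD ``okn_noise_sd`` is added.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(schedule.session_length * cfg.okn_rate))
    t = np.arange(n) / cfg.okn_rate
    slope = cfg.okn_slow_speed * _slope_profile(t, schedule, cfg.transition_width)
    position = np.cumsum(slope) / cfg.okn_rate

    # blinks are drawn first so fast phases can be suppressed inside blink
    # gaps (a tracker cannot observe or annotate saccades while the eye is
    # closed, and an unannotated reset would be unrecoverable downstream)
    blink_events: list[tuple[float, float]] = []
    if cfg.blink_rate > 0:
        n_bl = rng.poisson(cfg.blink_rate * schedule.session_length)
        onsets = np.sort(rng.uniform(0, schedule.session_length, n_bl))
        durs = rng.uniform(0.1, 0.3, n_bl)
        blink_events = [(float(on), float(min(on + du, schedule.session_length)))
                        for on, du in zip(onsets, durs)]

    saccade_events: list[tuple[float, float]] = []
    if cfg.fast_phase_rate > 0:
        n_fp = rng.poisson(cfg.fast_phase_rate * schedule.session_length)
        fp_idx = np.unique(np.sort((rng.uniform(0, 1, n_fp) * (n - 1)).astype(int)))
        if blink_events and fp_idx.size:
            fp_t = fp_idx / cfg.okn_rate
            hidden = np.zeros(fp_idx.size, dtype=bool)
            for on, off in blink_events:
                hidden |= (fp_t >= on - 0.05) & (fp_t <= off + 0.05)
            fp_idx = fp_idx[~hidden]
        if fp_idx.size:
            # reset the trace to zero at each fast phase (sawtooth)
            base_vals = position[fp_idx]
            pos_in_seg = np.searchsorted(fp_idx, np.arange(n), side="right") - 1
            base = np.where(pos_in_seg >= 0, base_vals[np.maximum(pos_in_seg, 0)], 0.0)
            position = position - base
            saccade_events = [(i / cfg.okn_rate, i / cfg.okn_rate + 0.02) for i in fp_idx]

    if cfg.okn_noise_sd > 0:
        position = position + rng.normal(0.0, cfg.okn_noise_sd, n)

    for on, off in blink_events:
        i0, i1 = int(on * cfg.okn_rate), int(np.ceil(off * cfg.okn_rate))
        position[i0:i1] = np.nan

    return OculomotorTrace(
        samples=position,
        rate=cfg.okn_rate,
        start_time=0.0,
        blink_events=blink_events,
        saccade_events=saccade_events,
    )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD noise with 1/f amplitude spectrum."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec = spec / np.sqrt(f)
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _default_channel_names(n: int) -> list[str]:
    names: list[str] = []
    for roi in ("front", "back", "left_temporal", "right_temporal"):
        names.extend(ROI_CHANNELS[roi])
    if n <= len(names):
        return names[:n]
    names = names + [f"EXT{i}" for i in range(n - len(names))]
    return names


def _premod_windows(schedule: PerceptSchedule, premod_ms: float):
    wins = []
    for i, ts in enumerate(schedule.switch_times):
        direction = f"to_{schedule.percepts[i + 1]}"
        wins.append((max(ts - premod_ms / 1000.0, 0.0), float(ts), direction))
    return wins


def synth_eeg(
    schedule: PerceptSchedule, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Recording, GroundTruth]:
    """Synthesise multichannel EEG with switch-dependent anterior-to-
    posterior lagged coupling and anterior low-frequency modulation.

    Every channel gets independent 1/f background noise of SD ``noise_sd``.
    Anterior (front-ROI) channels share a white latent source A(t) and, in
    the ``premod_window`` before each switch, a ``lowfreq_hz`` oscillation
    whose amplitude depends on the upcoming percept.  Posterior (back-ROI)
    channels receive ``g * A(t - coupling_delay)`` with g =
    ``coupling_gain_int`` before a to-INT switch, ``coupling_gain_dif``
    before a to-DIF switch and ``baseline_gain`` elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lag = int(round(cfg.coupling_delay / 1000.0 * cfg.eeg_rate))
    n = int(round(schedule.session_length * cfg.eeg_rate))
    t = np.arange(n) / cfg.eeg_rate
    names = _default_channel_names(cfg.eeg_channels)
    front = [i for i, nm in enumerate(names) if nm in ROI_CHANNELS["front"]]
    back = [i for i, nm in enumerate(names) if nm in ROI_CHANNELS["back"]]

    a_ext = rng.normal(size=n + lag)  # white latent source, see module docstring
    a_now = a_ext[lag:]
    a_lag = a_ext[:n]

    gain = np.full(n, cfg.baseline_gain)
    amp = np.zeros(n)
    wins = _premod_windows(schedule, cfg.premod_window)
    for w0, w1, direction in wins:
        i0, i1 = int(round(w0 * cfg.eeg_rate)), int(round(w1 * cfg.eeg_rate))
        if direction == "to_INT":
            gain[i0:i1] = cfg.coupling_gain_int
            amp[i0:i1] = cfg.lowfreq_amp_int
        else:
            gain[i0:i1] = cfg.coupling_gain_dif
            amp[i0:i1] = cfg.lowfreq_amp_dif
    osc = amp * np.sin(2.0 * np.pi * cfg.lowfreq_hz * t + rng.uniform(0, 2 * np.pi))

    data = np.empty((cfg.eeg_channels, n))
    for ch in range(cfg.eeg_channels):
        bg = cfg.noise_sd * _pink_noise(rng, n)
        if ch in front:
            data[ch] = bg + a_now + osc
        elif ch in back:
            data[ch] = bg + gain * a_lag
        else:
            data[ch] = bg

    gt = GroundTruth(
        schedule=schedule,
        coupling_delay_ms=cfg.coupling_delay,
        premod_windows=wins,
        gains={"to_INT": cfg.coupling_gain_int, "to_DIF": cfg.coupling_gain_dif,
               "baseline": cfg.baseline_gain},
        lowfreq_amps={"to_INT": cfg.lowfreq_amp_int, "to_DIF": cfg.lowfreq_amp_dif},
    )
    rec = Recording(data=data, rate=cfg.eeg_rate, ch_names=names,
                    events=schedule.switch_events())
    return rec, gt


def simulate_session(cfg: SimConfig, session_length: float = 240.0,
                     seed: int | None = None) -> Session:
    """Generate a full synthetic session: schedule, OKN trace, EEG, ground
    truth, and button events with direction-dependent report latencies.

    Identical ``cfg`` (including seed) yields bit-identical output.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    # oversample durations so the cumulative sum safely covers the session
    mean_dur = cfg.gamma_shape * cfg.gamma_scale
    n_dur = max(int(session_length / mean_dur * 3) + 10, 20)
    durations = rng.gamma(cfg.gamma_shape, cfg.gamma_scale, n_dur)
    initial = "INT" if rng.uniform() < 0.5 else "DIF"
    schedule = build_schedule(durations, session_length, initial_percept=initial)

    okn = synth_okn(schedule, cfg, rng)
    eeg, gt = synth_eeg(schedule, cfg, rng)

    buttons = []
    for ev in schedule.switch_events():
        mu = cfg.button_delay_int if ev.direction == "to_INT" else cfg.button_delay_dif
        delay = max(rng.normal(mu, cfg.button_delay_sd), 0.05)
        bt = ev.time + delay
        if bt < session_length:
            buttons.append(SwitchEvent(time=bt, direction=ev.direction, source="button"))

    return Session(
        okn=okn,
        eeg=eeg,
        switch_events=schedule.switch_events(),
        button_events=buttons,
        ground_truth=gt,
    )
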