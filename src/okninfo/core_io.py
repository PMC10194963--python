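"""EEG containers, preprocessing, epoching, ROI definitions, and file I/O.

The preprocessing chain mirrors a conventional perceptual-switch EEG
pipeline: resample to 250 Hz, band-pass 1-100 Hz, 50 Hz notch, average
reference; epochs of -2000..+500 ms around each switch; rejection on
amplitude (|x| > 150 uV) and linear drift (> 60 uV over the epoch); and the
trial-exclusion rule that drops any switch whose predecessor occurred less
than 2 s earlier, so the pre-switch window contains a single percept.

ICA-based artifact removal and spherical-spline channel interpolation are
deliberately not reimplemented here: the pipeline accepts already-cleaned
recordings (or synthetic ones) and only produces channel drop lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

from .infodyn import RoiEpochs
from .okn import OculomotorTrace, SwitchEvent

__all__ = [
    "Recording",
    "RoiDefinition",
    "EpochCriteria",
    "EpochSet",
    "ROI_CHANNELS",
    "preprocess",
    "reject_channels",
    "filter_switch_events",
    "epoch_and_reject",
    "roi_average",
    "save_session",
    "load_session",
    "write_events_tsv",
    "read_events_tsv",
    "read_eye_samples",
    "read_eyelink_events",
    "read_raw_edf",
]

#: Default ROI montage (6 channels each, disjoint). The published electrode
#: sets are shown only as a figure; these are a synthetic reconstruction of
#: canonical bilateral clusters in the 10-20 system and are editable.
ROI_CHANNELS: dict[str, list[str]] = {
    "front": ["AF3", "AF4", "F3", "F1", "F2", "F4"],
    "back": ["P3", "P1", "Pz", "P2", "P4", "POz"],
    "left_temporal": ["FT7", "T7", "TP7", "C5", "CP5", "P7"],
    "right_temporal": ["FT8", "T8", "TP8", "C6", "CP6", "P8"],
}


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is (channels x samples) in microvolts."""

    data: np.ndarray
    rate: float
    ch_names: list[str]
    events: list[SwitchEvent] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel name count does not match data")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class RoiDefinition:
    name: str
    channels: tuple

    @classmethod
    def default(cls, name: str) -> "RoiDefinition":
        return cls(name=name, channels=tuple(ROI_CHANNELS[name]))


@dataclass
class EpochCriteria:
    """Epoching window and rejection thresholds."""

    window: tuple[float, float] = (-2.0, 0.5)  # s around the lock event
    amplitude_bound: float = 150.0  # uV
    slope_bound: float = 60.0  # uV total rise over the epoch
    min_inter_switch: float = 2.0  # s


@dataclass
class EpochSet:
    """Time-locked multichannel segments with per-epoch condition labels."""

    data: np.ndarray  # (n_epochs, n_channels, n_times)
    times: np.ndarray  # ms relative to lock event
    rate: float
    ch_names: list[str]
    labels: list[str]
    lock_times: np.ndarray
    rejection_log: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def preprocess(rec: Recording, target_rate: float = 250.0,
               band: tuple[float, float] = (1.0, 100.0), notch: float = 50.0) -> Recording:
    """Resample to 250 Hz, band-pass 1-100 Hz, 50 Hz notch, average
    reference — applied in that order, all filters zero-phase."""
    if rec.rate < target_rate:
        raise ValueError("recording rate below target rate")
    data = rec.data
    if rec.rate != target_rate:
        from fractions import Fraction

        frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    sos = signal.butter(4, band, btype="band", fs=target_rate, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    b, a = signal.iirnotch(notch, Q=35.0, fs=target_rate)
    data = signal.filtfilt(b, a, data, axis=1)
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(data=data, rate=target_rate, ch_names=list(rec.ch_names), events=list(rec.events))


def reject_channels(rec: Recording, sd_bounds: float = 2.0) -> tuple[list[str], list[str]]:
    """Flag channels whose variance deviates more than ``sd_bounds``
    standard deviations from the mean channel variance.

    Returns ``(keep, drop)`` channel-name lists; interpolation of dropped
    channels is delegated to established EEG tooling.
    """
    if rec.data.shape[0] < 8:
        raise ValueError("need at least 8 channels")
    var = rec.data.var(axis=1)
    z = (var - var.mean()) / var.std() if var.std() > 0 else np.zeros_like(var)
    drop = [name for name, zi in zip(rec.ch_names, z) if abs(zi) > sd_bounds]
    keep = [name for name in rec.ch_names if name not in drop]
    return keep, drop


def filter_switch_events(
    events: list[SwitchEvent],
    criteria: EpochCriteria | None = None,
) -> tuple[list[SwitchEvent], dict]:
    """Apply the trial-exclusion rules to a time-sorted switch stream.

    Removes (i) switches whose predecessor in the original stream occurred
    less than ``min_inter_switch`` seconds earlier, (ii) same-direction
    repetitions (the second of the pair), and (iii) switches whose epoch
    window contains another event after the lock (more than one response
    per epoch).  Returns the retained events and a per-rule count log.
    """
    criteria = criteria or EpochCriteria()
    ev = sorted(events, key=lambda e: e.time)
    n = len(ev)
    drop = [None] * n  # first-rule attribution
    for i in range(1, n):
        if drop[i] is None and ev[i].time - ev[i - 1].time < criteria.min_inter_switch:
            drop[i] = "min_inter_switch"
    for i in range(1, n):
        if drop[i] is None and ev[i].direction == ev[i - 1].direction:
            drop[i] = "repetition"
    post = criteria.window[1]
    for i in range(n):
        if drop[i] is not None:
            continue
        for j in range(n):
            if j != i and ev[i].time < ev[j].time <= ev[i].time + post:
                drop[i] = "multiple_responses"
                break
    kept = [e for e, d in zip(ev, drop) if d is None]
    log = {rule: sum(d == rule for d in drop) for rule in
           ("min_inter_switch", "repetition", "multiple_responses")}
    log["retained"] = len(kept)
    log["total"] = n
    return kept, log


def epoch_and_reject(
    rec: Recording,
    events: list[SwitchEvent],
    criteria: EpochCriteria | None = None,
) -> EpochSet:
    """Cut epochs at ``criteria.window`` around each event and reject on
    amplitude and linear-drift thresholds.

    An epoch is rejected if any channel sample exceeds the amplitude bound,
    or if the magnitude of any channel's least-squares linear fit total
    rise over the epoch exceeds the slope bound.  Rejection counts are
    first-rule attributed (amplitude checked first) and conserved:
    retained + skipped_edge + amplitude + slope = total.
    """
    criteria = criteria or EpochCriteria()
    w0, w1 = criteria.window
    i0_rel = int(round(w0 * rec.rate))
    i1_rel = int(round(w1 * rec.rate))
    n_t = i1_rel - i0_rel
    times_ms = (np.arange(n_t) + i0_rel) / rec.rate * 1000.0
    # slope of least-squares linear fit, expressed as total rise over the epoch
    t = np.arange(n_t, dtype=float)
    t_c = t - t.mean()
    slope_vec = t_c / (t_c @ t_c) * (n_t - 1)

    data, labels, locks = [], [], []
    log = {"amplitude": 0, "slope": 0, "skipped_edge": 0}
    for e in sorted(events, key=lambda ev: ev.time):
        centre = int(round(e.time * rec.rate))
        i0, i1 = centre + i0_rel, centre + i1_rel
        if i0 < 0 or i1 > rec.n_samples:
            log["skipped_edge"] += 1
            continue
        ep = rec.data[:, i0:i1]
        if np.abs(ep).max() > criteria.amplitude_bound:
            log["amplitude"] += 1
            continue
        rise = np.abs(ep @ slope_vec)
        if rise.max() > criteria.slope_bound:
            log["slope"] += 1
            continue
        data.append(ep)
        labels.append(e.direction)
        locks.append(e.time)
    log["retained"] = len(data)
    log["total"] = len(events)
    arr = np.stack(data) if data else np.empty((0, rec.data.shape[0], n_t))
    return EpochSet(
        data=arr,
        times=times_ms,
        rate=rec.rate,
        ch_names=list(rec.ch_names),
        labels=labels,
        lock_times=np.array(locks),
        rejection_log=log,
    )


def roi_average(epochs: EpochSet, roi: RoiDefinition | str, condition: str | None = None) -> RoiEpochs:
    """Unweighted mean across an ROI's channels, optionally restricted to
    epochs with a given condition label."""
    if isinstance(roi, str):
        roi = RoiDefinition.default(roi)
    idx = []
    for ch in roi.channels:
        if ch not in epochs.ch_names:
            raise KeyError(f"ROI channel {ch!r} missing from epochs")
        idx.append(epochs.ch_names.index(ch))
    sel = np.arange(epochs.n_epochs)
    if condition is not None:
        sel = np.array([i for i, lab in enumerate(epochs.labels) if lab == condition], dtype=int)
    values = epochs.data[sel][:, idx, :].mean(axis=1)
    return RoiEpochs(
        values=values,
        times=epochs.times,
        rate=epochs.rate,
        roi_name=roi.name,
        condition=condition or "",
    )


# ---------------------------------------------------------------------------
# Session container (HDF5) and delimited-text I/O
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _write_events(grp, name, events):
    sub = grp.create_group(name)
    sub.create_dataset("time_s", data=np.array([e.time for e in events], dtype=float))
    sub.create_dataset("direction", data=np.array([e.direction for e in events], dtype=object), dtype=_STR)
    sub.create_dataset("source", data=np.array([e.source for e in events], dtype=object), dtype=_STR)


def _read_events(grp):
    return [
        SwitchEvent(time=float(t), direction=d, source=s)
        for t, d, s in zip(
            grp["time_s"][()],
            [x.decode() if isinstance(x, bytes) else x for x in grp["direction"][()]],
            [x.decode() if isinstance(x, bytes) else x for x in grp["source"][()]],
        )
    ]


def save_session(path, session) -> None:
    """Write a simulated session to an HDF5 container with groups ``/eeg``,
    ``/okn``, ``/events`` and ``/ground_truth``."""
    with h5py.File(path, "w") as f:
        eeg = f.create_group("eeg")
        eeg.create_dataset("data", data=session.eeg.data)
        eeg.attrs["rate"] = session.eeg.rate
        eeg.create_dataset("ch_names", data=np.array(session.eeg.ch_names, dtype=object), dtype=_STR)

        okn = f.create_group("okn")
        okn.create_dataset("samples", data=session.okn.samples)
        okn.attrs["rate"] = session.okn.rate
        okn.attrs["start_time"] = session.okn.start_time
        okn.create_dataset("blink_events", data=np.array(session.okn.blink_events, dtype=float).reshape(-1, 2))
        okn.create_dataset("saccade_events", data=np.array(session.okn.saccade_events, dtype=float).reshape(-1, 2))

        ev = f.create_group("events")
        _write_events(ev, "switches", session.switch_events)
        _write_events(ev, "buttons", session.button_events)

        gt = f.create_group("ground_truth")
        sched = session.ground_truth.schedule
        gt.create_dataset("switch_times", data=sched.switch_times)
        gt.create_dataset("percepts", data=np.array(sched.percepts, dtype=object), dtype=_STR)
        gt.attrs["session_length"] = sched.session_length
        gt.attrs["coupling_delay_ms"] = session.ground_truth.coupling_delay_ms
        gt.create_dataset("premod_windows", data=np.array(
            [(a, b) for a, b, _ in session.ground_truth.premod_windows], dtype=float).reshape(-1, 2))
        gt.create_dataset("premod_directions", data=np.array(
            [d for _, _, d in session.ground_truth.premod_windows], dtype=object), dtype=_STR)


def load_session(path):
    """Read a session container written by :func:`save_session`."""
    from .syndata import GroundTruth, PerceptSchedule, Session

    with h5py.File(path, "r") as f:
        eeg = Recording(
            data=f["eeg/data"][()],
            rate=float(f["eeg"].attrs["rate"]),
            ch_names=[x.decode() if isinstance(x, bytes) else x for x in f["eeg/ch_names"][()]],
        )
        okn = OculomotorTrace(
            samples=f["okn/samples"][()],
            rate=float(f["okn"].attrs["rate"]),
            start_time=float(f["okn"].attrs["start_time"]),
            blink_events=[tuple(r) for r in f["okn/blink_events"][()]],
            saccade_events=[tuple(r) for r in f["okn/saccade_events"][()]],
        )
        switches = _read_events(f["events/switches"])
        buttons = _read_events(f["events/buttons"])
        sched = PerceptSchedule(
            switch_times=f["ground_truth/switch_times"][()],
            percepts=[x.decode() if isinstance(x, bytes) else x for x in f["ground_truth/percepts"][()]],
            session_length=float(f["ground_truth"].attrs["session_length"]),
        )
        wins = f["ground_truth/premod_windows"][()]
        dirs = [x.decode() if isinstance(x, bytes) else x for x in f["ground_truth/premod_directions"][()]]
        gt = GroundTruth(
            schedule=sched,
            coupling_delay_ms=float(f["ground_truth"].attrs["coupling_delay_ms"]),
            premod_windows=[(float(a), float(b), d) for (a, b), d in zip(wins, dirs)],
        )
    return Session(okn=okn, eeg=eeg, switch_events=switches, button_events=buttons, ground_truth=gt)


def write_events_tsv(path, events: list[SwitchEvent]) -> None:
    """Export events as tab-separated text: time_s, type, label."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f, delimiter="\t")
        w.writerow(["time_s", "type", "label"])
        for e in sorted(events, key=lambda ev: ev.time):
            w.writerow([f"{e.time:.6f}", e.source, e.direction])


def read_events_tsv(path) -> list[SwitchEvent]:
    events = []
    with open(path, newline="") as f:
        for row in csv.DictReader(f, delimiter="\t"):
            events.append(SwitchEvent(time=float(row["time_s"]), direction=row["label"], source=row["type"]))
    return events


def read_eye_samples(path, column: int = 1, rate: float = 500.0) -> OculomotorTrace:
    """Read eye-tracker samples from whitespace/tab-delimited text.

    Expects one sample per line with a timestamp in the first column and
    the gaze coordinate of interest in ``column``; missing samples may be
    ``.`` or empty (EyeLink ASC-style) and become NaN.
    """
    values, t0 = [], None
    with open(path) as f:
        for line in f:
            parts = line.split()
            if not parts or not _is_number(parts[0]):
                continue
            if t0 is None:
                t0 = float(parts[0])
            v = parts[column] if column < len(parts) else "."
            values.append(float(v) if _is_number(v) else np.nan)
    if not values:
        raise ValueError(f"no sample lines found in {path}")
    return OculomotorTrace(samples=np.array(values), rate=rate, start_time=0.0)


def read_eyelink_events(path, time_unit: float = 1e-3) -> dict[str, list[tuple[float, float]]]:
    """Parse EyeLink ASC-style EBLINK/ESACC lines into (onset, offset)
    second pairs (timestamps assumed milliseconds by default)."""
    out: dict[str, list[tuple[float, float]]] = {"blink": [], "saccade": []}
    kind = {"EBLINK": "blink", "ESACC": "saccade"}
    with open(path) as f:
        for line in f:
            parts = line.split()
            if len(parts) >= 4 and parts[0] in kind:
                out[kind[parts[0]]].append((float(parts[2]) * time_unit, float(parts[3]) * time_unit))
    return out


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_raw_edf(path, **kwargs) -> Recording:
    """Read a BDF/EDF recording via :mod:`mne` (lazy import) into a
    :class:`Recording` (data converted to microvolts)."""
    import mne

    reader = mne.io.read_raw_bdf if str(path).lower().endswith(".bdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error", **kwargs)
    return Recording(data=raw.get_data() * 1e6, rate=float(raw.info["sfreq"]), ch_names=list(raw.ch_names))
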