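"""End-to-end study helpers on synthetic sessions.

These functions chain the full pipeline — session synthesis, trial
exclusion, epoching, ROI averaging, information measures — into the
per-subject quantities that the group-level cluster statistics consume.
They exist so that simulation studies (and the acceptance checks) exercise
exactly the same code path a real analysis would.

Problem sizes (session length, delay grid, epoch window) default to desk
scale: single-CPU friendly while keeping enough switch-locked epochs per
condition (~35-40) for stable across-epoch information estimates.
"""

from __future__ import annotations

import numpy as np

from . import core_io, infodyn, okn, syndata

__all__ = [
    "default_delays",
    "synth_velocity_epochs",
    "subject_dirinfo_maps",
    "subject_complexity_series",
    "group_maps",
    "switch_count_correlation",
]

CONDITIONS = ("to_INT", "to_DIF")


def default_delays(max_ms: float = 200.0, step_ms: float = 4.0) -> np.ndarray:
    """Delay grid in ms (0..max in 4-ms steps, the sample period at 250 Hz)."""
    return np.arange(0.0, max_ms + step_ms / 2, step_ms)


def synth_velocity_epochs(
    n: int,
    seed: int,
    okn_noise_sd: float = 0.03,
    input_length: int = 625,
    rate: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate labeled slow-phase-velocity epochs for decoder training.

    Each epoch comes from a short synthetic OKN trace containing a single
    switch at its centre, run through the full slow-phase pipeline; the
    label is the switch direction.  Returns ``(X, y)`` with X of shape
    (n, input_length).
    """
    cfg = syndata.SimConfig(seed=seed, okn_noise_sd=okn_noise_sd, okn_rate=rate)
    rng = np.random.default_rng(seed)
    half = input_length / rate / 2.0
    margin = half + 0.5  # smoothing + filter edge clearance
    xs, ys = [], []
    while len(xs) < n:
        first = "INT" if rng.uniform() < 0.5 else "DIF"
        second = "DIF" if first == "INT" else "INT"
        sched = syndata.PerceptSchedule(
            np.array([margin]), [first, second], 2.0 * margin
        )
        trace = syndata.synth_okn(sched, cfg, rng)
        vel = okn.slow_phase_pipeline(trace)
        ep, kept = okn.extract_velocity_epochs(vel, [margin], window=(-half, half))
        if kept.size and ep.shape[1] == input_length:
            xs.append(ep[0])
            ys.append(f"to_{second}")
    return np.asarray(xs), np.asarray(ys)


def _session_epochs(seed, cfg_kwargs, session_length, window):
    cfg = syndata.SimConfig(seed=seed, **cfg_kwargs)
    rng = np.random.default_rng(seed)
    mean_dur = cfg.gamma_shape * cfg.gamma_scale
    durs = rng.gamma(cfg.gamma_shape, cfg.gamma_scale,
                     max(int(session_length / mean_dur * 3) + 10, 20))
    sched = syndata.build_schedule(
        durs, session_length, "INT" if rng.uniform() < 0.5 else "DIF"
    )
    rec, _ = syndata.synth_eeg(sched, cfg, rng)
    events, _ = core_io.filter_switch_events(sched.switch_events())
    return core_io.epoch_and_reject(rec, events, core_io.EpochCriteria(window=window))


def subject_dirinfo_maps(
    seed: int,
    cfg_kwargs: dict | None = None,
    session_length: float = 480.0,
    window: tuple[float, float] = (-0.8, 0.1),
    delays: np.ndarray | None = None,
    min_epochs: int = 16,
) -> dict | None:
    """Directed-information maps for one synthetic subject.

    Returns ``{(direction, condition): (n_delays, n_times) array}`` with
    direction in {"fwd" (front->back), "rev" (back->front)}, or None if a
    condition has fewer than ``min_epochs`` usable epochs.
    """
    cfg_kwargs = dict(cfg_kwargs or {})
    cfg_kwargs.setdefault("eeg_channels", 12)
    delays = default_delays() if delays is None else delays
    eps = _session_epochs(seed, cfg_kwargs, session_length, window)
    out = {}
    for cond in CONDITIONS:
        front = core_io.roi_average(eps, "front", condition=cond)
        back = core_io.roi_average(eps, "back", condition=cond)
        if front.n_epochs < min_epochs:
            return None
        out[("fwd", cond)] = infodyn.directed_information(
            front, back, delays, min_epochs=min_epochs).values
        out[("rev", cond)] = infodyn.directed_information(
            back, front, delays, min_epochs=min_epochs).values
    return out


def subject_complexity_series(
    seed: int,
    cfg_kwargs: dict | None = None,
    session_length: float = 480.0,
    window: tuple[float, float] = (-0.8, 0.1),
    step_ms: float = 20.0,
    roi: str = "front",
    min_epochs: int = 8,
) -> dict | None:
    """Sliding-window complexity time courses for one synthetic subject,
    per condition: ``{condition: (n_windows,) array}``."""
    cfg_kwargs = dict(cfg_kwargs or {})
    cfg_kwargs.setdefault("eeg_channels", 12)
    eps = _session_epochs(seed, cfg_kwargs, session_length, window)
    out = {}
    for cond in CONDITIONS:
        roi_eps = core_io.roi_average(eps, roi, condition=cond)
        if roi_eps.n_epochs < min_epochs:
            return None
        out[cond] = infodyn.complexity_timecourse(roi_eps, step_ms=step_ms).values
    return out


def group_maps(
    subject_fn,
    n_subjects: int,
    base_seed: int,
) -> dict:
    """Collect per-subject outputs into stacked group arrays.

    ``subject_fn(seed)`` must return a dict of equally keyed arrays or
    None (subject skipped); seeds count up from ``base_seed`` until
    ``n_subjects`` valid subjects are collected.
    """
    collected: list[dict] = []
    seed = base_seed
    while len(collected) < n_subjects:
        res = subject_fn(seed)
        seed += 1
        if res is not None:
            collected.append(res)
        if seed - base_seed > 10 * n_subjects + 50:
            raise RuntimeError("too many invalid subjects")
    keys = collected[0].keys()
    return {k: np.stack([c[k] for c in collected]) for k in keys}


def switch_count_correlation(
    n_subjects: int = 15, base_seed: int = 0, session_lengths=(180.0, 360.0)
) -> float:
    """Pearson correlation, across synthetic subjects, between the number
    of detected OKN switches and the ground-truth switch count."""
    true_counts, det_counts = [], []
    rng = np.random.default_rng(base_seed)
    for i in range(n_subjects):
        length = float(rng.uniform(*session_lengths))
        cfg = syndata.SimConfig(seed=base_seed + 1000 + i)
        sess = syndata.simulate_session(cfg, session_length=length)
        vel = okn.slow_phase_pipeline(sess.okn)
        det = okn.detect_switches(vel)
        true_counts.append(len(sess.switch_events))
        det_counts.append(len(det))
    return float(np.corrcoef(true_counts, det_counts)[0, 1])
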