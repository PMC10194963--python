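"""Information dynamics: directed information and compression complexity.

Two complementary measures of the information carried by ROI-averaged EEG
around perceptual switches:

* **Directed information** (transfer entropy at a fixed lag),
  ``I(Y_t ; X_{t-tau} | Y_{t-tau})`` — how much the past of a sender signal
  X tells us about the present of a receiver Y beyond Y's own past,
  evaluated on a (delay x time) grid across epochs.  Estimation uses the
  Gaussian-copula approach: each variable is rank-transformed to standard
  normal margins across epochs, then conditional mutual information is
  computed in closed form from covariance determinants.  The estimate is
  therefore robust to (and invariant under) monotone amplitude transforms.
* **Information differentiation** (K complexity) — an upper bound on the
  algorithmic complexity of a signal window, estimated as the DEFLATE
  (gzip) compression ratio of the window after amplitude discretisation
  into 32 symbols.  Redundant (e.g., strongly oscillatory) windows compress
  well and score low; differentiated windows score high.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri, psi
from scipy.stats import rankdata

__all__ = [
    "RoiEpochs",
    "DelayTimeMap",
    "ComplexitySeries",
    "copula_normalize",
    "gaussian_cmi",
    "directed_information",
    "symbolize",
    "k_complexity",
    "complexity_timecourse",
]

LN2 = np.log(2.0)


@dataclass
class RoiEpochs:
    """ROI-averaged, switch-locked epochs: ``values`` is (epochs x time)."""

    values: np.ndarray
    times: np.ndarray  # ms relative to the lock event
    rate: float = 250.0
    roi_name: str = ""
    condition: str = ""

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[1] != self.times.size:
            raise ValueError("values and times length mismatch")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1000.0 / self.rate):
                raise ValueError("times spacing does not match rate")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass
class DelayTimeMap:
    """Directed information on a (delay x time) grid, in bits.

    Entries with ``t - tau`` before the epoch start are NaN (missing, not
    zero) and are excluded from downstream statistics.
    """

    values: np.ndarray  # (n_delays, n_times)
    delays: np.ndarray  # ms
    times: np.ndarray  # ms
    direction: str = ""
    condition: str = ""


@dataclass
class ComplexitySeries:
    """Sliding-window compression ratios (dimensionless) over time."""

    values: np.ndarray  # (n_windows,) mean over epochs
    times: np.ndarray  # ms, window centres
    per_epoch: np.ndarray | None = None  # (n_epochs, n_windows)
    window_ms: float = 100.0
    step_ms: float = 4.0
    n_symbols: int = 32


def copula_normalize(samples, axis: int = 0) -> np.ndarray:
    """Gaussian-copula rank transform.

    Ranks (stable/ordinal tie-break, with a warning on ties) are mapped to
    standard-normal quantiles ``Phi^{-1}((rank - 0.5) / n)``.  Invariant
    under any strictly monotone transform of the input.
    """
    x = np.asarray(samples, dtype=float)
    n = x.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 samples for the copula transform")
    mn = x.min(axis=axis)
    mx = x.max(axis=axis)
    if np.any(mn == mx):
        raise ValueError("constant input: no rank information")
    uniq = np.apply_along_axis(lambda c: np.unique(c).size, axis, x) if x.ndim > 1 else np.array(np.unique(x).size)
    if np.any(uniq < n):
        warnings.warn("ties present; broken by stable order")
    r = rankdata(x, method="ordinal", axis=axis)
    return ndtri((r - 0.5) / n)


def _gauss_ent_corr(d: int, n: int) -> float:
    """Bias-correction term (nats) for the entropy of a d-dim Gaussian
    estimated from n samples (Gaussian-copula estimator lineage)."""
    psiterms = psi((n - np.arange(1, d + 1)) / 2.0) / 2.0
    dterm = (LN2 - np.log(n - 1.0)) / 2.0
    return d * dterm + psiterms.sum()


def gaussian_cmi(x, y, z, bias_correct: bool = False) -> float:
    """Conditional mutual information I(X;Y|Z), in bits, under a Gaussian
    model on (already copula-normalized) scalar samples.

    ``I = 1/2 * log2( |S_xz| |S_yz| / (|S_z| |S_xyz|) )`` with S the
    covariance matrices.  Optional small-sample bias correction subtracts
    the expected entropy bias of each determinant term.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    n = x.size
    if y.size != n or z.size != n:
        raise ValueError("x, y, z must have equal length")
    if n < 16:
        raise ValueError("need at least 16 samples")
    c = np.cov(np.vstack([x, y, z]))
    det_z = c[2, 2]
    det_xz = c[0, 0] * c[2, 2] - c[0, 2] ** 2
    det_yz = c[1, 1] * c[2, 2] - c[1, 2] ** 2
    det_xyz = np.linalg.det(c)
    if det_z <= 0:
        raise np.linalg.LinAlgError("singular covariance in CMI computation")
    # degenerate conditioning: z (numerically) determines x or y, so the
    # conditional information is zero by definition
    tiny = 1e-12
    if det_yz <= tiny * c[1, 1] * det_z or det_xz <= tiny * c[0, 0] * det_z:
        return 0.0
    if det_xyz <= 0:
        raise np.linalg.LinAlgError("singular covariance in CMI computation")
    i = 0.5 * np.log2(det_xz * det_yz / (det_z * det_xyz))
    if bias_correct:
        corr = (
            _gauss_ent_corr(2, n) + _gauss_ent_corr(2, n) - _gauss_ent_corr(1, n) - _gauss_ent_corr(3, n)
        ) / LN2
        i -= corr
    return float(i)


def directed_information(
    source: RoiEpochs,
    target: RoiEpochs,
    delays: np.ndarray | None = None,
    bias_correct: bool = False,
    min_epochs: int = 16,
) -> DelayTimeMap:
    """Delay-resolved directed information from ``source`` (X) to ``target``
    (Y) across epochs.

    For every time t and delay tau the triplet ``(Y_t, X_{t-tau},
    Y_{t-tau})`` is copula-normalized across epochs and
    ``I(X_{t-tau}; Y_t | Y_{t-tau})`` is computed under the Gaussian model.
    Delays default to 0..500 ms in steps of 4 ms and must be multiples of
    the sample period.  Entries where ``t - tau`` precedes the epoch start
    are NaN.  At tau = 0 the quantity is identically zero (conditioning on
    Y_t itself).
    """
    if source.values.shape != target.values.shape:
        raise ValueError("source and target must share epochs and times")
    if not np.array_equal(source.times, target.times) or source.rate != target.rate:
        raise ValueError("source and target must share the time grid")
    n_ep, n_t = source.values.shape
    if n_ep < min_epochs:
        raise ValueError(f"need at least {min_epochs} epochs, got {n_ep}")
    dt = 1000.0 / source.rate
    if delays is None:
        delays = np.arange(0.0, 500.0 + dt / 2, 4.0)
    delays = np.asarray(delays, dtype=float)
    lag_f = delays / dt
    lags = np.rint(lag_f).astype(int)
    if not np.allclose(lag_f, lags, atol=1e-9):
        raise ValueError("delays must be multiples of the sample period")

    xn = copula_normalize(source.values, axis=0)
    yn = copula_normalize(target.values, axis=0)
    xn = xn - xn.mean(axis=0)
    yn = yn - yn.mean(axis=0)
    denom = n_ep - 1
    g_xy = xn.T @ yn / denom
    g_yy = yn.T @ yn / denom
    var_x = np.einsum("ij,ij->j", xn, xn) / denom
    var_y = np.diag(g_yy).copy()

    out = np.full((lags.size, n_t), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for k, lag in enumerate(lags):
            if lag == 0:
                out[k, :] = 0.0
                continue
            t_idx = np.arange(lag, n_t)
            a = t_idx - lag
            va, vb, vc = var_x[a], var_y[t_idx], var_y[a]
            cab = g_xy[a, t_idx]
            cac = g_xy[a, a]
            cbc = g_yy[t_idx, a]
            det_z = vc
            det_xz = va * vc - cac**2
            det_yz = vb * vc - cbc**2
            det_xyz = (
                va * (vb * vc - cbc**2)
                - cab * (cab * vc - cbc * cac)
                + cac * (cab * cbc - vb * cac)
            )
            vals = 0.5 * np.log2(det_xz * det_yz / (det_z * det_xyz))
            if bias_correct:
                vals = vals - (
                    2 * _gauss_ent_corr(2, n_ep) - _gauss_ent_corr(1, n_ep) - _gauss_ent_corr(3, n_ep)
                ) / LN2
            out[k, t_idx] = vals
    return DelayTimeMap(
        values=out,
        delays=delays,
        times=source.times.copy(),
        direction=f"{source.roi_name}->{target.roi_name}",
        condition=target.condition or source.condition,
    )


def symbolize(window_values, n_symbols: int = 32) -> np.ndarray:
    """Discretise a signal window into ``n_symbols`` equal-width amplitude
    bins spanning the window's [min, max]; the maximum maps to the top bin.

    Returns one byte per symbol (uint8).  Affine transforms ``a*x + b``
    (a > 0) of the window yield identical symbol strings.
    """
    x = np.asarray(window_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    if not 2 <= n_symbols <= 256:
        raise ValueError("n_symbols must be in [2, 256]")
    rng = np.ptp(x)
    if rng == 0:
        warnings.warn("constant window; all symbols identical")
        return np.zeros(x.size, dtype=np.uint8)
    idx = np.floor((x - x.min()) / rng * n_symbols).astype(np.int64)
    return np.minimum(idx, n_symbols - 1).astype(np.uint8)


def _deflate_size(payload: bytes, level: int = 6) -> int:
    """Raw-DEFLATE compressed size in bytes (no zlib/gzip header bytes)."""
    co = zlib.compressobj(level, zlib.DEFLATED, -zlib.MAX_WBITS)
    return len(co.compress(payload) + co.flush())


def k_complexity(window_values, n_symbols: int = 32, level: int = 6) -> float:
    """Compression-ratio estimate of Kolmogorov complexity: the window is
    symbolized (32 amplitude bins) and DEFLATE-compressed at fixed level 6;
    the ratio is compressed bytes / original bytes."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        syms = symbolize(window_values, n_symbols)
    payload = syms.tobytes()
    return _deflate_size(payload, level) / len(payload)


def complexity_timecourse(
    epochs: RoiEpochs,
    window_ms: float = 100.0,
    step_ms: float = 4.0,
    n_symbols: int = 32,
) -> ComplexitySeries:
    """Sliding-window K complexity per epoch, averaged across epochs.

    Window and step are converted to samples at the epoch rate; the number
    of windows is ``floor((L - w) / s) + 1``.  Binning uses each window's
    own amplitude range, making the series locally affine-invariant.
    """
    dt = 1000.0 / epochs.rate
    w = int(round(window_ms / dt))
    s = max(int(round(step_ms / dt)), 1)
    n_t = epochs.values.shape[1]
    if w > n_t:
        raise ValueError("window longer than epoch")
    if w < 2:
        raise ValueError("window shorter than 2 samples")
    n_win = (n_t - w) // s + 1
    starts = np.arange(n_win) * s
    per_epoch = np.empty((epochs.n_epochs, n_win))
    for e in range(epochs.n_epochs):
        row = epochs.values[e]
        wins = np.lib.stride_tricks.sliding_window_view(row, w)[::s]
        mins = wins.min(axis=1)
        rngs = np.ptp(wins, axis=1)
        for i in range(n_win):
            if rngs[i] == 0:
                syms = np.zeros(w, dtype=np.uint8)
            else:
                idx = np.floor((wins[i] - mins[i]) / rngs[i] * n_symbols).astype(np.int64)
                syms = np.minimum(idx, n_symbols - 1).astype(np.uint8)
            payload = syms.tobytes()
            per_epoch[e, i] = _deflate_size(payload) / len(payload)
    centres = epochs.times[starts] + (w - 1) * dt / 2.0
    return ComplexitySeries(
        values=per_epoch.mean(axis=0),
        times=centres,
        per_epoch=per_epoch,
        window_ms=window_ms,
        step_ms=step_ms,
        n_symbols=n_symbols,
    )
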