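"""Cluster-based permutation statistics for paired within-subject designs.

Grid points (time series, delay x time maps, or frequency x time maps) are
compared across subjects with dependent-samples t tests; points with
p < 0.01 are clustered under spatial adjacency (neighbours in 1-D,
4-connectivity in 2-D) and each cluster's mass is the sum of its t values.
The null distribution of the largest cluster mass is built by randomly
flipping each subject's condition labels (equivalently, the sign of the
within-subject difference) and the Monte-Carlo p-value of each observed
cluster is ``(1 + #{perm >= observed}) / (n_perm + 1)``.  Positive and
negative clusters form separate families (two-sided testing).

Interaction (double-subtraction) contrasts test the per-subject difference
of differences ``(A1 - A2) - (B1 - B2)`` against zero with the one-sample
sign-flip analogue of the same procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ClusterResult",
    "paired_t_map",
    "cluster_permutation",
    "cluster_permutation_1samp",
    "interaction_contrast",
]

#: Stand-in t value for zero-variance, nonzero-mean differences (degenerate
#: paired t); large but finite so cluster sums stay well-defined.
T_DEGENERATE = 1e12


@dataclass
class ClusterResult:
    """One suprathreshold cluster and its Monte-Carlo p-value."""

    mask: np.ndarray  # boolean over the grid
    cluster_stat: float  # summed t
    p_value: float
    sign: int  # +1 or -1

    @property
    def indices(self) -> tuple:
        return np.nonzero(self.mask)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    """Paired t statistic over axis 0; degenerate (zero-variance) points
    get 0 for zero mean and +/-T_DEGENERATE otherwise."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t = np.where(zero_var & (mean == 0), 0.0, t)
    t = np.where(zero_var & (mean != 0), np.sign(mean) * T_DEGENERATE, t)
    return t


def paired_t_map(set_a: np.ndarray, set_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per grid point, dependent-samples t and two-sided p across subjects.

    ``set_a``/``set_b`` are (n_subjects, *grid) arrays with matched
    subjects.  NaN grid points (e.g., masked map entries) yield NaN.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shapes")
    n = a.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    t = _t_from_diffs(a - b)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return t, p


def _label_clusters(supra: np.ndarray) -> list[np.ndarray]:
    structure = ndimage.generate_binary_structure(supra.ndim, 1)  # 4-connectivity in 2-D
    labels, n_lab = ndimage.label(supra, structure=structure)
    return [labels == k for k in range(1, n_lab + 1)]


def _cluster_sums(t: np.ndarray, thresh: float) -> list[tuple[float, np.ndarray, int]]:
    out = []
    valid = np.isfinite(t)
    for sign in (+1, -1):
        supra = valid & (sign * t > thresh)
        for mask in _label_clusters(supra):
            out.append((float(t[mask].sum()), mask, sign))
    return out


def cluster_permutation_1samp(
    diffs: np.ndarray,
    point_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[ClusterResult]:
    """Sign-flip cluster permutation test of (n_subjects, *grid)
    within-subject difference maps against zero.

    NaN grid points are excluded from clustering.  Only the largest
    |cluster mass| per permutation enters the null distribution.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.shape[0]
    grid_shape = d.shape[1:]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100: Monte-Carlo p-values are coarse")
    rng = np.random.default_rng(seed)
    thresh = stats.t.ppf(1.0 - point_alpha / 2.0, n - 1)

    t_obs = _t_from_diffs(d)
    observed = _cluster_sums(t_obs, thresh)
    if not observed:
        return []

    flat = d.reshape(n, -1)
    nan_cols = np.isnan(flat).any(axis=0)
    flat = np.where(np.isnan(flat), 0.0, flat)
    ssq = (flat**2).sum(axis=0)
    null_max = np.empty(n_perm)
    chunk = max(min(n_perm, int(2e8 // max(flat.shape[1], 1) // 8)), 1)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice(np.array([-1.0, 1.0]), size=(m, n))
        s1 = signs @ flat  # (m, G)
        mean = s1 / n
        var = (ssq[None, :] - n * mean**2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = mean / np.sqrt(var / n)
        t_perm = np.where(var <= 0, np.where(mean == 0, 0.0, np.sign(mean) * T_DEGENERATE), t_perm)
        t_perm[:, nan_cols] = np.nan
        for r in range(m):
            sums = _cluster_sums(t_perm[r].reshape(grid_shape), thresh)
            null_max[done + r] = max((abs(s) for s, _, _ in sums), default=0.0)
        done += m

    results = []
    for stat, mask, sign in observed:
        p = (1.0 + np.sum(null_max >= abs(stat))) / (n_perm + 1.0)
        results.append(ClusterResult(mask=mask, cluster_stat=stat, p_value=float(p), sign=sign))
    results.sort(key=lambda r: r.p_value)
    return results


def cluster_permutation(
    set_a: np.ndarray,
    set_b: np.ndarray,
    point_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[ClusterResult]:
    """Paired two-condition cluster permutation test: subject-wise condition
    labels are exchanged at random, equivalent to sign-flipping the
    within-subject difference maps."""
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shapes")
    return cluster_permutation_1samp(a - b, point_alpha=point_alpha, n_perm=n_perm, seed=seed)


def interaction_contrast(
    set_a1: np.ndarray,
    set_a2: np.ndarray,
    set_b1: np.ndarray,
    set_b2: np.ndarray,
    point_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[ClusterResult]:
    """Double-subtraction interaction: per subject ``(A1 - A2) - (B1 - B2)``
    tested against zero by sign-flip cluster permutation."""
    shapes = {np.shape(s) for s in (set_a1, set_a2, set_b1, set_b2)}
    if len(shapes) != 1:
        raise ValueError("all four sets must share subjects and grids")
    d = (np.asarray(set_a1, float) - np.asarray(set_a2, float)) - (
        np.asarray(set_b1, float) - np.asarray(set_b2, float)
    )
    return cluster_permutation_1samp(d, point_alpha=point_alpha, n_perm=n_perm, seed=seed)
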