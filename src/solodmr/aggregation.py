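"""Combining per-CpG p-values within a genomic window.

Fisher's method assumes the combined tests are independent; neighbouring CpGs
are co-methylated, so a window of k correlated CpGs carries fewer than 2k
effective degrees of freedom. The Empirical Brown method keeps Fisher's
statistic X = −2·Σ ln p_i but refers it to a rescaled chi-square: X/c with
df effective degrees of freedom, where c and df are calibrated from the
control population alone (never the patient), making a calibration reusable
across patients.

Calibration: each probe's control M-value vector is converted to
w = −2·ln(P̂(X ≥ x)) with P̂ the right-tail empirical proportion (floored at
1/n). Under the null each w is marginally ~χ²₂ (mean 2, variance 4), so the
mean of the summed statistic is 2k; its variance is estimated as
4k + 2·Σ_{i<j} cov(w_i, w_j) with cov taken as 4·corr(w_i, w_j) — the
empirical correlation rescaled to the exact χ²₂ marginal variance, so the
independence limit (c = 1, df = 2k: Fisher) and the perfect-correlation
limit (c = k, df = 2k/k) hold exactly at any control count. A c below 1 is
capped at 1: the combined p is never more liberal than Fisher's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .methylome_io import MethylomeError

__all__ = [
    "BrownCalibration",
    "fisher_aggregate",
    "brown_calibrate",
    "brown_aggregate",
    "empirical_w",
    "calibrate_windows",
    "aggregate_windows",
]

_TINY_P = 1e-300


@dataclass(frozen=True)
class BrownCalibration:
    """Scale factor and effective degrees of freedom for one window.

    ``psi_mean`` = 2k, ``psi_var`` = estimated variance of X = −2·Σ ln p,
    ``c`` = psi_var / (2·psi_mean) capped below at 1, ``df`` = 2·psi_mean²/psi_var
    capped above at 2k.
    """

    psi_mean: float
    psi_var: float
    c: float
    df: float


def fisher_aggregate(pvals) -> float:
    """Fisher's method: X = −2·Σ ln p_i on χ² with 2k degrees of freedom."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise MethylomeError("cannot aggregate an empty p-value vector")
    if np.any(p > 1) or np.any(p < 0):
        raise MethylomeError("p-values must lie in [0, 1]")
    p = np.clip(p, _TINY_P, 1.0)
    x = -2 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, df=2 * p.size))


def empirical_w(controls_m: np.ndarray) -> np.ndarray:
    """Per-probe transformed control vectors w = −2·ln((# values ≥ x)/n).

    ``controls_m`` is a k × n matrix (probes × controls); rows must be
    non-constant. The right-tail empirical proportion is at least 1/n, so w
    is finite. Standardizing each row first (as the empirical Brown recipe
    states) leaves the result unchanged — the transform is rank-based.
    """
    a = np.asarray(controls_m, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    k, n = a.shape
    if n < 3:
        raise MethylomeError("Brown calibration needs at least 3 controls")
    if np.any(np.ptp(a, axis=1) == 0):
        raise MethylomeError("a probe is constant across controls: cannot calibrate")
    rank_min = stats.rankdata(a, method="min", axis=1)
    count_ge = n - rank_min + 1
    return -2 * np.log(count_ge / n)


def _unit_rows(w: np.ndarray) -> np.ndarray:
    """Rows centered and scaled to unit norm (so dot products are correlations)."""
    wc = w - w.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(wc, axis=1, keepdims=True)
    return wc / norms


def brown_calibrate(controls_m) -> BrownCalibration:
    """Calibrate c and df for one window from its k × n control M values."""
    w = empirical_w(controls_m)
    k = w.shape[0]
    v = _unit_rows(w)
    s = v.sum(axis=0)
    psi_var = 4.0 * float(s @ s)  # = 4k + 8·Σ_{i<j} corr(w_i, w_j)
    psi_mean = 2.0 * k
    c = psi_var / (2 * psi_mean)
    if c < 1.0:
        c, df = 1.0, 2.0 * k
    else:
        df = 2 * psi_mean**2 / psi_var
    return BrownCalibration(psi_mean=psi_mean, psi_var=psi_var, c=c, df=df)


def brown_aggregate(pvals, calibration: BrownCalibration) -> float:
    """Empirical Brown combined p: upper tail of χ²(df) at (−2·Σ ln p)/c."""
    p = np.asarray(pvals, dtype=float)
    if 2 * p.size != calibration.psi_mean:
        raise MethylomeError(
            f"calibration is for k = {calibration.psi_mean / 2:.0f} probes, "
            f"got {p.size} p-values"
        )
    if np.any(p > 1) or np.any(p < 0):
        raise MethylomeError("p-values must lie in [0, 1]")
    p = np.clip(p, _TINY_P, 1.0)
    x = -2 * np.sum(np.log(p))
    return float(stats.chi2.sf(x / calibration.c, df=calibration.df))


# ---------------------------------------------------------------------------
# batch interface used by dmr_calling and semisim
# ---------------------------------------------------------------------------


def calibrate_windows(
    controls_m: np.ndarray, windows: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Brown calibration for many windows sharing one control set.

    ``controls_m`` is the full probes × n control M matrix; ``windows`` is a
    list of integer row-index arrays. Returns arrays (c, df) per window. The
    expensive rank transform is computed once for every probe that appears in
    any window.
    """
    used = np.unique(np.concatenate(windows)) if windows else np.array([], int)
    if used.size == 0:
        return np.array([]), np.array([])
    w = empirical_w(controls_m[used])
    v = _unit_rows(w)
    row_of = {int(g): i for i, g in enumerate(used)}
    sizes = np.array([len(win) for win in windows])
    flat = np.array([row_of[int(g)] for win in windows for g in win])
    bounds = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    sums = np.add.reduceat(v[flat], bounds, axis=0)
    psi_var = 4.0 * np.einsum("ij,ij->i", sums, sums)
    psi_mean = 2.0 * sizes
    c = psi_var / (2 * psi_mean)
    df = 2 * psi_mean**2 / psi_var
    low = c < 1.0
    c[low] = 1.0
    df[low] = 2.0 * sizes[low]
    return c, df


def aggregate_windows(
    p_raw: np.ndarray, windows: list[np.ndarray], c: np.ndarray, df: np.ndarray
) -> np.ndarray:
    """Brown-combined p per window from the per-probe raw p-value vector."""
    logp = np.log(np.clip(p_raw, _TINY_P, 1.0))
    sizes = np.array([len(win) for win in windows])
    flat = np.concatenate(windows) if windows else np.array([], int)
    bounds = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    x = -2 * np.add.reduceat(logp[flat], bounds)
    return stats.chi2.sf(x / c, df=df)
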