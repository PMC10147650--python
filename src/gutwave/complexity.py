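"""Signal stability and complexity measures: sample entropy, multiscale
sample entropy, and detrended fluctuation analysis (DFA).

Sample entropy follows the Richman–Moorman convention: with tolerance ``r``
and template length ``m``, ``B`` counts pairs of the first ``n - m``
templates of length ``m`` whose Chebyshev distance is <= r (self-matches
excluded), ``A`` counts the same pairs extended to length ``m + 1``, and the
entropy is ``-ln(A / B)``. A perfectly regular series therefore scores 0.

DFA integrates the mean-removed series, detrends it polynomially inside
non-overlapping windows, and estimates the scaling exponent alpha as the
log-log slope of the RMS fluctuation versus window size. White noise gives
alpha ~ 0.5, its running sum alpha ~ 1.5.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist

from .errors import InvalidArgumentError

log = logging.getLogger(__name__)


def sample_entropy(series, m: int = 2, r: float = 0.15) -> float:
    """Sample entropy of a 1-D series.

    Parameters
    ----------
    series : array-like
        Input series, length > m + 1.
    m : int
        Template length.
    r : float
        Absolute match tolerance (Chebyshev), > 0.

    Returns
    -------
    float
        ``-ln(A/B)``. When no extended match exists (``A == 0``) the finite
        cap ``ln(B*(B-1) + 1)`` is returned instead of infinity so the value
        stays usable in downstream t-tests; the event is logged.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if m < 1:
        raise InvalidArgumentError("m must be >= 1")
    if n <= m + 1:
        raise InvalidArgumentError(f"series too short for m={m}: n={n}")
    if r <= 0:
        raise InvalidArgumentError("r must be > 0")

    # First n - m templates of length m and their (m+1)-extensions.
    templates = sliding_window_view(x, m + 1)  # (n - m, m + 1)
    b = int(np.count_nonzero(pdist(templates[:, :m], metric="chebyshev") <= r))
    if b == 0:
        return 0.0
    a = int(np.count_nonzero(pdist(templates, metric="chebyshev") <= r))
    if a == 0:
        log.debug("sample_entropy: A == 0, returning finite cap (B=%d)", b)
        return math.log(b * (b - 1) + 1)
    return -math.log(a / b)


def coarse_grain(series, scale: int) -> np.ndarray:
    """Non-overlapping mean coarse-graining by an integer factor."""
    x = np.asarray(series, dtype=float).ravel()
    if scale < 1:
        raise InvalidArgumentError("scale must be >= 1")
    if scale == 1:
        return x
    k = x.size // scale
    if k == 0:
        raise InvalidArgumentError("series shorter than one coarse-grained point")
    return x[: k * scale].reshape(k, scale).mean(axis=1)


def multiscale_sample_entropy(
    series, scales=(1, 2, 3, 4, 5), m: int = 2, r_factor: float = 0.15
) -> np.ndarray:
    """Sample entropy of coarse-grained versions of the series.

    The tolerance is fixed at ``r_factor`` times the sample standard
    deviation of the *original* series for every scale, so the values are
    comparable across scales and invariant to overall signal amplitude.
    """
    x = np.asarray(series, dtype=float).ravel()
    scales = tuple(int(s) for s in scales)
    if any(s < 1 for s in scales):
        raise InvalidArgumentError("scales must be positive")
    if x.size // max(scales) <= m + 1:
        raise InvalidArgumentError("series too short for the largest scale")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        # Constant series: perfectly regular at every scale.
        return np.zeros(len(scales))
    r = r_factor * sd
    return np.array([sample_entropy(coarse_grain(x, s), m=m, r=r) for s in scales])


def _dfa_windows(lo: int, hi: int, n_points: int = 12) -> np.ndarray:
    w = np.unique(np.round(np.geomspace(lo, hi, n_points)).astype(int))
    return w[(w >= lo) & (w <= hi)]


def dfa_fluctuations(series, windows, order: int = 1, integrate: bool = True):
    """RMS fluctuation F(n) of the integrated, window-detrended series.

    Returns ``(windows, F)`` with one F per window size; windows larger than
    the series are dropped. With ``integrate=False`` the series is treated
    as an already-built profile (useful to verify that order-p detrending
    annihilates a degree-p trend).
    """
    x = np.asarray(series, dtype=float).ravel()
    profile = np.cumsum(x - x.mean()) if integrate else x - x.mean()
    n = profile.size
    ws, fs = [], []
    for w in np.asarray(windows, dtype=int):
        k = n // w
        if k < 1:
            continue
        seg = profile[: k * w].reshape(k, w)
        t = np.arange(w, dtype=float)
        design = np.vander(t, order + 1)  # columns t^order .. 1
        coef, *_ = np.linalg.lstsq(design, seg.T, rcond=None)
        resid = seg.T - design @ coef
        ws.append(w)
        fs.append(np.sqrt(np.mean(resid**2)))
    return np.array(ws), np.array(fs)


def dfa(
    series,
    short_range=(4, 16),
    long_range=(16, 64),
    order: int = 1,
    n_points: int = 12,
):
    """DFA scaling exponents over short, long and overall window ranges.

    Parameters
    ----------
    series : array-like
        Length must be at least 4x the largest window.
    short_range, long_range : (int, int)
        Inclusive window-size ranges (in samples) for the short- and
        long-scale exponents; the overall exponent spans both.

    Returns
    -------
    (alpha_short, alpha_long, alpha_overall)
    """
    x = np.asarray(series, dtype=float).ravel()
    lo, hi = int(short_range[0]), int(long_range[1])
    if lo < order + 2:
        raise InvalidArgumentError("smallest window too small for detrend order")
    if x.size < 4 * hi:
        raise InvalidArgumentError(
            f"series length {x.size} < 4 x largest window {hi}"
        )
    windows = _dfa_windows(lo, hi, n_points)
    ws, fl = dfa_fluctuations(x, windows, order=order)
    if np.any(fl <= 0):
        raise InvalidArgumentError("zero fluctuation; series has no variability")
    logw, logf = np.log(ws), np.log(fl)

    def _slope(mask):
        if np.count_nonzero(mask) < 2:
            raise InvalidArgumentError("too few window sizes in range")
        return float(np.polyfit(logw[mask], logf[mask], 1)[0])

    short_mask = (ws >= short_range[0]) & (ws <= short_range[1])
    long_mask = (ws >= long_range[0]) & (ws <= long_range[1])
    return (
        _slope(short_mask),
        _slope(long_mask),
        _slope(np.ones_like(ws, dtype=bool)),
    )
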