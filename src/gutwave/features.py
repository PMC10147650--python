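"""Extraction of the 24 electrical features from one grid recording.

The feature set covers seven waveform quantities (dominant and average
frequency, dominant power, amplitude, period, upstroke slope, propagation
velocity), three rhythm-band power percentages, five multiscale
sample-entropy scales, three DFA scaling exponents, and six propagation
features (five pattern percentages plus a pattern-change index).

Per-channel scalar features are aggregated across the grid by median for
robustness to dead electrodes; velocity and propagation are computed on the
grid jointly. Rhythm percentages are computed on the channel-averaged
spectrum so they sum to exactly 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .complexity import dfa, multiscale_sample_entropy
from .config import ExtractorConfig
from .errors import (
    DegenerateGeometryError,
    InsufficientEventsError,
    InvalidArgumentError,
    NoRhythmError,
    RejectedRecordingError,
)
from .recording import (
    FEATURE_NAMES,
    MEARecording,
    PROP_PCT_FEATURES,
    RHYTHM_PCT_FEATURES,
    TISSUE_BASE_CPM,
)

log = logging.getLogger(__name__)

PATTERNS = ("forward", "backward", "radial", "colliding", "unorganized")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass
class QualityVerdict:
    passed: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self):
        assert self.passed == (not self.reasons)


def bandpass(x: np.ndarray, fs: float, config: ExtractorConfig | None = None) -> np.ndarray:
    """Zero-phase band-pass over the analysis band (0.5-60 cpm by default)."""
    config = config or ExtractorConfig()
    lo = config.band_low_cpm / 60.0
    hi = min(config.band_high_cpm / 60.0, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def quality_check(rec: MEARecording, config: ExtractorConfig | None = None) -> QualityVerdict:
    """Baseline signal-quality filter.

    Fails when more than half the channels are flat, when the band-passed
    amplitude is below threshold, or when the channel-averaged spectrum has
    no peak exceeding ``peak_median_ratio`` times the in-band median.
    """
    config = config or ExtractorConfig()
    reasons = []
    sds = rec.signals.std(axis=1)
    flat = sds < config.flatline_sd_uv
    if flat.mean() > config.max_flatline_fraction:
        reasons.append("flatline")

    bp = bandpass(rec.signals, rec.fs, config)
    use = ~flat if (~flat).any() else np.ones_like(flat)
    amp_est = np.median((bp[use].max(axis=1) - bp[use].min(axis=1)) / 2.0)
    if amp_est < config.min_amplitude_uv:
        reasons.append("low_amplitude")

    try:
        freqs, psd = welch_spectrum(rec.signals, rec.fs, config=config)
        mean_psd = psd.mean(axis=0) if psd.ndim == 2 else psd
        band = _band_mask(freqs, config)
        in_band = mean_psd[band]
        med = np.median(in_band) if in_band.size else 0.0
        peak = in_band.max() if in_band.size else 0.0
        if peak <= 0 or (med > 0 and peak / med < config.peak_median_ratio):
            reasons.append("no_detectable_rhythm")
    except InvalidArgumentError:
        reasons.append("no_detectable_rhythm")

    return QualityVerdict(passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------


def welch_spectrum(
    x,
    fs: float,
    nperseg: int | None = None,
    config: ExtractorConfig | None = None,
):
    """Welch power spectral density (Hann window, 50% overlap).

    ``x`` may be 1-D or channels x samples. Segments are zero-padded so the
    frequency grid resolves at least ``spectral_resolution_cpm``.
    """
    config = config or ExtractorConfig()
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 16:
        raise InvalidArgumentError("series too short for spectral estimation")
    if nperseg is None:
        nperseg = n
    nperseg = int(min(nperseg, n))
    res_hz = config.spectral_resolution_cpm / 60.0
    nfft = int(2 ** math.ceil(math.log2(max(nperseg, fs / res_hz))))
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
        detrend="constant",
        axis=-1,
    )
    return freqs, psd


def _band_mask(freqs_hz: np.ndarray, config: ExtractorConfig) -> np.ndarray:
    cpm = freqs_hz * 60.0
    return (cpm >= config.band_low_cpm) & (cpm <= config.band_high_cpm)


def dominant_frequency_power(
    freqs_hz: np.ndarray, psd: np.ndarray, config: ExtractorConfig | None = None
):
    """Dominant in-band frequency (cpm) and its power (uV^2).

    Ties are broken toward the lower frequency. The dominant power is the
    peak spectral density integrated over one frequency bin.
    """
    config = config or ExtractorConfig()
    band = _band_mask(freqs_hz, config)
    if not band.any():
        raise NoRhythmError("analysis band is empty")
    f_band, p_band = freqs_hz[band], np.asarray(psd, dtype=float)[band]
    if p_band.max() <= 0:
        raise NoRhythmError("no spectral power in the analysis band")
    i = int(np.argmax(p_band))  # first maximum = lowest frequency on ties
    df = freqs_hz[1] - freqs_hz[0]
    return float(f_band[i] * 60.0), float(p_band[i] * df)


def rhythm_percentages(
    freqs_hz: np.ndarray,
    psd: np.ndarray,
    tissue: str,
    config: ExtractorConfig | None = None,
):
    """Percentages of in-band power below / within / above the tissue's
    normal slow-wave band (``normal_band_rel`` x base frequency).

    The three bands partition the analysis band, so the percentages sum to
    exactly 100.
    """
    config = config or ExtractorConfig()
    f0 = TISSUE_BASE_CPM[tissue]
    lo_rel, hi_rel = config.normal_band_rel
    cpm = freqs_hz * 60.0
    band = _band_mask(freqs_hz, config)
    p = np.asarray(psd, dtype=float)
    total = p[band].sum()
    if total <= 0:
        raise NoRhythmError("zero total band power")
    brady = p[band & (cpm < lo_rel * f0)].sum()
    normal = p[band & (cpm >= lo_rel * f0) & (cpm <= hi_rel * f0)].sum()
    tachy = p[band & (cpm > hi_rel * f0)].sum()
    return (
        100.0 * brady / total,
        100.0 * normal / total,
        100.0 * tachy / total,
    )


# ---------------------------------------------------------------------------
# Event detection and waveform features
# ---------------------------------------------------------------------------


@dataclass
class Events:
    """Wave events on one channel (sample indices into the filtered trace)."""

    peaks: np.ndarray
    troughs: np.ndarray
    onsets: np.ndarray
    filtered: np.ndarray
    fs: float

    def __len__(self):
        return len(self.peaks)

    @property
    def peak_times(self) -> np.ndarray:
        return self.peaks / self.fs


def detect_events(
    x,
    fs: float,
    config: ExtractorConfig | None = None,
    dominant_period_s: float | None = None,
) -> Events:
    """Detect slow-wave events (peak, preceding trough, upstroke onset).

    Peaks are found on the band-passed trace with a refractory distance of
    half the dominant period and a prominence of at least
    ``event_prominence_mads`` times the out-of-band noise MAD.
    """
    config = config or ExtractorConfig()
    x = np.asarray(x, dtype=float).ravel()
    bp = bandpass(x, fs, config)
    if dominant_period_s is None:
        freqs, psd = welch_spectrum(x, fs, config=config)
        try:
            dom_cpm, _ = dominant_frequency_power(freqs, psd, config)
            dominant_period_s = 60.0 / dom_cpm
        except NoRhythmError:
            return Events(np.array([], int), np.array([], int), np.array([], int), bp, fs)

    noise = x - bp
    mad = 1.4826 * np.median(np.abs(noise - np.median(noise)))
    span = bp.max() - bp.min()
    prominence = max(config.event_prominence_mads * mad, 0.02 * span, 1e-9)
    distance = max(1, int(round(config.refractory_fraction * dominant_period_s * fs)))
    peaks, _ = sps.find_peaks(bp, distance=distance, prominence=prominence)

    troughs = np.empty(len(peaks), dtype=int)
    onsets = np.empty(len(peaks), dtype=int)
    win = int(round(dominant_period_s * fs))
    for k, pk in enumerate(peaks):
        start = peaks[k - 1] if k > 0 else max(0, pk - win)
        if start >= pk:
            start = max(0, pk - 1)
        tr = start + int(np.argmin(bp[start : pk + 1]))
        troughs[k] = tr
        seg = bp[tr : pk + 1]
        onsets[k] = tr + (int(np.argmax(np.diff(seg))) if seg.size > 1 else 0)
    return Events(peaks, troughs, onsets, bp, fs)


def waveform_features(events: Events, channel=None, fs: float | None = None):
    """(average_frequency cpm, amplitude uV, period s, slope uV/s).

    Average frequency is 60 x (n-1) / elapsed time between first and last
    peak; amplitude is the mean peak-to-trough excursion; slope is the mean
    per-event maximum upstroke rate.
    """
    if len(events) < 2:
        raise InsufficientEventsError(f"{len(events)} events (< 2)")
    x = np.asarray(channel, dtype=float) if channel is not None else events.filtered
    fs = fs if fs is not None else events.fs
    t = events.peaks / fs
    avg_freq = 60.0 * (len(events) - 1) / (t[-1] - t[0])
    period = float(np.mean(np.diff(t)))
    amplitude = float(np.mean(x[events.peaks] - x[events.troughs]))
    slopes = []
    for tr, pk in zip(events.troughs, events.peaks):
        seg = x[tr : pk + 1]
        if seg.size > 1:
            slopes.append(np.max(np.diff(seg)) * fs)
    slope = float(np.mean(slopes)) if slopes else 0.0
    return float(avg_freq), amplitude, period, slope


# ---------------------------------------------------------------------------
# Velocity
# ---------------------------------------------------------------------------


@dataclass
class VelocityEstimate:
    speed_um_s: float
    capped: bool = False
    slowness_x: float = 0.0  # s/um along the longitudinal axis
    slowness_y: float = 0.0


def _pair_lags(bp, pairs, fs, max_lag):
    """Cross-correlation lag (seconds, parabolic-refined) of b after a for
    each (a, b) channel pair."""
    n = bp.shape[1]
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    spec = np.fft.rfft(bp, nfft, axis=1)
    a_idx = np.array([p[0] for p in pairs])
    b_idx = np.array([p[1] for p in pairs])
    corr = np.fft.irfft(np.conj(spec[a_idx]) * spec[b_idx], nfft, axis=1)
    # corr[., tau] = sum_t a[t] * b[t + tau], circular; tau < 0 wraps to end.
    taus = np.concatenate([np.arange(-max_lag, 0), np.arange(0, max_lag + 1)])
    window = corr[:, taus % nfft]
    best = np.argmax(window, axis=1)
    lags = taus[best].astype(float)
    # Parabolic sub-sample refinement where neighbours exist.
    interior = (best > 0) & (best < len(taus) - 1)
    i = np.arange(len(pairs))[interior]
    y0 = window[i, best[interior] - 1]
    y1 = window[i, best[interior]]
    y2 = window[i, best[interior] + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    lags[interior] += np.clip(shift, -0.5, 0.5)
    return lags / fs


def estimate_velocity(
    rec: MEARecording,
    config: ExtractorConfig | None = None,
    bp: np.ndarray | None = None,
    dominant_period_s: float | None = None,
) -> VelocityEstimate:
    """Propagation speed from adjacent-electrode cross-correlation lags.

    Lags are measured between adjacent electrode pairs (never more than half
    a dominant period apart, so no phase wrapping) and combined into a
    plane-wave slowness vector; speed is the reciprocal of its magnitude,
    capped at ``velocity_max_um_s`` for near-synchronous activity.
    """
    config = config or ExtractorConfig()
    if rec.grid_rows < 2 or rec.grid_cols < 2:
        raise DegenerateGeometryError("plane fit requires a 2-D electrode grid")
    if bp is None:
        bp = bandpass(rec.signals, rec.fs, config)
    sds = bp.std(axis=1)
    nonflat = sds >= min(config.flatline_sd_uv, max(sds.max(), 1e-12) * 1e-3)
    if nonflat.sum() < 4:
        raise InvalidArgumentError("fewer than 4 non-flat channels")
    if dominant_period_s is None:
        freqs, psd = welch_spectrum(rec.signals[nonflat], rec.fs, config=config)
        dom_cpm, _ = dominant_frequency_power(freqs, psd.mean(axis=0), config)
        dominant_period_s = 60.0 / dom_cpm

    max_lag = max(1, int(np.floor(0.5 * dominant_period_s * rec.fs)))
    cols = rec.grid_cols
    ch = np.arange(rec.n_channels)
    horizontal = [
        (c, c + 1)
        for c in ch
        if (c % cols) < cols - 1 and nonflat[c] and nonflat[c + 1]
    ]
    vertical = [
        (c, c + cols)
        for c in ch
        if c + cols < rec.n_channels and nonflat[c] and nonflat[c + cols]
    ]
    if not horizontal or not vertical:
        raise DegenerateGeometryError("no usable adjacent electrode pairs")
    lags_h = _pair_lags(bp, horizontal, rec.fs, max_lag)
    lags_v = _pair_lags(bp, vertical, rec.fs, max_lag)
    sx = float(np.median(lags_h)) / rec.pitch_um  # s/um
    sy = float(np.median(lags_v)) / rec.pitch_um
    slowness = math.hypot(sx, sy)
    if slowness < 1.0 / config.velocity_max_um_s:
        log.debug("velocity capped at %.0f um/s (near-synchronous)", config.velocity_max_um_s)
        return VelocityEstimate(config.velocity_max_um_s, capped=True, slowness_x=sx, slowness_y=sy)
    return VelocityEstimate(1.0 / slowness, capped=False, slowness_x=sx, slowness_y=sy)


# ---------------------------------------------------------------------------
# Propagation patterns
# ---------------------------------------------------------------------------


def _plane_fit(xy, t):
    """Least-squares plane t = a*x + b*y + c; returns (a, b, r2)."""
    design = np.column_stack([xy, np.ones(len(t))])
    coef, *_ = np.linalg.lstsq(design, t, rcond=None)
    resid = t - design @ coef
    ss_tot = np.sum((t - t.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return coef[0], coef[1], r2


def _grid_neighbors(n_ch, cols):
    nbrs = [[] for _ in range(n_ch)]
    for c in range(n_ch):
        if c % cols < cols - 1:
            nbrs[c].append(c + 1)
            nbrs[c + 1].append(c)
        if c + cols < n_ch:
            nbrs[c].append(c + cols)
            nbrs[c + cols].append(c)
    return nbrs


def _match_wave(anchor_time, ref, event_times, neighbors, window_s):
    """Region-growing match of one wave's arrival time on each channel.

    Starting from the reference channel, each grid neighbour is matched to
    its event nearest in time to the already-matched neighbour, so lags
    accumulate across the grid without phase wrapping.
    """
    matched = {ref: anchor_time}
    queue = [ref]
    while queue:
        cur = queue.pop(0)
        for nb in neighbors[cur]:
            if nb in matched:
                continue
            times = event_times[nb]
            if times.size == 0:
                continue
            j = int(np.searchsorted(times, matched[cur]))
            cands = [k for k in (j - 1, j) if 0 <= k < times.size]
            best = min(cands, key=lambda k: abs(times[k] - matched[cur]))
            if abs(times[best] - matched[cur]) <= window_s:
                matched[nb] = times[best]
                queue.append(nb)
    return matched


def _classify_wave(matched, positions, cols, rows, config):
    idx = np.array(sorted(matched))
    t = np.array([matched[c] for c in idx])
    if idx.size < max(6, positions.shape[0] // 2):
        return "unorganized"
    xy = positions[idx]
    a, b, r2 = _plane_fit(xy, t)
    if r2 >= config.prop_min_r2 and (a != 0 or b != 0):
        angle = math.degrees(math.atan2(b, a))
        if abs(angle) <= config.prop_angle_deg:
            return "forward"
        if abs(angle) >= 180.0 - config.prop_angle_deg:
            return "backward"
    # Colliding: opposing plane waves on the two grid halves.
    col_of = idx % cols
    mid = cols / 2.0
    left, right = col_of < mid, col_of >= mid
    if left.sum() >= 3 and right.sum() >= 3:
        al, _, r2l = _plane_fit(xy[left], t[left])
        ar, _, r2r = _plane_fit(xy[right], t[right])
        if r2l >= config.prop_min_r2 and r2r >= config.prop_min_r2 and al > 0 > ar:
            return "colliding"
    # Radial: linear arrival time versus distance from an interior source.
    src = idx[int(np.argmin(t))]
    src_col, src_row = src % cols, src // cols
    if 0 < src_col < cols - 1 and 0 < src_row < rows - 1:
        d = np.linalg.norm(xy - positions[src], axis=1)
        design = np.column_stack([d, np.ones_like(d)])
        coef, *_ = np.linalg.lstsq(design, t, rcond=None)
        resid = t - design @ coef
        ss_tot = np.sum((t - t.mean()) ** 2)
        r2d = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        if r2d >= config.prop_min_r2 and coef[0] > 0:
            return "radial"
    return "unorganized"


def propagation_features(
    rec: MEARecording,
    config: ExtractorConfig | None = None,
    events: list | None = None,
    dominant_period_s: float | None = None,
):
    """Classify every detected wave and summarize the pattern mix.

    Returns ``(percentages, change_index)`` where ``percentages`` is a dict
    over forward/backward/radial/colliding/unorganized summing to 100 and
    ``change_index`` is 1 minus the modal-pattern fraction.
    """
    config = config or ExtractorConfig()
    if events is None:
        events = [detect_events(rec.signals[c], rec.fs, config, dominant_period_s)
                  for c in range(rec.n_channels)]
    n_with = sum(1 for ev in events if len(ev) > 0)
    if n_with < rec.n_channels / 2:
        raise NoRhythmError("events detectable on fewer than half the channels")
    if dominant_period_s is None:
        freqs, psd = welch_spectrum(rec.signals, rec.fs, config=config)
        dom_cpm, _ = dominant_frequency_power(freqs, psd.mean(axis=0), config)
        dominant_period_s = 60.0 / dom_cpm

    onset_times = [ev.onsets / rec.fs if len(ev) else np.array([]) for ev in events]
    ref = int(np.argmax([len(ev) for ev in events]))
    anchors = onset_times[ref]
    if anchors.size == 0:
        raise NoRhythmError("no classifiable waves")
    positions = rec.channel_positions()
    neighbors = _grid_neighbors(rec.n_channels, rec.grid_cols)
    window_s = config.prop_match_window_periods * dominant_period_s

    labels = []
    for t0 in anchors:
        matched = _match_wave(t0, ref, onset_times, neighbors, window_s)
        labels.append(
            _classify_wave(matched, positions, rec.grid_cols, rec.grid_rows, config)
        )
    n = len(labels)
    counts = {p: labels.count(p) for p in PATTERNS}
    percentages = {p: 100.0 * counts[p] / n for p in PATTERNS}
    change_index = 1.0 - max(counts.values()) / n
    return percentages, change_index


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def _complexity_channel_indices(n_ch: int, k: int) -> np.ndarray:
    return np.unique(np.round(np.linspace(0, n_ch - 1, min(k, n_ch))).astype(int))


def extract_features(
    rec: MEARecording, config: ExtractorConfig | None = None
) -> pd.Series:
    """Extract the canonical 24-feature vector from one recording.

    Raises :class:`RejectedRecordingError` when the recording fails the
    baseline quality checks; deterministic for a given recording and
    configuration.
    """
    config = config or ExtractorConfig()
    verdict = quality_check(rec, config)
    if not verdict.passed:
        raise RejectedRecordingError(verdict.reasons)

    f0 = TISSUE_BASE_CPM[rec.tissue]
    nperseg = int(round(config.welch_segment_periods * rec.fs * 60.0 / f0))
    freqs, psd = welch_spectrum(rec.signals, rec.fs, nperseg=nperseg, config=config)
    mean_psd = psd.mean(axis=0)
    dom_cpm_grid, _ = dominant_frequency_power(freqs, mean_psd, config)
    period_guess = 60.0 / dom_cpm_grid

    band = _band_mask(freqs, config)
    df_hz = freqs[1] - freqs[0]
    per_ch_argmax = np.argmax(psd[:, band], axis=1)
    f_band = freqs[band]
    dom_freq = float(np.median(f_band[per_ch_argmax] * 60.0))
    dom_power = float(np.median(psd[:, band][np.arange(psd.shape[0]), per_ch_argmax] * df_hz))

    pct_brady, pct_normal, pct_tachy = rhythm_percentages(freqs, mean_psd, rec.tissue, config)

    bp = bandpass(rec.signals, rec.fs, config)
    noise = rec.signals - bp
    events = []
    for c in range(rec.n_channels):
        mad = 1.4826 * np.median(np.abs(noise[c] - np.median(noise[c])))
        span = bp[c].max() - bp[c].min()
        prominence = max(config.event_prominence_mads * mad, 0.02 * span, 1e-9)
        distance = max(1, int(round(config.refractory_fraction * period_guess * rec.fs)))
        peaks, _ = sps.find_peaks(bp[c], distance=distance, prominence=prominence)
        troughs = np.empty(len(peaks), dtype=int)
        onsets = np.empty(len(peaks), dtype=int)
        win = int(round(period_guess * rec.fs))
        for k, pk in enumerate(peaks):
            start = peaks[k - 1] if k > 0 else max(0, pk - win)
            if start >= pk:
                start = max(0, pk - 1)
            tr = start + int(np.argmin(bp[c, start : pk + 1]))
            troughs[k] = tr
            seg = bp[c, tr : pk + 1]
            onsets[k] = tr + (int(np.argmax(np.diff(seg))) if seg.size > 1 else 0)
        events.append(Events(peaks, troughs, onsets, bp[c], rec.fs))

    wf = [waveform_features(ev) for ev in events if len(ev) >= 2]
    if not wf:
        raise InsufficientEventsError("no channel has >= 2 events")
    wf = np.array(wf)
    avg_freq, amplitude, period, slope = np.median(wf, axis=0)

    vel = estimate_velocity(rec, config, bp=bp, dominant_period_s=period_guess)
    pct, change_index = propagation_features(
        rec, config, events=events, dominant_period_s=period_guess
    )

    cidx = _complexity_channel_indices(rec.n_channels, config.complexity_channels)
    mse = np.median(
        [
            multiscale_sample_entropy(
                bp[c], scales=config.mse_scales, m=config.mse_m, r_factor=config.mse_r_factor
            )
            for c in cidx
        ],
        axis=0,
    )
    alphas = np.median(
        [
            dfa(rec.signals[c], config.dfa_short, config.dfa_long, order=config.dfa_order)
            for c in cidx
        ],
        axis=0,
    )

    values = {
        "dominant_frequency": dom_freq,
        "average_frequency": float(avg_freq),
        "dominant_power": dom_power,
        "amplitude": float(amplitude),
        "period": float(period),
        "slope": float(slope),
        "velocity": vel.speed_um_s,
        "pct_brady": pct_brady,
        "pct_normal": pct_normal,
        "pct_tachy": pct_tachy,
        **{f"mse_scale_{i + 1}": float(mse[i]) for i in range(5)},
        "dfa_alpha_short": float(alphas[0]),
        "dfa_alpha_long": float(alphas[1]),
        "dfa_alpha_overall": float(alphas[2]),
        **{f"pct_prop_{p}": pct[p] for p in PATTERNS},
        "prop_pattern_change_index": float(change_index),
    }
    return pd.Series([values[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES))


def validate_ef_vector(ef: pd.Series, tol: float = 1e-6) -> None:
    """Raise if a feature vector violates the structural invariants."""
    if list(ef.index) != list(FEATURE_NAMES):
        raise InvalidArgumentError("feature vector index mismatch")
    if not np.all(np.isfinite(ef.values.astype(float))):
        raise InvalidArgumentError("non-finite feature value")
    if abs(sum(ef[f] for f in RHYTHM_PCT_FEATURES) - 100.0) > tol:
        raise InvalidArgumentError("rhythm percentages do not sum to 100")
    if abs(sum(ef[f] for f in PROP_PCT_FEATURES) - 100.0) > tol:
        raise InvalidArgumentError("propagation percentages do not sum to 100")
    if ef["period"] <= 0 or ef["dominant_frequency"] <= 0 or ef["average_frequency"] <= 0:
        raise InvalidArgumentError("non-positive period or frequency")
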