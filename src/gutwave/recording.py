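"""Multi-electrode recording container and canonical feature names.

A recording is a rectangular grid of extracellular electrodes sampled
simultaneously; signals are stored channels x samples in microvolts, with
channels in row-major grid order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

TISSUES = ("stomach", "duodenum", "ileum", "colon")

#: Tissue-typical slow-wave base frequencies (cycles per minute). These are
#: order-of-magnitude values; only relative (pre/post drug) changes matter
#: downstream.
TISSUE_BASE_CPM = {"stomach": 5.0, "duodenum": 17.0, "ileum": 12.0, "colon": 7.0}

PHASES = ("baseline", "post_drug")

#: Canonical names and order of the 24 electrical features.
FEATURE_NAMES = (
    "dominant_frequency",
    "average_frequency",
    "dominant_power",
    "amplitude",
    "period",
    "slope",
    "velocity",
    "pct_brady",
    "pct_normal",
    "pct_tachy",
    "mse_scale_1",
    "mse_scale_2",
    "mse_scale_3",
    "mse_scale_4",
    "mse_scale_5",
    "dfa_alpha_short",
    "dfa_alpha_long",
    "dfa_alpha_overall",
    "pct_prop_forward",
    "pct_prop_backward",
    "pct_prop_radial",
    "pct_prop_colliding",
    "pct_prop_unorganized",
    "prop_pattern_change_index",
)

#: Features normalized by difference (percentage points) rather than ratio.
#: The rhythm and propagation percentages are bounded shares of a whole, and
#: the pattern-change index is a bounded fraction whose baseline is
#: legitimately zero on regular recordings, so ratio normalization would be
#: degenerate.
DIFFERENCE_FEATURES = frozenset(
    (
        "pct_brady",
        "pct_normal",
        "pct_tachy",
        "pct_prop_forward",
        "pct_prop_backward",
        "pct_prop_radial",
        "pct_prop_colliding",
        "pct_prop_unorganized",
        "prop_pattern_change_index",
    )
)

RHYTHM_PCT_FEATURES = ("pct_brady", "pct_normal", "pct_tachy")
PROP_PCT_FEATURES = (
    "pct_prop_forward",
    "pct_prop_backward",
    "pct_prop_radial",
    "pct_prop_colliding",
    "pct_prop_unorganized",
)


@dataclass
class MEARecording:
    """One grid recording with its acquisition metadata.

    Parameters
    ----------
    signals
        Array of shape (channels, samples) in microvolts; channels are in
        row-major grid order (channel = row * grid_cols + col).
    fs
        Sampling frequency in Hz.
    """

    signals: np.ndarray
    fs: float
    grid_rows: int
    grid_cols: int
    pitch_um: float
    tissue: str
    drug_id: str = "none"
    dose: float = float("nan")
    phase: str = "baseline"
    repeat: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise InvalidArgumentError("signals must be channels x samples")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.tissue not in TISSUES:
            raise InvalidArgumentError(f"unknown tissue {self.tissue!r}")
        if self.phase not in PHASES:
            raise InvalidArgumentError(f"unknown phase {self.phase!r}")
        if self.grid_rows * self.grid_cols != self.signals.shape[0]:
            raise InvalidArgumentError("grid shape inconsistent with channel count")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_positions(self) -> np.ndarray:
        """(channels, 2) electrode coordinates in micrometres (x = column axis,
        the tissue's longitudinal axis; y = row axis)."""
        rows, cols = np.divmod(np.arange(self.n_channels), self.grid_cols)
        return np.column_stack([cols * self.pitch_um, rows * self.pitch_um]).astype(float)
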