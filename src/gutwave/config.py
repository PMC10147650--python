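"""Analysis configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class ExtractorConfig:
    """Tunable parameters of feature extraction and quality filtering.

    Frequencies are in cycles per minute (cpm), amplitudes in microvolts.
    """

    # Spectral analysis band and rhythm bands (relative to tissue base f0).
    band_low_cpm: float = 0.5
    band_high_cpm: float = 60.0
    normal_band_rel: tuple = (0.5, 1.5)
    # Welch estimator: segment length in dominant periods, zero-padded so the
    # frequency grid resolves at least `spectral_resolution_cpm`.
    welch_segment_periods: float = 8.0
    spectral_resolution_cpm: float = 0.25
    # Quality thresholds.
    flatline_sd_uv: float = 1.0
    max_flatline_fraction: float = 0.5
    peak_median_ratio: float = 4.0
    min_amplitude_uv: float = 5.0
    # Event detection.
    event_prominence_mads: float = 3.0
    refractory_fraction: float = 0.5
    # Complexity features.
    mse_m: int = 2
    mse_r_factor: float = 0.15
    mse_scales: tuple = (1, 2, 3, 4, 5)
    dfa_short: tuple = (4, 16)
    dfa_long: tuple = (16, 64)
    dfa_order: int = 1
    # Number of channels (spread evenly over the grid) used for MSE/DFA;
    # aggregated by median.
    complexity_channels: int = 4
    # Propagation classification.
    prop_min_r2: float = 0.7
    prop_angle_deg: float = 45.0
    prop_match_window_periods: float = 0.6
    # Velocity estimation.
    velocity_max_um_s: float = 20000.0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExtractorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        tuple_fields = {
            f.name for f in fields(cls) if isinstance(getattr(cls(), f.name), tuple)
        }
        for k in list(d):
            if k in tuple_fields:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ProtocolConfig:
    """Classification-protocol settings."""

    algorithms: tuple = ("naive_bayes", "discriminant", "tree", "knn", "svm")
    n_randomizations: int = 7
    validation_margin_points: float = 0.5
    coverage_threshold: float = 0.8
    split_mode: str = "row"  # or "drug"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["algorithms"] = list(d["algorithms"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "algorithms" in d:
            d["algorithms"] = tuple(d["algorithms"])
        return cls(**d)
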