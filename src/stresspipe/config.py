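"""Pipeline configuration.

All tunable thresholds of the preprocessing and feature-extraction stages
live here, so a run is fully described by one :class:`PipelineConfig`.
Defaults are the protocol values where the protocol fixes them (120 s
windows, 20% RR artifact threshold, 10% window rejection, 4 Hz spectral
resampling) and documented package choices elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PreprocessConfig:
    """Windowing, artifact screening and EDA decomposition settings."""

    window_s: float = 120.0          # analysis window length
    rr_threshold: float = 0.20       # relative RR deviation that flags a beat
    reject_frac: float = 0.10        # window invalid if flagged fraction exceeds this
    max_correct_frac: float = 0.50   # refuse spline correction above this flagged fraction
    eda_epoch_s: float = 5.0         # EDA artifact screening epoch
    eda_slope_thr: float = 0.5       # µS per sample; motion-rule slope threshold
    acc_sd_thr: float = 0.1          # g; accelerometer magnitude SD that marks motion
    eda_floor: float = 0.01          # µS; plausibility lower bound
    eda_ceil: float = 60.0           # µS; plausibility upper bound
    tonic_cutoff_hz: float = 0.05    # low-pass cutoff of the tonic/phasic split
    tonic_filter_order: int = 4


@dataclass
class FeatureConfig:
    """HRV and EDA feature-extraction settings."""

    resample_hz: float = 4.0             # tachogram resampling rate for spectra
    pnn_threshold_ms: float = 50.0       # pNN50 successive-difference threshold
    hist_bin_ms: float = 1000.0 / 128.0  # RR histogram bin width (1/128 s)
    vlf_band: tuple[float, float] = (0.0, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    peak_prominence_uS: float = 0.01        # SCR peak counting
    strong_peak_prominence_uS: float = 0.10  # strong SCR peaks
    min_peak_separation_s: float = 1.0
    min_rr_count: int = 10               # fewer corrected intervals drops the window
    min_freq_span_s: float = 60.0        # minimum beat coverage for spectral features
    min_eda_span_s: float = 30.0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)


DEFAULT_CONFIG = PipelineConfig()
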