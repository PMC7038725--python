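"""Canonical feature schema: 13 HRV + 7 phasic-EDA + 7 tonic-EDA = 27 names.

The order is fixed; every feature table, vector and model modality refers
to these names.
"""

from __future__ import annotations

HRV_FEATURES: tuple[str, ...] = (
    "hrv_mean_rr",     # ms, mean RR interval
    "hrv_sdnn",        # ms, SD of RR intervals
    "hrv_rmssd",       # ms, root mean square of successive differences
    "hrv_pnn50",       # %, successive differences > 50 ms
    "hrv_tri_index",   # dimensionless, n / modal histogram bin count (1/128 s bins)
    "hrv_tinn",        # ms, base width of triangular histogram fit
    "hrv_lf_power",    # ms^2, 0.04-0.15 Hz
    "hrv_hf_power",    # ms^2, 0.15-0.4 Hz
    "hrv_lf_hf",       # ratio
    "hrv_lf_peak",     # Hz, prevalent LF oscillation
    "hrv_hf_peak",     # Hz, prevalent HF oscillation
    "hrv_vlf_power",   # ms^2, 0.00-0.04 Hz
    "hrv_sdsd",        # ms, SD of successive differences
)

_EDA_COMPONENT_FEATURES: tuple[str, ...] = (
    "mean", "sd", "n_peaks", "n_strong_peaks", "p20", "p80", "quart_dev",
)

EDA_PHASIC_FEATURES: tuple[str, ...] = tuple(
    f"eda_phasic_{f}" for f in _EDA_COMPONENT_FEATURES
)
EDA_TONIC_FEATURES: tuple[str, ...] = tuple(
    f"eda_tonic_{f}" for f in _EDA_COMPONENT_FEATURES
)
EDA_FEATURES: tuple[str, ...] = EDA_PHASIC_FEATURES + EDA_TONIC_FEATURES

FEATURE_NAMES: tuple[str, ...] = HRV_FEATURES + EDA_FEATURES

assert len(FEATURE_NAMES) == 27

#: feature subsets used by the model matrix
MODALITY_COLUMNS: dict[str, tuple[str, ...]] = {
    "hrv": HRV_FEATURES,
    "eda": EDA_FEATURES,
    "combined": FEATURE_NAMES,
}
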