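"""HRV and EDA feature extraction.

Thirteen heart-rate-variability features are computed per window from the
corrected RR series: time-domain statistics (mean RR, SDNN, RMSSD, pNN50,
SDSD), the geometric histogram measures (triangular index with 1/128-s
bins, TINN), and frequency-domain band powers from an FFT periodogram of
the tachogram cubic-spline-resampled at 4 Hz (VLF 0-0.04 Hz, LF
0.04-0.15 Hz, HF 0.15-0.4 Hz, LF/HF ratio and band peak frequencies).
Seven distribution/peak features are computed from each EDA component
(phasic and tonic): mean, SD, peak counts at two prominence levels, the
20th and 80th percentiles and the quartile deviation.  Window vectors are
averaged into one session-level vector.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, periodogram

from .config import FeatureConfig
from .preprocessing import EDADecomposition, InsufficientData, WindowRecord, epoch_flags_to_samples
from .schema import EDA_PHASIC_FEATURES, EDA_TONIC_FEATURES, FEATURE_NAMES, HRV_FEATURES

logger = logging.getLogger(__name__)

DEFAULT = FeatureConfig()


# ---------------------------------------------------------------------------
# HRV time domain

def _rr_histogram(rr_ms: np.ndarray, bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """RR histogram on a grid of ``bin_ms``-wide bins aligned at zero."""
    lo = math.floor(rr_ms.min() / bin_ms)
    hi = math.floor(rr_ms.max() / bin_ms) + 1
    edges = np.arange(lo, hi + 1) * bin_ms
    counts, _ = np.histogram(rr_ms, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts, centers


def _tinn(counts: np.ndarray, centers: np.ndarray, bin_ms: float) -> float:
    """Base width (ms) of the best least-squares triangle fit to the histogram.

    The apex sits on the modal bin; candidate base points run over the bin
    grid (one bin beyond each end included); ties prefer the narrowest
    triangle.
    """
    m = int(np.argmax(counts))
    X = centers[m]
    Y = counts[m]
    n_cands = np.concatenate(([centers[0] - bin_ms], centers[: m + 1]))
    m_cands = np.concatenate((centers[m:], [centers[-1] + bin_ms]))

    best_err, best_width = np.inf, 0.0
    for N in n_cands:
        for M in m_cands:
            q = np.zeros_like(counts, dtype=float)
            rising = (centers > N) & (centers < X)
            if X > N:
                q[rising] = Y * (centers[rising] - N) / (X - N)
            falling = (centers > X) & (centers < M)
            if M > X:
                q[falling] = Y * (M - centers[falling]) / (M - X)
            q[centers == X] = Y
            err = float(np.sum((counts - q) ** 2))
            width = M - N
            if err < best_err - 1e-12 or (abs(err - best_err) <= 1e-12 and width < best_width):
                best_err, best_width = err, width
    return best_width


def hrv_time_features(rr_ms: Sequence[float], cfg: FeatureConfig = DEFAULT) -> dict[str, float]:
    """Seven time-domain / geometric HRV features from corrected intervals."""
    rr = np.asarray(rr_ms, dtype=float)
    if len(rr) < cfg.min_rr_count:
        raise InsufficientData(
            f"hrv_time_features needs >= {cfg.min_rr_count} intervals, got {len(rr)}"
        )
    diffs = np.diff(rr)
    counts, centers = _rr_histogram(rr, cfg.hist_bin_ms)
    return {
        "hrv_mean_rr": float(rr.mean()),
        "hrv_sdnn": float(rr.std(ddof=1)),
        "hrv_rmssd": float(np.sqrt(np.mean(diffs ** 2))),
        "hrv_pnn50": float(100.0 * np.sum(np.abs(diffs) > cfg.pnn_threshold_ms) / len(diffs)),
        "hrv_tri_index": float(len(rr) / counts.max()),
        "hrv_tinn": _tinn(counts, centers, cfg.hist_bin_ms),
        "hrv_sdsd": float(diffs.std(ddof=1)),
    }


# ---------------------------------------------------------------------------
# HRV frequency domain

def resample_tachogram(
    rr_ms: np.ndarray, beat_s: np.ndarray, rate_hz: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resample of the (beat time, RR) tachogram on a uniform grid."""
    order = np.argsort(beat_s)
    t, r = np.asarray(beat_s, float)[order], np.asarray(rr_ms, float)[order]
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * rate_hz)) + 1) / rate_hz
    return grid, CubicSpline(t, r)(grid)


def hrv_freq_features(
    rr_ms: Sequence[float],
    beat_s: Sequence[float],
    cfg: FeatureConfig = DEFAULT,
) -> dict[str, float]:
    """Six frequency-domain HRV features from the 4 Hz-resampled tachogram.

    Band power is the rectangle-rule integral of the one-sided FFT
    periodogram over half-open bands; the VLF band excludes the DC bin.
    LF/HF and band peaks are NaN when the denominator band is empty of
    power (e.g. a constant RR series).
    """
    rr = np.asarray(rr_ms, dtype=float)
    t = np.asarray(beat_s, dtype=float)
    if len(rr) < 4 or (t[-1] - t[0]) < cfg.min_freq_span_s:
        raise InsufficientData(
            f"hrv_freq_features needs >= {cfg.min_freq_span_s:.0f} s of beats"
        )
    _, x = resample_tachogram(rr, t, cfg.resample_hz)
    x = x - x.mean()
    f, p = periodogram(x, fs=cfg.resample_hz, window="boxcar",
                       detrend=False, scaling="density")
    df = f[1] - f[0]

    def band(lo: float, hi: float) -> tuple[float, float]:
        mask = (f >= lo) & (f < hi) & (f > 0)
        power = float(p[mask].sum() * df)
        if not mask.any() or power <= 0:
            return power, float("nan")
        peak = float(f[mask][np.argmax(p[mask])])
        return power, peak

    vlf, _ = band(*cfg.vlf_band)
    lf, lf_peak = band(*cfg.lf_band)
    hf, hf_peak = band(*cfg.hf_band)
    return {
        "hrv_vlf_power": vlf,
        "hrv_lf_power": lf,
        "hrv_hf_power": hf,
        "hrv_lf_hf": lf / hf if hf > 0 else float("nan"),
        "hrv_lf_peak": lf_peak,
        "hrv_hf_peak": hf_peak,
    }


# ---------------------------------------------------------------------------
# EDA components

def eda_component_features(
    component: Sequence[float],
    excluded: Optional[np.ndarray] = None,
    cfg: FeatureConfig = DEFAULT,
    rate_hz: float = 4.0,
) -> dict[str, float]:
    """Seven distribution/peak features of one EDA component.

    Samples under the ``excluded`` artifact mask contribute to neither the
    distribution statistics nor the peak counts.  Peaks are local maxima
    with a minimum prominence and >= 1 s separation; strong peaks use the
    higher prominence threshold.
    """
    x = np.asarray(component, dtype=float)
    if excluded is None:
        excluded = np.zeros(len(x), dtype=bool)
    excluded = np.asarray(excluded, dtype=bool)
    valid = x[~excluded]
    if len(valid) < cfg.min_eda_span_s * rate_hz:
        raise InsufficientData(
            f"eda_component_features needs >= {cfg.min_eda_span_s:.0f} s of clean samples"
        )
    dist = max(1, int(round(cfg.min_peak_separation_s * rate_hz)))
    peaks, _ = find_peaks(x, prominence=cfg.peak_prominence_uS, distance=dist)
    strong, _ = find_peaks(x, prominence=cfg.strong_peak_prominence_uS, distance=dist)
    peaks = peaks[~excluded[peaks]]
    strong = strong[~excluded[strong]]
    p20, p25, p75, p80 = np.percentile(valid, [20, 25, 75, 80], method="linear")
    return {
        "mean": float(valid.mean()),
        "sd": float(valid.std(ddof=1)) if len(valid) > 1 else 0.0,
        "n_peaks": float(len(peaks)),
        "n_strong_peaks": float(len(strong)),
        "p20": float(p20),
        "p80": float(p80),
        "quart_dev": float((p75 - p25) / 2.0),
    }


# ---------------------------------------------------------------------------
# assembly

def build_feature_vector(
    window: WindowRecord,
    decomposition: Optional[EDADecomposition],
    cfg: FeatureConfig = DEFAULT,
    eda_rate: float = 4.0,
) -> dict[str, float]:
    """All 27 features of a valid window, NaN for an unavailable modality."""
    if not window.valid:
        raise ValueError("build_feature_vector requires a valid window")
    vec = {name: float("nan") for name in FEATURE_NAMES}

    rr = window.rr_corrected_ms if window.rr_corrected_ms is not None else window.rr_ms
    try:
        vec.update(hrv_time_features(rr, cfg))
        vec.update(hrv_freq_features(rr, window.beat_s, cfg))
    except InsufficientData as exc:
        logger.warning("window %s/%d: HRV missing (%s)",
                       window.session_id, window.window_index, exc)

    if decomposition is not None:
        mask = None
        if window.eda_artifact_epochs is not None:
            mask = epoch_flags_to_samples(
                window.eda_artifact_epochs, len(decomposition.phasic), eda_rate=eda_rate
            )
        try:
            ph = eda_component_features(decomposition.phasic, mask, cfg, eda_rate)
            to = eda_component_features(decomposition.tonic, mask, cfg, eda_rate)
            vec.update({k: ph[k.removeprefix("eda_phasic_")] for k in EDA_PHASIC_FEATURES})
            vec.update({k: to[k.removeprefix("eda_tonic_")] for k in EDA_TONIC_FEATURES})
        except InsufficientData as exc:
            logger.warning("window %s/%d: EDA missing (%s)",
                           window.session_id, window.window_index, exc)
    return vec


def aggregate_session(window_vectors: Sequence[dict[str, float]]) -> tuple[dict[str, float], int]:
    """Per-feature mean over a session's valid windows.

    Missing (NaN) entries are excluded feature-by-feature, so a window
    lacking one modality still contributes its other features.  Returns
    the aggregate vector and the number of contributing windows.
    """
    if len(window_vectors) == 0:
        raise InsufficientData("aggregate_session: no valid windows")
    agg = {}
    for name in FEATURE_NAMES:
        vals = np.array([v[name] for v in window_vectors], dtype=float)
        vals = vals[np.isfinite(vals)]
        agg[name] = float(vals.mean()) if len(vals) else float("nan")
    return agg, len(window_vectors)


def modality_of(name: str) -> str:
    return "hrv" if name in HRV_FEATURES else "eda"
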