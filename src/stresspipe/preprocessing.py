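"""Signal conditioning: windowing, RR artifact handling, EDA screening and
phasic/tonic decomposition.

Signals are cut into non-overlapping 2-minute windows.  RR intervals are
screened with a relative-deviation rule: a beat is an artifact when it
deviates by more than 20% from the last non-flagged interval, which stops
a single ectopic beat from flagging its normal successor.  Flagged beats
are replaced by cubic-spline interpolation over the clean beats (Kubios-
style), and windows whose raw artifact fraction exceeds 10% are rejected
outright.  EDA is screened per 5-s epoch with a deterministic motion rule
(steep conductance change coinciding with accelerometer activity, or
implausible absolute levels) and split into a slow tonic level and a fast
phasic residual by a zero-phase low-pass filter at 0.05 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .config import PreprocessConfig
from .io_e4 import ChannelSeries, RawRecording

logger = logging.getLogger(__name__)

DEFAULT = PreprocessConfig()


class TooManyArtifacts(ValueError):
    """More than half of a window's beats are flagged; correction refused."""


class InsufficientData(ValueError):
    """Input too short for the requested operation."""


@dataclass
class WindowRecord:
    """One half-open analysis window [t_start, t_end) of a session."""

    session_id: str
    window_index: int
    t_start: float
    t_end: float
    rr_ms: np.ndarray                 # intervals whose beat time falls in the window
    beat_s: np.ndarray                # beat times (s since session start)
    eda_uS: np.ndarray                # 4 Hz EDA samples in the window
    rr_artifact_flags: Optional[np.ndarray] = None
    rr_corrected_ms: Optional[np.ndarray] = None
    eda_artifact_epochs: Optional[np.ndarray] = None
    valid: Optional[bool] = None

    @property
    def window_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class EDADecomposition:
    """Tonic (slow level) and phasic (fast residual) EDA components.

    tonic + phasic reconstructs the input exactly by construction.
    """

    tonic: np.ndarray
    phasic: np.ndarray


def slice_channel(ch: ChannelSeries, t0: float, t1: float) -> np.ndarray:
    """Samples of a uniformly sampled channel with offsets in [t0, t1)."""
    if ch.sample_rate is None or len(ch) == 0:
        return ch.values[:0]
    i0 = int(np.ceil(t0 * ch.sample_rate - 1e-9))
    i1 = int(np.ceil(t1 * ch.sample_rate - 1e-9))
    return ch.values[max(i0, 0):max(i1, 0)]


def segment_windows(
    recording: RawRecording, window_s: float = DEFAULT.window_s
) -> list[WindowRecord]:
    """Cut a session into contiguous half-open windows from session start.

    The trailing partial window is dropped.  Every IBI event is assigned
    to exactly one window by its beat time; a beat at exactly a window
    boundary belongs to the later window.
    """
    span = recording.duration_s
    n = int(np.floor(span / window_s + 1e-9))
    if n == 0:
        logger.warning(
            "session %s spans %.1f s < one %.0f s window; no windows",
            recording.session_id, span, window_s,
        )
        return []

    offsets = recording.ibi.offsets_s
    rr_ms = recording.ibi.rr_s * 1000.0
    windows = []
    for i in range(n):
        t0, t1 = i * window_s, (i + 1) * window_s
        in_win = (offsets >= t0) & (offsets < t1)
        windows.append(WindowRecord(
            session_id=recording.session_id,
            window_index=i,
            t_start=t0,
            t_end=t1,
            rr_ms=rr_ms[in_win].copy(),
            beat_s=offsets[in_win].copy(),
            eda_uS=np.asarray(slice_channel(recording.eda, t0, t1), dtype=float).copy(),
        ))
    return windows


def detect_rr_artifacts(
    rr_ms: np.ndarray, threshold: float = DEFAULT.rr_threshold
) -> np.ndarray:
    """Flag RR intervals deviating > ``threshold`` from the last clean one.

    The first interval is never flagged (it has no reference).  The
    reference is the most recent non-flagged interval, so one ectopic beat
    does not flag the normal beat that follows it.
    """
    rr = np.asarray(rr_ms, dtype=float)
    flags = np.zeros(len(rr), dtype=bool)
    if len(rr) < 2:
        logger.warning("detect_rr_artifacts: fewer than 2 intervals, nothing to flag")
        return flags
    ref = rr[0]
    for i in range(1, len(rr)):
        if abs(rr[i] - ref) / ref > threshold:
            flags[i] = True
        else:
            ref = rr[i]
    return flags


def correct_rr(
    rr_ms: np.ndarray,
    flags: np.ndarray,
    max_correct_frac: float = DEFAULT.max_correct_frac,
) -> np.ndarray:
    """Replace flagged intervals by cubic-spline interpolation over clean beats.

    Edge beats outside the clean support are extrapolated and clamped to the
    range of the clean intervals.  Refuses (raises
    :class:`TooManyArtifacts`) when more than half the beats are flagged.
    """
    rr = np.asarray(rr_ms, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if rr.shape != flags.shape:
        raise ValueError("flags must align with rr_ms")
    n_flag = int(flags.sum())
    if n_flag == 0:
        return rr.copy()
    if n_flag / len(rr) > max_correct_frac:
        raise TooManyArtifacts(
            f"{n_flag}/{len(rr)} beats flagged exceeds {max_correct_frac:.0%}"
        )
    idx = np.arange(len(rr))
    good = idx[~flags]
    bad = idx[flags]
    out = rr.copy()
    if len(good) == 1:
        out[bad] = rr[good[0]]
        return out
    if len(good) < 4:
        out[bad] = np.interp(bad, good, rr[good])
    else:
        spline = CubicSpline(good, rr[good], extrapolate=True)
        out[bad] = spline(bad)
    # extrapolated edge beats clamped to the clean range
    lo, hi = rr[good].min(), rr[good].max()
    edge = (bad < good[0]) | (bad > good[-1])
    out[bad[edge]] = np.clip(out[bad[edge]], lo, hi)
    return out


def reject_window(flags: np.ndarray, max_frac: float = DEFAULT.reject_frac) -> bool:
    """Window validity under the artifact-fraction rule.

    A window is kept when at most ``max_frac`` of its beats are flagged
    (strictly more than 10% rejects; exactly 10% is kept).  Empty windows
    are invalid.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) == 0:
        return False
    return bool(flags.sum() / len(flags) <= max_frac)


def detect_eda_artifacts(
    eda_uS: np.ndarray,
    acc_raw: Optional[np.ndarray],
    temp_C: Optional[np.ndarray] = None,
    cfg: PreprocessConfig = DEFAULT,
    acc_rate: float = 32.0,
    eda_rate: float = 4.0,
) -> np.ndarray:
    """Flag 5-s EDA epochs as artifactual using a deterministic rule.

    An epoch is flagged when a steep per-sample conductance change
    (> ``eda_slope_thr`` µS) coincides with accelerometer activity
    (magnitude SD > ``acc_sd_thr`` g in the epoch), or when the signal
    leaves the plausibility bounds [floor, ceil] µS.  ``acc_raw`` is the
    (n, 3) axis array in 1/64 g units; without it the screen falls back to
    EDA-only rules (bounds plus bare slope) with a warning.
    """
    eda = np.asarray(eda_uS, dtype=float)
    n_epochs = int(np.ceil(len(eda) / (cfg.eda_epoch_s * eda_rate))) if len(eda) else 0
    flags = np.zeros(n_epochs, dtype=bool)
    have_acc = acc_raw is not None and len(acc_raw) > 0
    if not have_acc:
        logger.warning("detect_eda_artifacts: no accelerometer; EDA-only rules")
        acc_mag = None
    else:
        acc_mag = np.linalg.norm(np.asarray(acc_raw, dtype=float), axis=1) / 64.0  # g

    e_per = int(round(cfg.eda_epoch_s * eda_rate))
    a_per = int(round(cfg.eda_epoch_s * acc_rate))
    # change arriving at sample i (0 for the first sample), so a step across
    # an epoch boundary is attributed to the epoch it enters
    delta = np.abs(np.diff(eda, prepend=eda[:1])) if len(eda) else eda
    for k in range(n_epochs):
        seg = eda[k * e_per:(k + 1) * e_per]
        if len(seg) == 0:
            continue
        out_of_bounds = bool(np.any((seg < cfg.eda_floor) | (seg > cfg.eda_ceil)))
        steep = float(np.max(delta[k * e_per:(k + 1) * e_per])) > cfg.eda_slope_thr
        if have_acc:
            aseg = acc_mag[k * a_per:(k + 1) * a_per]
            moving = len(aseg) > 1 and float(np.std(aseg)) > cfg.acc_sd_thr
            flags[k] = out_of_bounds or (steep and moving)
        else:
            flags[k] = out_of_bounds or steep
    return flags


def epoch_flags_to_samples(
    epoch_flags: np.ndarray, n_samples: int,
    epoch_s: float = DEFAULT.eda_epoch_s, eda_rate: float = 4.0,
) -> np.ndarray:
    """Expand per-epoch flags to a per-sample exclusion mask."""
    mask = np.zeros(n_samples, dtype=bool)
    per = int(round(epoch_s * eda_rate))
    for k, f in enumerate(np.asarray(epoch_flags, dtype=bool)):
        if f:
            mask[k * per:(k + 1) * per] = True
    return mask


def decompose_eda(
    eda_uS: np.ndarray, cfg: PreprocessConfig = DEFAULT, eda_rate: float = 4.0,
) -> EDADecomposition:
    """Split cleaned EDA into tonic and phasic components.

    Tonic is a zero-phase low-pass (Butterworth, order ``tonic_filter_order``,
    cutoff ``tonic_cutoff_hz``) of the signal; phasic is the residual, so
    tonic + phasic reconstructs the input exactly.
    """
    eda = np.asarray(eda_uS, dtype=float)
    if len(eda) < 30 * eda_rate:
        raise InsufficientData(
            f"decompose_eda needs >= 30 s of signal, got {len(eda) / eda_rate:.1f} s"
        )
    sos = butter(cfg.tonic_filter_order, cfg.tonic_cutoff_hz, btype="low",
                 fs=eda_rate, output="sos")
    tonic = sosfiltfilt(sos, eda)
    return EDADecomposition(tonic=tonic, phasic=eda - tonic)


def preprocess_window(
    window: WindowRecord,
    recording: RawRecording,
    cfg: PreprocessConfig = DEFAULT,
) -> WindowRecord:
    """Run the full artifact pipeline on one window, in place.

    Sets RR flags, validity (10% rule, pre-correction), corrected RR and
    per-epoch EDA artifact flags.  A window whose flagged fraction makes
    correction impossible is marked invalid instead of raising.
    """
    flags = detect_rr_artifacts(window.rr_ms, cfg.rr_threshold)
    window.rr_artifact_flags = flags
    window.valid = reject_window(flags, cfg.reject_frac)
    if window.valid:
        try:
            window.rr_corrected_ms = correct_rr(window.rr_ms, flags, cfg.max_correct_frac)
        except TooManyArtifacts:
            window.valid = False
    acc = slice_channel(recording.acc, window.t_start, window.t_end)
    temp = slice_channel(recording.temp, window.t_start, window.t_end)
    window.eda_artifact_epochs = detect_eda_artifacts(
        window.eda_uS, acc if len(acc) else None, temp if len(temp) else None, cfg,
        acc_rate=recording.acc.sample_rate or 32.0,
        eda_rate=recording.eda.sample_rate or 4.0,
    )
    return window
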