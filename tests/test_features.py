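"""Feature extraction against independent brute-force oracles."""

import math

import numpy as np
import pytest

from stresspipe.config import FeatureConfig
from stresspipe.features import (
    aggregate_session,
    build_feature_vector,
    eda_component_features,
    hrv_freq_features,
    hrv_time_features,
)
from stresspipe.preprocessing import InsufficientData, WindowRecord, decompose_eda
from stresspipe.schema import EDA_FEATURES, FEATURE_NAMES, HRV_FEATURES

CFG = FeatureConfig()


# -- independent oracles (deliberately naive) --------------------------------

def oracle_time_features(rr):
    n = len(rr)
    mean = sum(rr) / n
    sdnn = math.sqrt(sum((x - mean) ** 2 for x in rr) / (n - 1))
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn50 = 100.0 * sum(abs(d) > 50 for d in diffs) / len(diffs)
    dmean = sum(diffs) / len(diffs)
    sdsd = math.sqrt(sum((d - dmean) ** 2 for d in diffs) / (len(diffs) - 1))
    binw = 1000.0 / 128.0
    bins = {}
    for x in rr:
        bins[math.floor(x / binw)] = bins.get(math.floor(x / binw), 0) + 1
    tri = n / max(bins.values())
    return mean, sdnn, rmssd, pnn50, sdsd, tri


def oracle_percentile(xs, q):
    xs = sorted(xs)
    pos = (len(xs) - 1) * q / 100.0
    lo, hi = math.floor(pos), math.ceil(pos)
    return xs[lo] + (xs[hi] - xs[lo]) * (pos - lo)


# -- HRV time domain ---------------------------------------------------------

def test_constant_rr_degenerate():
    f = hrv_time_features([800.0] * 150)
    assert f["hrv_mean_rr"] == 800.0
    assert f["hrv_sdnn"] == 0.0
    assert f["hrv_rmssd"] == 0.0
    assert f["hrv_pnn50"] == 0.0
    assert f["hrv_sdsd"] == 0.0
    assert f["hrv_tri_index"] == 1.0
    assert f["hrv_tinn"] == 0.0


def test_alternating_60ms_pnn50_full():
    rr = [800.0, 860.0] * 10
    assert hrv_time_features(rr)["hrv_pnn50"] == 100.0


def test_time_features_match_bruteforce_oracle(rng):
    rr = (800 + rng.normal(0, 40, 20)).tolist()
    f = hrv_time_features(rr)
    mean, sdnn, rmssd, pnn50, sdsd, tri = oracle_time_features(rr)
    assert f["hrv_mean_rr"] == pytest.approx(mean, abs=1e-9)
    assert f["hrv_sdnn"] == pytest.approx(sdnn, abs=1e-9)
    assert f["hrv_rmssd"] == pytest.approx(rmssd, abs=1e-9)
    assert f["hrv_pnn50"] == pytest.approx(pnn50, abs=1e-9)
    assert f["hrv_sdsd"] == pytest.approx(sdsd, abs=1e-9)
    assert f["hrv_tri_index"] == pytest.approx(tri, abs=1e-9)


def test_too_few_intervals_rejected():
    with pytest.raises(InsufficientData):
        hrv_time_features([800.0] * 9)


# -- HRV frequency domain ----------------------------------------------------

def _sinusoid_beats(freq, amp, total=120.0, base=800.0):
    t, offs, rrs = 0.0, [], []
    while True:
        rr = (base + amp * math.sin(2 * math.pi * freq * t)) / 1000.0
        if t + rr > total:
            break
        t += rr
        offs.append(t)
        rrs.append(rr * 1000.0)
    return np.array(rrs), np.array(offs)


def test_constant_rr_spectrum_empty():
    rr, offs = _sinusoid_beats(0.25, 0.0)
    f = hrv_freq_features(rr, offs)
    assert f["hrv_lf_power"] == pytest.approx(0.0, abs=1e-12)
    assert f["hrv_hf_power"] == pytest.approx(0.0, abs=1e-12)
    assert math.isnan(f["hrv_lf_hf"])


@pytest.mark.parametrize("freq,band", [(0.25, "hf"), (0.10, "lf")])
def test_sinusoid_lands_in_its_band(freq, band):
    rr, offs = _sinusoid_beats(freq, 50.0)
    f = hrv_freq_features(rr, offs)
    other = "lf" if band == "hf" else "hf"
    assert f[f"hrv_{band}_power"] > 10 * f[f"hrv_{other}_power"]
    # peak within one frequency bin of the injected frequency
    n_grid = int(np.floor((offs[-1] - offs[0]) * 4.0)) + 1
    df = 4.0 / n_grid
    assert f[f"hrv_{band}_peak"] == pytest.approx(freq, abs=df + 1e-12)


def test_band_powers_satisfy_parseval(rng):
    from stresspipe.features import resample_tachogram

    rr, offs = _sinusoid_beats(0.25, 30.0)
    rr = rr + rng.normal(0, 10, len(rr))
    f = hrv_freq_features(rr, offs)
    _, x = resample_tachogram(rr, offs)
    total = f["hrv_vlf_power"] + f["hrv_lf_power"] + f["hrv_hf_power"]
    # bands cover [0, 0.4); remainder lives above 0.4 Hz, so compare against
    # the variance of the resampled tachogram low-passed into those bands
    from scipy.signal import periodogram

    xf, p = periodogram(x - x.mean(), fs=4.0, window="boxcar",
                        detrend=False, scaling="density")
    df = xf[1]
    expected = float(p[(xf > 0) & (xf < 0.4)].sum() * df)
    assert total == pytest.approx(expected, rel=1e-9)
    full = float(p[xf > 0].sum() * df)
    assert full == pytest.approx(float(np.var(x - x.mean())), rel=0.05)


def test_short_beat_span_rejected():
    rr, offs = _sinusoid_beats(0.25, 10.0, total=30.0)
    with pytest.raises(InsufficientData):
        hrv_freq_features(rr, offs)


# -- EDA components ----------------------------------------------------------

def test_constant_component():
    f = eda_component_features(np.full(480, 2.5))
    assert f["mean"] == 2.5
    assert f["sd"] == 0.0
    assert f["n_peaks"] == 0 and f["n_strong_peaks"] == 0
    assert f["p20"] == 2.5 and f["p80"] == 2.5 and f["quart_dev"] == 0.0


def test_three_injected_scrs_counted():
    from stresspipe.synthetic_data import _scr_pulse

    x = np.full(480, 0.0)
    t = np.arange(480) / 4.0
    for onset in (20.0, 60.0, 100.0):
        i0 = int(onset * 4)
        tau = t[i0:i0 + 60] - onset
        x[i0:i0 + 60] += 0.5 * _scr_pulse(tau, 0.75, 2.0)
    f = eda_component_features(x)
    assert f["n_peaks"] == 3
    assert f["n_strong_peaks"] == 3


def test_percentiles_match_sorting_oracle():
    xs = np.arange(1.0, 101.0)  # 1..100 µS
    f = eda_component_features(np.tile(xs, 2)[:200])
    base = np.tile(xs, 2)[:200].tolist()
    assert f["p20"] == pytest.approx(oracle_percentile(base, 20), abs=1e-9)
    assert f["p80"] == pytest.approx(oracle_percentile(base, 80), abs=1e-9)
    qd = (oracle_percentile(base, 75) - oracle_percentile(base, 25)) / 2
    assert f["quart_dev"] == pytest.approx(qd, abs=1e-9)


def test_excluded_epochs_do_not_contribute():
    x = np.full(480, 1.0)
    x[100] = 5.0  # spike inside an excluded region
    excluded = np.zeros(480, bool)
    excluded[80:120] = True
    f = eda_component_features(x, excluded)
    assert f["n_peaks"] == 0
    assert f["mean"] == 1.0


def test_all_excluded_rejected():
    with pytest.raises(InsufficientData):
        eda_component_features(np.full(480, 1.0), np.ones(480, bool))


# -- assembly ----------------------------------------------------------------

def _valid_window(rr_ms=None):
    if rr_ms is None:
        rng = np.random.default_rng(1)
        rr_ms = 800 + rng.normal(0, 30, 150)
    beat_s = np.cumsum(rr_ms) / 1000.0
    return WindowRecord(
        session_id="s", window_index=0, t_start=0.0, t_end=120.0,
        rr_ms=np.asarray(rr_ms), beat_s=beat_s,
        eda_uS=np.full(480, 2.0),
        rr_artifact_flags=np.zeros(len(rr_ms), bool),
        rr_corrected_ms=np.asarray(rr_ms),
        eda_artifact_epochs=np.zeros(24, bool),
        valid=True,
    )


def test_vector_has_27_features_in_schema_order():
    win = _valid_window()
    vec = build_feature_vector(win, decompose_eda(win.eda_uS))
    assert tuple(vec.keys()) == FEATURE_NAMES
    assert len(vec) == 27


def test_missing_eda_keeps_hrv():
    win = _valid_window()
    vec = build_feature_vector(win, None)
    assert all(np.isfinite(vec[n]) for n in HRV_FEATURES)
    assert all(math.isnan(vec[n]) for n in EDA_FEATURES)


def test_aggregate_examples():
    win = _valid_window()
    vec = build_feature_vector(win, decompose_eda(win.eda_uS))
    agg, n = aggregate_session([vec, vec])
    assert n == 2
    for name in FEATURE_NAMES:
        if math.isnan(vec[name]):
            assert math.isnan(agg[name])
        else:
            assert agg[name] == pytest.approx(vec[name])

    a = dict(vec, hrv_mean_rr=700.0)
    b = dict(vec, hrv_mean_rr=900.0)
    assert aggregate_session([a, b])[0]["hrv_mean_rr"] == pytest.approx(800.0)

    # per-feature missingness: EDA mean over remaining windows only
    c = dict(vec)
    for name in EDA_FEATURES:
        c[name] = float("nan")
    agg, _ = aggregate_session([vec, c])
    assert agg["eda_tonic_mean"] == pytest.approx(vec["eda_tonic_mean"])

    with pytest.raises(InsufficientData):
        aggregate_session([])


def test_hf_amplitude_monotonicity():
    """More respiratory-band modulation raises HF power and RMSSD."""
    from stresspipe.labeling import RELAXED
    from stresspipe.synthetic_data import SimParams, StateProfile, simulate_ibi

    profile = StateProfile(((120.0, RELAXED),))
    hf_powers, rmssds = [], []
    for amp in (10.0, 40.0):
        hp, rm = [], []
        for seed in range(10):
            params = SimParams(hf_amp_relaxed=amp, lf_amp_relaxed=0.0, rr_noise_sd=5.0)
            ibi = simulate_ibi(profile, params, seed)
            hp.append(hrv_freq_features(ibi.rr_s * 1000, ibi.offsets_s)["hrv_hf_power"])
            rm.append(hrv_time_features(ibi.rr_s * 1000)["hrv_rmssd"])
        hf_powers.append(np.mean(hp))
        rmssds.append(np.mean(rm))
    assert hf_powers[0] < hf_powers[1]
    assert rmssds[0] < rmssds[1]
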