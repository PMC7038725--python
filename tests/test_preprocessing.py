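"""Windowing, RR artifact rules, EDA screening and decomposition."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from stresspipe.config import PreprocessConfig
from stresspipe.io_e4 import ChannelSeries, IBISeries, RawRecording
from stresspipe.preprocessing import (
    InsufficientData,
    TooManyArtifacts,
    correct_rr,
    decompose_eda,
    detect_eda_artifacts,
    detect_rr_artifacts,
    reject_window,
    segment_windows,
)
from stresspipe.synthetic_data import inject_eda_artifact


def _recording(duration_s, beat_offsets=None):
    n_eda = int(duration_s * 4)
    if beat_offsets is None:
        beat_offsets = np.arange(0.8, duration_s + 1e-9, 0.8)
    rr = np.diff(np.concatenate([[0.0], beat_offsets]))
    return RawRecording(
        session_id="t", participant_id="p", environment="lab",
        eda=ChannelSeries(0.0, 4.0, np.full(n_eda, 2.0)),
        temp=ChannelSeries(0.0, 4.0, np.full(n_eda, 33.0)),
        acc=ChannelSeries(0.0, 32.0, np.tile([0.0, 0.0, 64.0], (int(duration_s * 32), 1))),
        ibi=IBISeries(0.0, np.asarray(beat_offsets), rr),
    )


class TestSegmentWindows:
    def test_exact_multiple(self):
        assert len(segment_windows(_recording(360.0))) == 3

    def test_trailing_partial_dropped(self):
        wins = segment_windows(_recording(350.0))
        assert len(wins) == 2
        assert wins[-1].t_end == 240.0

    def test_boundary_beat_goes_to_later_window(self):
        rec = _recording(240.0, beat_offsets=np.array([119.5, 120.0, 120.5]))
        wins = segment_windows(rec)
        assert wins[0].beat_s.tolist() == [119.5]
        assert wins[1].beat_s.tolist() == [120.0, 120.5]

    def test_too_short_returns_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert segment_windows(_recording(100.0)) == []
        assert any("no windows" in m for m in caplog.messages)

    def test_windowing_conserves_beats(self):
        rng = np.random.default_rng(3)
        offsets = np.cumsum(rng.uniform(0.6, 1.1, 700))
        rec = _recording(600.0, beat_offsets=offsets)
        wins = segment_windows(rec)
        covered = offsets[offsets < wins[-1].t_end]
        assert sum(len(w.beat_s) for w in wins) == len(covered)


class TestDetectRR:
    @pytest.mark.parametrize(
        "rr,expected",
        [
            # +25% flags; successor is compared with the last clean 800 -> clean
            ([800, 800, 1000, 800], [False, False, True, False]),
            ([800, 900], [False, False]),            # 12.5% below threshold
            ([800, 970], [False, True]),             # 21.25% above threshold
        ],
    )
    def test_rule_examples(self, rr, expected):
        assert detect_rr_artifacts(np.array(rr, float)).tolist() == expected

    def test_single_interval_warns_all_false(self, caplog):
        with caplog.at_level("WARNING"):
            flags = detect_rr_artifacts(np.array([800.0]))
        assert flags.tolist() == [False]

    def test_first_interval_never_flagged(self):
        flags = detect_rr_artifacts(np.array([2000.0, 800.0, 800.0]))
        assert not flags[0]


class TestCorrectRR:
    def test_no_flags_identity(self):
        rr = np.array([800.0, 820.0, 790.0])
        out = correct_rr(rr, np.zeros(3, bool))
        np.testing.assert_array_equal(out, rr)

    def test_interior_flag_matches_spline_oracle(self):
        rr = np.array([800.0, 820.0, 1200.0, 860.0, 880.0])
        flags = np.array([False, False, True, False, False])
        out = correct_rr(rr, flags)
        oracle = CubicSpline([0, 1, 3, 4], [800.0, 820.0, 860.0, 880.0])(2)
        assert out[2] == pytest.approx(float(oracle), abs=1e-9)
        assert 820.0 <= out[2] <= 860.0   # within the neighbors' range
        np.testing.assert_array_equal(out[~flags], rr[~flags])

    def test_edge_flag_clamped_to_valid_range(self):
        rr = np.array([2000.0, 800.0, 810.0, 820.0, 830.0])
        flags = np.array([True, False, False, False, False])
        out = correct_rr(rr, flags)
        assert 800.0 <= out[0] <= 830.0

    def test_majority_flagged_refused(self):
        rr = np.array([800.0] * 4)
        flags = np.array([True, True, True, False])
        with pytest.raises(TooManyArtifacts):
            correct_rr(rr, flags)

    def test_idempotent_under_redetection(self):
        """Correction never creates more flags than it removes."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            rr = 800 + rng.normal(0, 20, 60)
            idx = rng.choice(np.arange(1, 59), rng.integers(1, 5), replace=False)
            rr[idx] *= rng.choice([0.5, 1.6, 1.9])
            flags = detect_rr_artifacts(rr)
            corrected = correct_rr(rr, flags)
            assert detect_rr_artifacts(corrected).sum() <= flags.sum()


class TestRejectWindow:
    @pytest.mark.parametrize(
        "n_flagged,n,valid",
        [(6, 60, True), (7, 60, False), (0, 60, True)],
    )
    def test_ten_percent_boundary(self, n_flagged, n, valid):
        flags = np.zeros(n, bool)
        flags[:n_flagged] = True
        assert reject_window(flags) is valid

    def test_empty_invalid(self):
        assert reject_window(np.zeros(0, bool)) is False


class TestEDAArtifacts:
    def test_clean_signal_no_flags(self):
        rec = _recording(120.0)
        flags = detect_eda_artifacts(rec.eda.values, rec.acc.values)
        assert not flags.any()

    def test_step_with_acc_burst_flagged_without_burst_not(self):
        rec_burst = _recording(120.0)
        span = inject_eda_artifact(rec_burst, 40.0, 2.0, "step",
                                   with_acc_burst=True, seed=1)
        flags = detect_eda_artifacts(rec_burst.eda.values, rec_burst.acc.values)
        epoch = int(span[0] // 5)
        assert flags[epoch]

        rec_still = _recording(120.0)
        inject_eda_artifact(rec_still, 40.0, 2.0, "step",
                            with_acc_burst=False, seed=1)
        flags = detect_eda_artifacts(rec_still.eda.values, rec_still.acc.values)
        assert not flags[epoch]

    def test_below_floor_flagged(self):
        rec = _recording(60.0)
        rec.eda.values[10] = 0.0
        flags = detect_eda_artifacts(rec.eda.values, rec.acc.values)
        assert flags[0]

    def test_missing_acc_falls_back_with_warning(self, caplog):
        rec = _recording(60.0)
        with caplog.at_level("WARNING"):
            flags = detect_eda_artifacts(rec.eda.values, None)
        assert not flags.any()
        assert any("EDA-only" in m for m in caplog.messages)


class TestDecomposeEDA:
    def test_constant_input(self):
        d = decompose_eda(np.full(480, 3.0))
        np.testing.assert_allclose(d.tonic, 3.0, atol=1e-9)
        np.testing.assert_allclose(d.phasic, 0.0, atol=1e-9)

    def test_reconstruction_and_smoothness(self):
        from stresspipe.labeling import RELAXED
        from stresspipe.synthetic_data import SimParams, StateProfile, simulate_eda

        eda = simulate_eda(StateProfile(((120.0, RELAXED),)),
                           SimParams(scr_rate_relaxed=10.0), seed=2)
        d = decompose_eda(eda.values)
        np.testing.assert_allclose(d.tonic + d.phasic, eda.values, atol=1e-12)
        assert np.mean(np.abs(np.diff(d.tonic))) < np.mean(np.abs(np.diff(eda.values)))

    def test_pulse_peak_location_preserved(self):
        from stresspipe.synthetic_data import _scr_pulse

        x = np.full(480, 2.0)
        t = np.arange(480) / 4.0
        i0 = 120  # pulse onset at 30 s
        tau = t[i0:i0 + 60] - 30.0
        pulse = 0.5 * _scr_pulse(tau, 0.75, 2.0)
        x[i0:i0 + 60] += pulse
        d = decompose_eda(x)
        assert abs(int(np.argmax(d.phasic)) - (i0 + int(np.argmax(pulse)))) <= 1

    def test_short_input_rejected(self):
        with pytest.raises(InsufficientData):
            decompose_eda(np.full(40, 1.0))
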