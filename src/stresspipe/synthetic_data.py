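"""Synthetic multi-session study generator.

No public recording of the kind of cohort this pipeline targets exists,
so every downstream stage is exercised on synthetic sessions that carry
the signal structure the analysis assumes:

* RR intervals follow a sinusoid-plus-noise model,
  ``rr(t) = rr_mean(state) + lf_amp(state)·sin(2π·f_LF·t)
  + hf_amp(state)·sin(2π·f_HF·t) + N(0, σ)``, with beat times
  accumulating the RR durations.  Stress shortens the mean RR, damps the
  HF (respiratory/vagal) modulation and raises LF/HF — the canonical
  autonomic stress signature.  Band powers of this model are analytically
  known, which makes the spectral features verifiable in closed form.
* EDA is a state-dependent tonic level with a slow random walk plus
  Poisson-arriving skin-conductance responses (bi-exponential pulses,
  rise τ≈0.75 s, decay τ≈2 s); stress raises both the tonic level and
  the SCR rate.
* Motion/contact artifacts can be injected with an exact ground-truth
  mask: ectopic-like RR jumps (×0.5 or ×1.5–2.0) and EDA steps/spikes
  co-occurring with accelerometer bursts.
* Self-reports are drawn from state-consistent PSS-5 item distributions
  with a symmetric flip probability; daily-life flips default higher than
  lab flips, emulating the lower reliability of field self-reports.

A study consists of one lab session per participant (baseline → stressor
→ recovery, each phase context-labeled and self-reported) and several
daily-life sessions carrying self-reports only.  Durations are scaled
down from hour-long field sessions so the full evaluation matrix runs in
minutes; the latent per-session state is recorded as ground truth for
test oracles only and never feeds a pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .io_e4 import ChannelSeries, IBISeries, RawRecording
from .labeling import PSSResponse, RELAXED, STRESSED, SessionLabels

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class StateProfile:
    """Ordered (duration_s, state) segments of one session."""

    segments: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile needs at least one segment")
        for dur, state in self.segments:
            if dur <= 0:
                raise ValueError(f"segment duration must be > 0, got {dur}")
            if state not in (RELAXED, STRESSED):
                raise ValueError(f"unknown state {state!r}")

    @property
    def total_s(self) -> float:
        return sum(d for d, _ in self.segments)

    def state_at(self, t: float) -> str:
        acc = 0.0
        for dur, state in self.segments:
            acc += dur
            if t < acc:
                return state
        return self.segments[-1][1]


@dataclass(frozen=True)
class SimParams:
    """Signal, artifact and label-noise parameters of the generator.

    Defaults encode a strong but physiologically plausible stress
    contrast: ~150 ms RR shortening, HF modulation cut to about a third,
    a doubled tonic skin-conductance level and a fourfold SCR rate.
    """

    rr_mean_relaxed: float = 850.0    # ms
    rr_mean_stressed: float = 700.0   # ms
    lf_amp_relaxed: float = 30.0      # ms
    lf_amp_stressed: float = 40.0
    hf_amp_relaxed: float = 40.0
    hf_amp_stressed: float = 15.0
    lf_freq: float = 0.10             # Hz
    hf_freq: float = 0.25             # Hz
    rr_noise_sd: float = 15.0         # ms
    scr_rate_relaxed: float = 2.0     # events/min
    scr_rate_stressed: float = 8.0
    scr_amp_range: tuple[float, float] = (0.1, 0.6)  # µS
    scr_rise_tau: float = 0.75        # s
    scr_decay_tau: float = 2.0        # s
    tonic_level_relaxed: float = 2.0  # µS
    tonic_level_stressed: float = 4.0
    tonic_walk_sd: float = 0.003      # µS per 4 Hz sample
    artifact_rate_rr: float = 2.0     # per 100 beats
    artifact_rate_eda: float = 0.5    # per minute
    selfreport_flip_p_lab: float = 0.05
    selfreport_flip_p_daily: float = 0.20

    def __post_init__(self) -> None:
        for name in ("rr_mean_relaxed", "rr_mean_stressed"):
            v = getattr(self, name)
            if not 300 < v < 1500:
                raise ValueError(f"{name}={v} outside plausible (300, 1500) ms")
        if not 0.04 < self.lf_freq < 0.15:
            raise ValueError("lf_freq must lie inside the LF band (0.04, 0.15) Hz")
        if not 0.15 < self.hf_freq < 0.4:
            raise ValueError("hf_freq must lie inside the HF band (0.15, 0.4) Hz")
        for name in ("selfreport_flip_p_lab", "selfreport_flip_p_daily"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name}={v} outside [0, 0.5)")

    def rr_mean(self, state: str) -> float:
        return self.rr_mean_stressed if state == STRESSED else self.rr_mean_relaxed

    def lf_amp(self, state: str) -> float:
        return self.lf_amp_stressed if state == STRESSED else self.lf_amp_relaxed

    def hf_amp(self, state: str) -> float:
        return self.hf_amp_stressed if state == STRESSED else self.hf_amp_relaxed

    def scr_rate(self, state: str) -> float:
        return self.scr_rate_stressed if state == STRESSED else self.scr_rate_relaxed

    def tonic_level(self, state: str) -> float:
        return self.tonic_level_stressed if state == STRESSED else self.tonic_level_relaxed


LAB_PHASES: tuple[tuple[str, str], ...] = (
    ("baseline", RELAXED), ("stress", STRESSED), ("recovery", RELAXED),
)


@dataclass(frozen=True)
class StudyDesign:
    """Scaled-down study layout: one lab session + daily EMA sessions each."""

    n_participants: int = 12
    lab_phase_s: float = 240.0
    n_daily_sessions: int = 4
    daily_session_s: float = 600.0
    relaxed_share_daily: float = 0.73
    params: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")


@dataclass
class SessionUnit:
    """One labeled analysis unit: a lab phase or a whole daily session."""

    session_id: str
    participant_id: str
    environment: str
    phase: Optional[str]          # lab phase name, None for daily
    t0: float
    t1: float
    labels: SessionLabels
    truth_state: str              # latent state; test oracle only


@dataclass
class ArtifactMask:
    """Exact positions of injected artifacts (ground truth for detectors)."""

    rr_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    eda_epochs: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class StudyDataset:
    recordings: list[RawRecording]
    units: list[SessionUnit]
    artifact_truth: dict[str, ArtifactMask] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# signal generators

def simulate_ibi(profile: StateProfile, params: SimParams, seed: RngLike) -> IBISeries:
    """Beat-by-beat RR generation under the sinusoid-plus-noise model."""
    rng = _rng(seed)
    for dur, state in profile.segments:
        if dur < 2 * params.rr_mean(state) / 1000.0:
            raise ValueError(f"segment of {dur} s holds fewer than 2 beats")
    total = profile.total_s
    t = 0.0
    offsets, rrs = [], []
    while True:
        state = profile.state_at(t)
        rr_ms = (
            params.rr_mean(state)
            + params.lf_amp(state) * np.sin(2 * np.pi * params.lf_freq * t)
            + params.hf_amp(state) * np.sin(2 * np.pi * params.hf_freq * t)
            + (rng.normal(0.0, params.rr_noise_sd) if params.rr_noise_sd > 0 else 0.0)
        )
        rr_s = float(np.clip(rr_ms / 1000.0, 0.2, 3.0))
        if t + rr_s > total + 1e-9:
            break
        t += rr_s
        offsets.append(t)
        rrs.append(rr_s)
    return IBISeries(start_time=0.0, offsets_s=np.array(offsets), rr_s=np.array(rrs))


def _scr_pulse(tau_grid: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Bi-exponential SCR kinetics, normalized to unit peak amplitude."""
    shape = np.exp(-tau_grid / decay) - np.exp(-tau_grid / rise)
    t_peak = np.log(decay / rise) * rise * decay / (decay - rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return shape / peak


def simulate_eda(
    profile: StateProfile,
    params: SimParams,
    seed: RngLike,
    rate_hz: float = 4.0,
    return_truth: bool = False,
):
    """Tonic level + random walk + Poisson SCR train, sampled at 4 Hz.

    With ``return_truth`` the injected SCR event list [(time_s, amp_uS)]
    is returned alongside the series, for test oracles.
    """
    rng = _rng(seed)
    n = int(round(profile.total_s * rate_hz))
    t_grid = np.arange(n) / rate_hz
    tonic = np.array([params.tonic_level(profile.state_at(t)) for t in t_grid])
    if params.tonic_walk_sd > 0:
        tonic = tonic + np.cumsum(rng.normal(0.0, params.tonic_walk_sd, n))

    events: list[tuple[float, float]] = []
    out = tonic.copy()
    offset = 0.0
    for dur, state in profile.segments:
        rate_per_s = params.scr_rate(state) / 60.0
        k = rng.poisson(rate_per_s * dur)
        times = np.sort(rng.uniform(0.0, dur, k)) + offset
        amps = rng.uniform(*params.scr_amp_range, k)
        events.extend(zip(times.tolist(), amps.tolist()))
        offset += dur
    for te, amp in events:
        i0 = int(np.ceil(te * rate_hz))
        i1 = min(n, i0 + int(15 * rate_hz))  # pulse support: 15 s
        if i0 >= n:
            continue
        tau = t_grid[i0:i1] - te
        out[i0:i1] += amp * _scr_pulse(tau, params.scr_rise_tau, params.scr_decay_tau)

    out = np.maximum(out, 0.011)  # conductance stays positive, above the floor
    series = ChannelSeries(start_time=0.0, sample_rate=rate_hz, values=out)
    return (series, events) if return_truth else series


def simulate_acc(duration_s: float, seed: RngLike, rate_hz: float = 32.0) -> ChannelSeries:
    """Still-wrist accelerometer: gravity on z plus small jitter (1/64 g units)."""
    rng = _rng(seed)
    n = int(round(duration_s * rate_hz))
    vals = np.column_stack([
        rng.normal(0.0, 1.0, n),
        rng.normal(0.0, 1.0, n),
        rng.normal(64.0, 1.0, n),
    ])
    return ChannelSeries(start_time=0.0, sample_rate=rate_hz, values=vals)


def simulate_temp(duration_s: float, seed: RngLike, rate_hz: float = 4.0) -> ChannelSeries:
    """Skin temperature around 33 °C with slow drift."""
    rng = _rng(seed)
    n = int(round(duration_s * rate_hz))
    vals = 33.0 + np.cumsum(rng.normal(0.0, 0.002, n))
    return ChannelSeries(start_time=0.0, sample_rate=rate_hz, values=vals)


# ---------------------------------------------------------------------------
# artifacts

def inject_eda_artifact(
    recording: RawRecording,
    t0: float,
    magnitude_uS: float = 2.0,
    kind: str = "step",
    with_acc_burst: bool = True,
    burst_sd_g: float = 0.3,
    epoch_s: float = 5.0,
    seed: RngLike = 0,
) -> tuple[float, float]:
    """Inject one EDA artifact epoch (in place); returns its (t0, t1) span.

    ``step`` raises the signal by ``magnitude_uS`` for the rest of the
    epoch; ``spike`` adds a one-second triangular transient.  With
    ``with_acc_burst`` the accelerometer gets a matching motion burst, so
    the default screen's motion rule can fire.
    """
    rng = _rng(seed)
    eda = recording.eda
    rate = eda.sample_rate or 4.0
    i0 = int(round(t0 * rate))
    i1 = min(len(eda), i0 + int(round(epoch_s * rate)))
    if kind == "step":
        eda.values[i0:i1] += magnitude_uS
    elif kind == "spike":
        width = max(2, int(rate))
        ramp = np.concatenate([np.linspace(0, 1, width // 2, endpoint=False),
                               np.linspace(1, 0, width - width // 2)])
        j1 = min(i1, i0 + width)
        eda.values[i0:j1] += magnitude_uS * ramp[: j1 - i0]
    else:
        raise ValueError(f"unknown EDA artifact kind {kind!r}")
    if with_acc_burst and len(recording.acc):
        arate = recording.acc.sample_rate or 32.0
        a0 = int(round(t0 * arate))
        a1 = min(len(recording.acc), a0 + int(round(epoch_s * arate)))
        recording.acc.values[a0:a1] += rng.normal(0.0, burst_sd_g * 64.0, (a1 - a0, 3))
    return (t0, t0 + epoch_s)


def inject_artifacts(
    recording: RawRecording, params: SimParams, seed: RngLike
) -> tuple[RawRecording, ArtifactMask]:
    """Return a copy of the recording with RR and EDA artifacts injected.

    RR artifacts scale isolated beats by 0.5 or by 1.5–2.0 (ectopic-like
    jumps well past the 20% screening rule); beat times are rebuilt by
    re-accumulating the altered durations.  EDA artifacts are steps or
    spikes placed on 5-s epoch boundaries, each with a co-occurring
    accelerometer burst.  The mask records the exact injected positions.
    """
    rng = _rng(seed)
    ibi = IBISeries(recording.ibi.start_time,
                    recording.ibi.offsets_s.copy(), recording.ibi.rr_s.copy())
    eda = ChannelSeries(recording.eda.start_time, recording.eda.sample_rate,
                        recording.eda.values.copy())
    acc = ChannelSeries(recording.acc.start_time, recording.acc.sample_rate,
                        recording.acc.values.copy())
    out = replace(recording, ibi=ibi, eda=eda, acc=acc)
    mask = ArtifactMask()

    n_beats = len(ibi)
    n_rr = int(round(params.artifact_rate_rr / 100.0 * n_beats))
    if n_rr > 0 and n_beats > 2:
        chosen: list[int] = []
        for cand in rng.permutation(np.arange(1, n_beats)):
            if all(abs(cand - c) > 1 for c in chosen):
                chosen.append(int(cand))
            if len(chosen) == n_rr:
                break
        chosen_arr = np.array(sorted(chosen), dtype=int)
        rr = ibi.rr_s.copy()
        for i in chosen_arr:
            factor = 0.5 if rng.random() < 0.5 else rng.uniform(1.5, 2.0)
            rr[i] *= factor
        offsets = np.empty_like(rr)
        offsets[0] = ibi.offsets_s[0]
        offsets[1:] = offsets[0] + np.cumsum(rr[1:])
        out.ibi = IBISeries(ibi.start_time, offsets, rr)
        mask.rr_indices = chosen_arr

    minutes = out.duration_s / 60.0
    n_eda = int(round(params.artifact_rate_eda * minutes))
    if n_eda > 0 and len(eda) > 0:
        n_epochs = int(out.duration_s // 5.0)
        starts = rng.choice(n_epochs, size=min(n_eda, n_epochs), replace=False) * 5.0
        for t0 in np.sort(starts):
            kind = "step" if rng.random() < 0.5 else "spike"
            span = inject_eda_artifact(
                out, float(t0), magnitude_uS=rng.uniform(1.5, 3.0), kind=kind,
                with_acc_burst=True, seed=rng,
            )
            mask.eda_epochs.append(span)
    return out, mask


# ---------------------------------------------------------------------------
# labels and study assembly

def simulate_selfreport(latent_state: str, flip_p: float, seed: RngLike) -> PSSResponse:
    """Draw a PSS-5 response consistent with the latent state, or — with
    probability ``flip_p`` — with the opposite state.

    State-consistent distributions are constructed so the binarized score
    always matches the drawn state: relaxed responses score 5–12 (< 15),
    stressed responses 20–30 (>= 15).
    """
    if not 0 <= flip_p < 0.5:
        raise ValueError(f"flip_p={flip_p} outside [0, 0.5)")
    rng = _rng(seed)
    state = latent_state
    if rng.random() < flip_p:
        state = RELAXED if state == STRESSED else STRESSED
    if state == STRESSED:
        h, c = rng.integers(1, 4, 2)
        a, s, f = rng.integers(4, 7, 3)
    else:
        h, c = rng.integers(4, 7, 2)
        a, s, f = rng.integers(1, 3, 3)
    return PSSResponse(int(h), int(c), int(a), int(s), int(f))


def _simulate_recording(
    session_id: str,
    participant_id: str,
    environment: str,
    profile: StateProfile,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[RawRecording, ArtifactMask]:
    rec = RawRecording(
        session_id=session_id,
        participant_id=participant_id,
        environment=environment,
        eda=simulate_eda(profile, params, rng),
        temp=simulate_temp(profile.total_s, rng),
        acc=simulate_acc(profile.total_s, rng),
        ibi=simulate_ibi(profile, params, rng),
    )
    if params.artifact_rate_rr > 0 or params.artifact_rate_eda > 0:
        return inject_artifacts(rec, params, rng)
    return rec, ArtifactMask()


def simulate_study(design: StudyDesign, seed: RngLike) -> StudyDataset:
    """Generate a full study: lab + daily sessions, labels, artifact truth.

    Every lab phase is one analysis unit carrying both the known-context
    phase and a simulated self-report (lab flip probability); every daily
    session is one unit with a self-report only (daily flip probability).
    Daily latent states are stressed for an exact ``1 − relaxed_share``
    fraction of sessions, randomly placed across participants.
    """
    rng = _rng(seed)
    params = design.params
    recordings: list[RawRecording] = []
    units: list[SessionUnit] = []
    truth: dict[str, ArtifactMask] = {}

    total_daily = design.n_participants * design.n_daily_sessions
    n_stressed = int(round((1.0 - design.relaxed_share_daily) * total_daily))
    stressed_slots = set(rng.permutation(total_daily)[:n_stressed].tolist())

    for p in range(design.n_participants):
        pid = f"P{p + 1:02d}"
        sid = f"{pid}_lab"
        profile = StateProfile(tuple((design.lab_phase_s, st) for _, st in LAB_PHASES))
        rec, mask = _simulate_recording(sid, pid, "lab", profile, params, rng)
        recordings.append(rec)
        truth[sid] = mask
        for i, (phase, state) in enumerate(LAB_PHASES):
            pss = simulate_selfreport(state, params.selfreport_flip_p_lab, rng)
            units.append(SessionUnit(
                session_id=sid, participant_id=pid, environment="lab", phase=phase,
                t0=i * design.lab_phase_s, t1=(i + 1) * design.lab_phase_s,
                labels=SessionLabels(context=phase, pss=pss),
                truth_state=state,
            ))

        for d in range(design.n_daily_sessions):
            slot = p * design.n_daily_sessions + d
            state = STRESSED if slot in stressed_slots else RELAXED
            sid = f"{pid}_daily{d + 1}"
            profile = StateProfile(((design.daily_session_s, state),))
            rec, mask = _simulate_recording(sid, pid, "daily", profile, params, rng)
            recordings.append(rec)
            truth[sid] = mask
            pss = simulate_selfreport(state, params.selfreport_flip_p_daily, rng)
            units.append(SessionUnit(
                session_id=sid, participant_id=pid, environment="daily", phase=None,
                t0=0.0, t1=design.daily_session_s,
                labels=SessionLabels(context=None, pss=pss),
                truth_state=state,
            ))

    return StudyDataset(recordings=recordings, units=units, artifact_truth=truth)
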