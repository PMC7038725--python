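"""End-to-end session processing: raw recording → session feature records.

Glue between preprocessing, feature extraction and aggregation.  Each
labeled analysis unit (a lab protocol phase or a whole daily session)
collects the valid 2-minute windows that fall entirely inside its span,
and their feature vectors are averaged into one :class:`SessionRecord`.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .config import DEFAULT_CONFIG, PipelineConfig
from .features import aggregate_session, build_feature_vector
from .io_e4 import RawRecording, SessionRecord
from .preprocessing import (
    InsufficientData,
    WindowRecord,
    decompose_eda,
    preprocess_window,
    segment_windows,
)
from .synthetic_data import SessionUnit, StudyDataset

logger = logging.getLogger(__name__)


def process_recording(
    recording: RawRecording, cfg: PipelineConfig = DEFAULT_CONFIG
) -> list[tuple[WindowRecord, Optional[dict[str, float]]]]:
    """Window, clean and featurize one recording.

    Returns (window, feature-vector) pairs; the vector is None for
    invalid windows.
    """
    out = []
    eda_rate = recording.eda.sample_rate or 4.0
    for win in segment_windows(recording, cfg.preprocess.window_s):
        preprocess_window(win, recording, cfg.preprocess)
        vec = None
        if win.valid:
            decomp = None
            if len(win.eda_uS) >= 30 * eda_rate:
                decomp = decompose_eda(win.eda_uS, cfg.preprocess, eda_rate)
            vec = build_feature_vector(win, decomp, cfg.features, eda_rate)
        out.append((win, vec))
    return out


def extract_session_records(
    study: StudyDataset, cfg: PipelineConfig = DEFAULT_CONFIG
) -> list[SessionRecord]:
    """Run the full pipeline over a study and aggregate per analysis unit.

    Units with no valid window are dropped with a logged reason.
    """
    by_session: dict[str, list[tuple[WindowRecord, Optional[dict]]]] = {}
    for rec in study.recordings:
        by_session[rec.session_id] = process_recording(rec, cfg)
    rec_by_id = {r.session_id: r for r in study.recordings}

    records: list[SessionRecord] = []
    for unit in study.units:
        pairs = by_session.get(unit.session_id, [])
        vectors = [
            vec for win, vec in pairs
            if vec is not None and win.t_start >= unit.t0 - 1e-9 and win.t_end <= unit.t1 + 1e-9
        ]
        if not vectors:
            logger.warning(
                "unit %s/%s dropped: no valid windows in [%s, %s)",
                unit.session_id, unit.phase, unit.t0, unit.t1,
            )
            continue
        features, n_windows = aggregate_session(vectors)
        rec = rec_by_id[unit.session_id]
        records.append(SessionRecord(
            session_id=unit.session_id,
            participant_id=rec.participant_id,
            environment=unit.environment,
            phase=unit.phase,
            n_windows=n_windows,
            features=features,
            labels=unit.labels,
        ))
    return records


def extract_from_recordings(
    recordings: Sequence[RawRecording], cfg: PipelineConfig = DEFAULT_CONFIG
) -> list[SessionRecord]:
    """Whole-recording extraction (one unit per session, no label source)."""
    from .labeling import SessionLabels

    records = []
    for rec in recordings:
        vectors = [v for _, v in process_recording(rec, cfg) if v is not None]
        if not vectors:
            logger.warning("session %s dropped: no valid windows", rec.session_id)
            continue
        features, n_windows = aggregate_session(vectors)
        records.append(SessionRecord(
            session_id=rec.session_id,
            participant_id=rec.participant_id,
            environment=rec.environment,
            phase=None,
            n_windows=n_windows,
            features=features,
            labels=SessionLabels(),
        ))
    return records
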