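"""Reading and writing Empatica-E4-dialect session exports and feature tables.

An E4 session directory holds one CSV per channel.  Sampled channels
(EDA.csv, TEMP.csv, ACC.csv) start with a UNIX timestamp row, then a
sample-rate row, then samples (ACC has three columns, one per axis, in
units of 1/64 g).  IBI.csv starts with the timestamp and the literal
header token ``IBI``, followed by ``offset,duration`` rows in seconds.

Feature tables are plain CSV with one row per analysis unit (lab phase
or daily session), metadata and label columns, and the 27-feature
schema of :mod:`stresspipe.schema`.  Absent labels are written as the
reserved token ``NA`` — never an empty cell.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labeling import MISSING_TOKEN, PSSResponse, SessionLabels
from .schema import FEATURE_NAMES

logger = logging.getLogger(__name__)

ENVIRONMENTS = ("lab", "daily")


class E4FormatError(ValueError):
    """Malformed E4 export file (names the file and line)."""


class ValidationError(ValueError):
    """Structurally valid file whose contents violate an invariant."""


class SchemaError(ValueError):
    """Feature-table columns do not match the 27-feature schema."""


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ChannelSeries:
    """Uniformly sampled channel: start time (UNIX s), rate (Hz), samples.

    ``values`` is 1-D for single-axis channels and (n, 3) for the
    accelerometer (axes x, y, z in 1/64 g).
    """

    start_time: float
    sample_rate: Optional[float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate is not None and self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("channel contains non-finite samples")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        if self.sample_rate is None or len(self) == 0:
            return 0.0
        return len(self) / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample offsets in seconds relative to session start."""
        if self.sample_rate is None:
            return np.empty(0)
        return np.arange(len(self)) / self.sample_rate


@dataclass
class IBISeries:
    """Interbeat-interval event channel.

    ``offsets_s`` are beat times in seconds since ``start_time``;
    ``rr_s`` the preceding interbeat duration of each beat.
    """

    start_time: float
    offsets_s: np.ndarray
    rr_s: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_s = np.asarray(self.offsets_s, dtype=float)
        self.rr_s = np.asarray(self.rr_s, dtype=float)
        if self.offsets_s.shape != self.rr_s.shape:
            raise ValidationError("IBI offsets and durations differ in length")
        if len(self.offsets_s) and np.any(np.diff(self.offsets_s) <= 0):
            raise ValidationError("IBI offsets must be strictly increasing")
        if len(self.rr_s) and np.any(self.rr_s <= 0):
            raise ValidationError("IBI durations must be positive")

    def __len__(self) -> int:
        return len(self.offsets_s)

    @property
    def duration_s(self) -> float:
        return float(self.offsets_s[-1]) if len(self) else 0.0


@dataclass
class RawRecording:
    """One session's multi-channel export plus identity and environment."""

    session_id: str
    participant_id: str
    environment: str
    eda: ChannelSeries
    temp: ChannelSeries
    acc: ChannelSeries
    ibi: IBISeries

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValidationError(
                f"environment must be one of {ENVIRONMENTS}, got {self.environment!r}"
            )

    @property
    def duration_s(self) -> float:
        return max(
            self.eda.duration_s, self.temp.duration_s,
            self.acc.duration_s, self.ibi.duration_s,
        )


@dataclass
class SessionRecord:
    """Aggregated session-level feature vector with labels.

    ``features`` maps every schema name to a float (NaN when the modality
    was unavailable for the whole unit); ``phase`` is set for lab protocol
    phases and None for daily sessions.
    """

    session_id: str
    participant_id: str
    environment: str
    phase: Optional[str]
    n_windows: int
    features: dict[str, float]
    labels: SessionLabels = field(default_factory=SessionLabels)

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.features]
        extra = [n for n in self.features if n not in FEATURE_NAMES]
        if missing or extra:
            raise SchemaError(
                f"feature schema mismatch; missing={missing} unexpected={extra}"
            )


# ---------------------------------------------------------------------------
# E4 session directory I/O

_SAMPLED_FILES = {"eda": "EDA.csv", "temp": "TEMP.csv", "acc": "ACC.csv"}


def _read_sampled(path: Path, n_cols: int) -> ChannelSeries:
    lines = path.read_text().strip().splitlines()
    if len(lines) < 2:
        raise E4FormatError(f"{path.name}: expected timestamp and rate header rows")

    def parse_row(line: str, lineno: int, what: str) -> list[float]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != n_cols:
            raise E4FormatError(
                f"{path.name} line {lineno}: expected {n_cols} column(s) for {what}, "
                f"got {len(parts)}"
            )
        try:
            return [float(p) for p in parts]
        except ValueError as exc:
            raise E4FormatError(f"{path.name} line {lineno}: {exc}") from None

    start = parse_row(lines[0], 1, "start timestamp")[0]
    rate = parse_row(lines[1], 2, "sample rate")[0]
    if rate <= 0:
        raise E4FormatError(f"{path.name} line 2: sample rate must be positive, got {rate}")
    samples = [parse_row(line, i + 3, "sample") for i, line in enumerate(lines[2:])]
    values = np.asarray(samples, dtype=float)
    if n_cols == 1:
        values = values.reshape(-1)
    return ChannelSeries(start_time=start, sample_rate=rate, values=values)


def _read_ibi(path: Path) -> IBISeries:
    lines = path.read_text().strip().splitlines()
    if not lines:
        raise E4FormatError(f"{path.name}: empty file")
    header = [p.strip() for p in lines[0].split(",")]
    if len(header) != 2 or header[1] != "IBI":
        raise E4FormatError(
            f"{path.name} line 1: expected '<timestamp>,IBI' header, got {lines[0]!r}"
        )
    try:
        start = float(header[0])
    except ValueError:
        raise E4FormatError(f"{path.name} line 1: bad timestamp {header[0]!r}") from None
    offs, durs = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise E4FormatError(f"{path.name} line {i}: expected 'offset,duration'")
        try:
            offs.append(float(parts[0]))
            durs.append(float(parts[1]))
        except ValueError as exc:
            raise E4FormatError(f"{path.name} line {i}: {exc}") from None
    return IBISeries(start_time=start, offsets_s=np.array(offs), rr_s=np.array(durs))


def _empty_channel(n_axes: int = 1) -> ChannelSeries:
    shape = (0,) if n_axes == 1 else (0, n_axes)
    return ChannelSeries(start_time=0.0, sample_rate=None, values=np.empty(shape))


def read_e4_session(
    directory: str | Path,
    *,
    session_id: Optional[str] = None,
    participant_id: Optional[str] = None,
    environment: Optional[str] = None,
) -> RawRecording:
    """Read one E4 session directory into a :class:`RawRecording`.

    A ``meta.json`` file in the directory (as written by
    :func:`write_e4_session`) supplies session/participant/environment
    metadata; keyword arguments override it.  Missing channel files yield
    empty series with a logged warning.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a session directory: {directory}")

    meta: dict = {}
    meta_path = directory / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())

    channels: dict[str, ChannelSeries] = {}
    for key, fname in _SAMPLED_FILES.items():
        fpath = directory / fname
        n_cols = 3 if key == "acc" else 1
        if fpath.exists():
            channels[key] = _read_sampled(fpath, n_cols)
        else:
            logger.warning("%s: missing %s, using empty channel", directory.name, fname)
            channels[key] = _empty_channel(n_cols)

    ibi_path = directory / "IBI.csv"
    if ibi_path.exists():
        ibi = _read_ibi(ibi_path)
    else:
        logger.warning("%s: missing IBI.csv, using empty channel", directory.name)
        ibi = IBISeries(start_time=0.0, offsets_s=np.empty(0), rr_s=np.empty(0))

    return RawRecording(
        session_id=session_id or meta.get("session_id", directory.name),
        participant_id=participant_id or meta.get("participant_id", "unknown"),
        environment=environment or meta.get("environment", "daily"),
        eda=channels["eda"],
        temp=channels["temp"],
        acc=channels["acc"],
        ibi=ibi,
    )


def write_e4_session(recording: RawRecording, directory: str | Path) -> Path:
    """Write a recording as an E4-dialect session directory (inverse of reader)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def fmt(v: float) -> str:
        return repr(float(v))

    for key, fname in _SAMPLED_FILES.items():
        ch: ChannelSeries = getattr(recording, key)
        if len(ch) == 0:
            continue
        n_cols = 3 if key == "acc" else 1
        rows = [",".join([fmt(ch.start_time)] * n_cols), ",".join([fmt(ch.sample_rate)] * n_cols)]
        vals = ch.values.reshape(len(ch), -1)
        rows += [",".join(fmt(v) for v in row) for row in vals]
        (directory / fname).write_text("\n".join(rows) + "\n")

    if len(recording.ibi):
        rows = [f"{fmt(recording.ibi.start_time)},IBI"]
        rows += [
            f"{fmt(o)},{fmt(d)}"
            for o, d in zip(recording.ibi.offsets_s, recording.ibi.rr_s)
        ]
        (directory / "IBI.csv").write_text("\n".join(rows) + "\n")

    (directory / "meta.json").write_text(json.dumps({
        "session_id": recording.session_id,
        "participant_id": recording.participant_id,
        "environment": recording.environment,
    }, indent=1))
    return directory


# ---------------------------------------------------------------------------
# feature tables

_META_COLUMNS = ("session_id", "participant_id", "environment", "phase", "n_windows")
_LABEL_COLUMNS = ("context", "H", "C", "A", "S", "F")


def write_feature_table(records: Sequence[SessionRecord], path: str | Path) -> Path:
    """Write session records as one CSV row each; lossless for round-trip.

    Floats are written with 17 significant digits so the read-back value is
    bit-identical; absent labels use the reserved ``NA`` token.
    """
    path = Path(path)
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "session_id": rec.session_id,
            "participant_id": rec.participant_id,
            "environment": rec.environment,
            "phase": rec.phase if rec.phase is not None else MISSING_TOKEN,
            "n_windows": rec.n_windows,
            "context": rec.labels.context if rec.labels.context is not None else MISSING_TOKEN,
        }
        if rec.labels.pss is not None:
            for item, v in zip("HCASF", rec.labels.pss.items()):
                row[item] = v
        else:
            for item in "HCASF":
                row[item] = MISSING_TOKEN
        for name in FEATURE_NAMES:
            v = rec.features[name]
            row[name] = MISSING_TOKEN if (v is None or (isinstance(v, float) and math.isnan(v))) else repr(float(v))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_META_COLUMNS[:4]) + ["n_windows", "context"]
                      + list("HCASF") + list(FEATURE_NAMES))
    df.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> list[SessionRecord]:
    """Read a feature table back into session records.

    Raises :class:`SchemaError` listing offending columns when the file does
    not carry exactly the 27-feature schema plus metadata/label columns.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = set(_META_COLUMNS) | set(_LABEL_COLUMNS) | set(FEATURE_NAMES)
    have = set(df.columns)
    missing = sorted(expected - have)
    extra = sorted(have - expected)
    if missing or extra:
        raise SchemaError(f"feature table schema mismatch; missing={missing} unexpected={extra}")

    records: list[SessionRecord] = []
    for _, row in df.iterrows():
        items = [row[i] for i in "HCASF"]
        if all(i != MISSING_TOKEN for i in items):
            pss = PSSResponse(*(int(i) for i in items))
        else:
            pss = None
        labels = SessionLabels(
            context=None if row["context"] == MISSING_TOKEN else row["context"],
            pss=pss,
        )
        features = {
            name: (float("nan") if row[name] == MISSING_TOKEN else float(row[name]))
            for name in FEATURE_NAMES
        }
        records.append(SessionRecord(
            session_id=row["session_id"],
            participant_id=row["participant_id"],
            environment=row["environment"],
            phase=None if row["phase"] == MISSING_TOKEN else row["phase"],
            n_windows=int(row["n_windows"]),
            features=features,
            labels=labels,
        ))
    return records


def records_to_frame(records: Sequence[SessionRecord]) -> pd.DataFrame:
    """Tabular view of session records: metadata, derived labels, features."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "session_id": rec.session_id,
            "participant_id": rec.participant_id,
            "environment": rec.environment,
            "phase": rec.phase,
            "n_windows": rec.n_windows,
            "pss_score": rec.labels.pss_score,
            "stress_selfreport": rec.labels.stress_binary_selfreport,
            "stress_context": rec.labels.stress_binary_context,
        }
        row.update({name: rec.features[name] for name in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
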