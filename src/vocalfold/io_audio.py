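"""Audio input, event segmentation and squeal labels.

Recordings are 16-bit PCM WAV files (44.1 kHz stereo in the original study
protocol).  Raw audio is split into candidate acoustic events with a
moving-average volume rule; a candidate qualifies as a squeal when it lasts
at least 0.5 s.  Human-audited labels (pig, recording date, days relative to
surgery) are carried in delimited text files and are the unit of analysis
downstream.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "AcousticEvent",
    "SquealRecord",
    "RecoveryPhase",
    "PHASES",
    "phase_of_day",
    "read_recording",
    "write_recording",
    "moving_average_volume",
    "segment_events",
    "validate_squeal",
    "load_labels",
    "write_labels",
]

#: 16-bit PCM amplitude bounds.
PCM16_MIN, PCM16_MAX = -32768, 32767


@dataclass(frozen=True)
class AudioRecording:
    """Mono audio on the 16-bit integer amplitude scale.

    Samples are stored as float64 but keep the raw PCM scale
    (−32768..32767) so that amplitude-threshold rules stated on that scale
    apply directly.
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioRecording holds mono audio (1-D samples)")
        if samples.size == 0:
            raise ValueError("empty recording")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def slice(self, event: "AcousticEvent") -> np.ndarray:
        if not (0 <= event.start_sample < event.end_sample <= self.samples.size):
            raise IndexError(
                f"event [{event.start_sample}, {event.end_sample}) outside "
                f"recording of length {self.samples.size}"
            )
        return self.samples[event.start_sample : event.end_sample]


@dataclass(frozen=True)
class AcousticEvent:
    """Half-open sample interval [start_sample, end_sample) in a recording."""

    recording_id: str
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_sample < self.end_sample):
            raise ValueError("require 0 <= start_sample < end_sample")

    def duration_s(self, sample_rate: int) -> float:
        return (self.end_sample - self.start_sample) / sample_rate


@dataclass(frozen=True)
class SquealRecord:
    """A labeled squeal: an event plus animal / timeline metadata."""

    event: AcousticEvent
    pig_id: str
    recording_date: _dt.date
    days_from_surgery: int
    rater_id: str | None = None


@dataclass(frozen=True)
class RecoveryPhase:
    """A named window of days relative to surgery (inclusive bounds)."""

    name: str
    lo: float
    hi: float

    def contains(self, day: float) -> bool:
        return self.lo <= day <= self.hi


#: Study timeline: up to 33 days before surgery, first two weeks after,
#: mid recovery (50-100 d) and long term (150+ d).
PRE = RecoveryPhase("PRE", -33, -1)
POST_EARLY = RecoveryPhase("POST_EARLY", 0, 14)
POST_MID = RecoveryPhase("POST_MID", 50, 100)
POST_LATE = RecoveryPhase("POST_LATE", 150, np.inf)

PHASES: dict[str, RecoveryPhase] = {
    p.name: p for p in (PRE, POST_EARLY, POST_MID, POST_LATE)
}


def phase_of_day(day: float) -> str | None:
    """Map a signed day offset to its recovery-phase name (None in gaps)."""
    for phase in PHASES.values():
        if phase.contains(day):
            return phase.name
    return None


# ---------------------------------------------------------------------------
# WAV I/O


def read_recording(
    path: str | Path,
    channel_policy: Literal["mean", "left", "right"] = "mean",
    source_id: str | None = None,
) -> AudioRecording:
    """Read a PCM WAV file and collapse it to mono.

    Stereo files are mixed down according to ``channel_policy`` (default:
    per-frame mean of the channels).
    """
    path = Path(path)
    sample_rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"{path}: zero-length audio")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: expected integer PCM samples, got {data.dtype}")
    data = data.astype(np.float64)
    if data.ndim == 2:
        if channel_policy == "mean":
            data = data.mean(axis=1)
        elif channel_policy == "left":
            data = data[:, 0]
        elif channel_policy == "right":
            data = data[:, 1]
        else:
            raise ValueError(f"unknown channel_policy {channel_policy!r}")
    return AudioRecording(data, int(sample_rate), source_id or path.stem)


def write_recording(recording: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV (samples clipped to range)."""
    pcm = np.clip(np.round(recording.samples), PCM16_MIN, PCM16_MAX).astype(np.int16)
    wavfile.write(Path(path), recording.sample_rate, pcm)


# ---------------------------------------------------------------------------
# Segmentation


def moving_average_volume(
    recording: AudioRecording | np.ndarray,
    window_s: float = 0.1,
    sample_rate: int | None = None,
    mode: Literal["mean_abs", "rms"] = "mean_abs",
) -> np.ndarray:
    """Per-sample volume: moving average of |x| (or RMS) over a centered window.

    Edge windows are truncated, so the output has the input length.  The
    original extraction rule thresholds this trace at 500 on the raw PCM
    scale.
    """
    if isinstance(recording, AudioRecording):
        x = recording.samples
        sample_rate = recording.sample_rate
    else:
        x = np.asarray(recording, dtype=np.float64)
        if sample_rate is None:
            raise ValueError("sample_rate required for bare sample arrays")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = int(round(window_s * sample_rate))
    win = max(win, 1)
    if win > x.size:
        raise ValueError("window longer than recording")

    mag = np.abs(x) if mode == "mean_abs" else np.square(x)
    if mode not in ("mean_abs", "rms"):
        raise ValueError(f"unknown mode {mode!r}")
    half = win // 2
    csum = np.concatenate(([0.0], np.cumsum(mag)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (win - half), x.size)
    avg = (csum[hi] - csum[lo]) / (hi - lo)
    return np.sqrt(avg) if mode == "rms" else avg


def segment_events(
    recording: AudioRecording,
    threshold: float = 500.0,
    window_s: float = 0.1,
    min_gap_s: float = 0.2,
    mode: Literal["mean_abs", "rms"] = "mean_abs",
) -> list[AcousticEvent]:
    """Find maximal runs where the moving-average volume is >= threshold.

    Runs separated by silent gaps shorter than ``min_gap_s`` are merged so
    single calls with brief amplitude dips are not split.  Returned events
    are sorted and disjoint; an empty list means nothing crossed the
    threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    volume = moving_average_volume(recording, window_s, mode=mode)
    above = volume >= threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)

    min_gap = int(round(min_gap_s * recording.sample_rate))
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    return [
        AcousticEvent(recording.source_id, s, e) for s, e in merged
    ]


def validate_squeal(
    event: AcousticEvent,
    recording: AudioRecording,
    min_duration_s: float = 0.5,
) -> bool:
    """True iff the event lasts at least ``min_duration_s`` (inclusive)."""
    if not (0 <= event.start_sample < event.end_sample <= recording.samples.size):
        raise IndexError("event out of recording bounds")
    return event.duration_s(recording.sample_rate) >= min_duration_s


# ---------------------------------------------------------------------------
# Label tables

LABEL_COLUMNS = [
    "recording_id",
    "start_s",
    "end_s",
    "pig_id",
    "recording_date",
    "days_from_surgery",
    "rater_id",
]


def records_to_table(
    records: Iterable[SquealRecord], sample_rate: int
) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "recording_id": r.event.recording_id,
                "start_s": r.event.start_sample / sample_rate,
                "end_s": r.event.end_sample / sample_rate,
                "pig_id": r.pig_id,
                "recording_date": r.recording_date.isoformat(),
                "days_from_surgery": r.days_from_surgery,
                "rater_id": r.rater_id if r.rater_id is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)


def write_labels(table: pd.DataFrame, path: str | Path) -> None:
    """Write a squeal label table as CSV."""
    missing = [c for c in LABEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"label table missing columns: {missing}")
    table.to_csv(path, index=False)


def load_labels(
    path: str | Path,
    surgery_date: _dt.date | None = None,
) -> pd.DataFrame:
    """Load a squeal label table from CSV.

    When ``surgery_date`` is given, ``days_from_surgery`` is recomputed from
    the recording dates, overriding whatever the file stored.  A ``phase``
    column is added from the recovery windows (None for days in no window).
    """
    df = pd.read_csv(path, dtype={"recording_id": str, "pig_id": str})
    missing = [c for c in LABEL_COLUMNS if c not in df.columns and c != "rater_id"]
    if missing:
        raise ValueError(f"label file missing columns: {missing}")
    if "rater_id" not in df.columns:
        df["rater_id"] = ""
    if (df["end_s"] <= df["start_s"]).any():
        bad = df.index[df["end_s"] <= df["start_s"]].tolist()
        raise ValueError(f"non-positive event durations in rows {bad}")
    df["recording_date"] = pd.to_datetime(df["recording_date"]).dt.date
    if surgery_date is not None:
        df["days_from_surgery"] = [
            (d - surgery_date).days for d in df["recording_date"]
        ]
    df["days_from_surgery"] = df["days_from_surgery"].astype(int)
    df["phase"] = [phase_of_day(d) for d in df["days_from_surgery"]]
    return df
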