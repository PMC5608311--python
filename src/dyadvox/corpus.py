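"""Domain model for dyadic couple-therapy interaction corpora.

A corpus is organised as couples x timepoints (pre-therapy, 26 weeks,
2 years) x topics (husband-chosen, wife-chosen issue), each cell a
~10-minute two-speaker interaction.  One *outcome sample* pairs the two
pre-therapy interactions with the two interactions at a follow-up
horizon and carries a clinical outcome rating on a 1-4 scale
(1 deteriorated, 2 no change, 3 improved, 4 recovered).

File formats: PCM WAV for audio, an RTTM dialect for speech segments and
speaker turns, and comma-delimited tables for outcomes and features.
All times are session-relative seconds; intervals are half-open
[start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger("dyadvox")

TIMEPOINTS = ("pre", "26wk", "2yr")
HORIZONS = ("26wk", "2yr")
TOPICS = ("husband_chosen", "wife_chosen")
ROLES = ("H", "W")
RATINGS = (1, 2, 3, 4)


class CorpusError(ValueError):
    """Invalid corpus data (bad file, malformed table, broken invariant)."""


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass
class AudioSignal:
    """Mono audio: float samples in [-1, 1] plus a sample rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise CorpusError("AudioSignal must be mono (1-D samples)")
        if self.rate <= 0:
            raise CorpusError(f"sample rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise CorpusError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class SpeechSegment:
    """Half-open time span [start, end) with a label (speech / cluster id / role)."""

    start: float
    end: float
    label: str = "speech"

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end):
            raise CorpusError(
                f"invalid segment [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Turn:
    """A speaker-attributed speech span. role is 'H' (husband) or 'W' (wife)."""

    role: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CorpusError(f"turn role must be one of {ROLES}, got {self.role!r}")
        if not (0.0 <= self.start < self.end):
            raise CorpusError(f"invalid turn [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class FrameTrack:
    """Frame-level feature matrix for one speaker (see frame_features).

    values: (n_frames, n_features); times: frame centres in seconds;
    voiced: per-frame voicing flag.  Unvoiced frames carry NaN in the
    pitch / voice-quality columns, never zero.
    """

    values: np.ndarray
    times: np.ndarray
    voiced: np.ndarray
    feature_names: tuple[str, ...]
    hop: float = 0.010

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise CorpusError(
                f"FrameTrack shape {self.values.shape} does not match "
                f"{len(self.feature_names)} feature names"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class Interaction:
    """One ~10-minute problem-solving conversation of a couple."""

    couple_id: str
    timepoint: str
    topic: str
    audio: AudioSignal | None = None
    turns: list[Turn] = field(default_factory=list)
    tracks: dict[str, FrameTrack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise CorpusError(f"unknown timepoint {self.timepoint!r}")
        if self.topic not in TOPICS:
            raise CorpusError(f"unknown topic {self.topic!r}")
        self.turns = sorted(self.turns, key=lambda t: t.start)

    @property
    def session_key(self) -> tuple[str, str]:
        return (self.couple_id, self.timepoint)


@dataclass
class OutcomeSample:
    """One prediction unit: pre-therapy vs one follow-up horizon, rated 1-4.

    ``pre`` and ``post`` each map topic -> Interaction.  The two samples
    of a couple (26wk and 2yr horizons) share the identical pre
    interactions by reference.
    """

    couple_id: str
    pre: dict[str, Interaction]
    post: dict[str, Interaction]
    rating: int
    horizon: str

    def __post_init__(self) -> None:
        if self.rating not in RATINGS:
            raise CorpusError(f"rating must be 1..4, got {self.rating}")
        if self.horizon not in HORIZONS:
            raise CorpusError(f"horizon must be one of {HORIZONS}")
        for d in (self.pre, self.post):
            for topic, inter in d.items():
                if inter.couple_id != self.couple_id:
                    raise CorpusError(
                        f"interaction couple {inter.couple_id} != sample couple "
                        f"{self.couple_id}"
                    )

    @property
    def sample_id(self) -> str:
        return f"{self.couple_id}:{self.horizon}"

    @property
    def interactions(self) -> list[Interaction]:
        return [self.pre[t] for t in TOPICS] + [self.post[t] for t in TOPICS]


@dataclass
class Corpus:
    """A set of outcome samples plus free-form provenance metadata."""

    samples: list[OutcomeSample]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    def class_counts(self) -> dict[int, int]:
        counts = {r: 0 for r in RATINGS}
        for s in self.samples:
            counts[s.rating] += 1
        return counts

    def couples(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.couple_id)
        return list(seen)


# ---------------------------------------------------------------------------
# Audio I/O
# ---------------------------------------------------------------------------

def load_audio(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file as a mono float signal in [-1, 1].

    Multi-channel input is downmixed by channel averaging; the sample
    rate is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - wrap into a typed error
        raise CorpusError(f"unreadable WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise CorpusError(f"empty audio file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise CorpusError(f"unsupported WAV encoding {data.dtype} in {path}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, rate=int(rate))


def write_audio(signal: AudioSignal, path: str | Path) -> None:
    """Write a mono signal as 16-bit PCM WAV."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    data = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(Path(path), signal.rate, data)


# ---------------------------------------------------------------------------
# RTTM segment I/O
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[SpeechSegment]:
    """Read RTTM-style records: type file channel onset duration ... speaker.

    Returns segments sorted by onset.  Malformed lines raise a parse
    error naming the line number.
    """
    path = Path(path)
    segments: list[SpeechSegment] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise CorpusError(f"{path}:{lineno}: expected >= 6 fields, got {len(parts)}")
            try:
                onset = float(parts[3])
                dur = float(parts[4])
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: non-numeric onset/duration") from exc
            if dur <= 0 or onset < 0:
                raise CorpusError(
                    f"{path}:{lineno}: invalid onset {onset} / duration {dur}"
                )
            label = parts[5] if len(parts) == 6 else parts[7 if len(parts) > 7 else -1]
            segments.append(SpeechSegment(start=onset, end=onset + dur, label=label))
    segments.sort(key=lambda s: (s.start, s.end))
    return segments


def write_segments(
    segments: Iterable[SpeechSegment | Turn], path: str | Path, file_id: str = "session"
) -> None:
    """Write segments or turns as RTTM rows, seconds to 3 decimals."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        for seg in segments:
            label = seg.label if isinstance(seg, SpeechSegment) else seg.role
            fh.write(
                f"SPEAKER {file_id} 1 {seg.start:.3f} {seg.end - seg.start:.3f} "
                f"{label}\n"
            )


def turns_to_segments(turns: Sequence[Turn]) -> list[SpeechSegment]:
    return [SpeechSegment(t.start, t.end, t.role) for t in turns]


def segments_to_turns(segments: Sequence[SpeechSegment]) -> list[Turn]:
    return [Turn(role=s.label, start=s.start, end=s.end) for s in segments]


# ---------------------------------------------------------------------------
# Outcome table -> corpus assembly
# ---------------------------------------------------------------------------

def read_outcome_table(path: str | Path) -> pd.DataFrame:
    """Read a comma-delimited outcome table (couple_id, horizon, rating)."""
    df = pd.read_csv(path, dtype={"couple_id": str})
    required = {"couple_id", "horizon", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusError(f"outcome table missing columns: {sorted(missing)}")
    return df


def write_outcome_table(samples: Sequence[OutcomeSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "couple_id": [s.couple_id for s in samples],
            "horizon": [s.horizon for s in samples],
            "rating": [s.rating for s in samples],
        }
    ).to_csv(path, index=False)


def assemble_outcome_samples(
    sessions: Iterable[Interaction], outcome_table: pd.DataFrame
) -> Corpus:
    """Pair pre-therapy and follow-up interactions into rated outcome samples.

    One sample is created per outcome-table row for which both topic
    interactions exist at the pre timepoint and at the row's horizon.
    Rows with incomplete session data are dropped with a logged reason.
    Both horizon samples of a couple share the same pre interactions by
    reference.
    """
    by_session: dict[tuple[str, str], dict[str, Interaction]] = {}
    for inter in sessions:
        by_session.setdefault(inter.session_key, {})[inter.topic] = inter

    seen: set[tuple[str, str]] = set()
    samples: list[OutcomeSample] = []
    dropped = 0
    for _, row in outcome_table.iterrows():
        couple = str(row["couple_id"])
        horizon = str(row["horizon"])
        rating = int(row["rating"])
        if rating not in RATINGS:
            raise CorpusError(f"rating outside 1..4 for couple {couple}: {rating}")
        if horizon not in HORIZONS:
            raise CorpusError(f"unknown horizon {horizon!r} for couple {couple}")
        key = (couple, horizon)
        if key in seen:
            raise CorpusError(f"duplicate outcome row for {key}")
        seen.add(key)
        pre = by_session.get((couple, "pre"), {})
        post = by_session.get((couple, horizon), {})
        if set(pre) != set(TOPICS) or set(post) != set(TOPICS):
            logger.info(
                "dropping outcome row %s/%s: incomplete sessions (pre topics %s, "
                "post topics %s)", couple, horizon, sorted(pre), sorted(post)
            )
            dropped += 1
            continue
        samples.append(
            OutcomeSample(couple_id=couple, pre=pre, post=post, rating=rating,
                          horizon=horizon)
        )
    return Corpus(samples=samples, metadata={"dropped_rows": dropped})
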