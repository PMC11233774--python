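"""Readers/writers for transcripts, proximity logs and frequency lists.

Houses the shared domain types (:class:`Utterance`, :class:`Transcript`,
:class:`ProximityEvent`) and the analysis configuration.  The canonical
transcript exchange format is UTF-8 CSV with a fixed header; ELAN ``.eaf``
annotation files are supported read-only (one tier per speaker).
"""

from __future__ import annotations

import csv
import enum
import string
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Role",
    "Utterance",
    "Transcript",
    "ProximityEvent",
    "AnalysisConfig",
    "FormatError",
    "ValidationError",
    "tokenize",
    "read_transcript",
    "write_transcript",
    "read_proximity_log",
    "write_proximity_log",
    "read_frequency_list",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


class Role(str, enum.Enum):
    TEACHER = "teacher"
    FOCAL_CHILD = "focal_child"
    PEER = "peer"


# Characters stripped from token edges.  Internal apostrophes are preserved
# so contractions ("don't") remain single tokens.
_EDGE_PUNCT = string.punctuation + "‘’“”…–—"


def tokenize(text: str) -> list[str]:
    """Deterministic whitespace tokenization with edge-punctuation stripping.

    Case is preserved; consumers that need case-insensitive identity
    (unique-word counts, rare-word lookup, WER) fold it themselves.
    """
    tokens = []
    for unit in text.split():
        core = unit.strip(_EDGE_PUNCT)
        if core:
            tokens.append(core)
    return tokens


@dataclass
class Utterance:
    """One diarized, timestamped speech unit — the atom of the pipeline.

    ``tokens`` is always the deterministic tokenization of ``raw_text``;
    it may be empty only for vocalization-only rows, which every counting
    operation skips.
    """

    utterance_id: str
    recording_id: str
    speaker_id: str
    role: Role
    onset: float
    offset: float
    raw_text: str
    tokens: list[str] = field(default=None)  # type: ignore[assignment]
    in_proximity_of: frozenset[str] = frozenset()
    word_timings: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValidationError(
                f"utterance {self.utterance_id!r}: offset {self.offset} < onset {self.onset}"
            )
        if self.onset < 0:
            raise ValidationError(f"utterance {self.utterance_id!r}: negative onset")
        self.role = Role(self.role)
        if self.tokens is None:
            self.tokens = tokenize(self.raw_text)
        self.in_proximity_of = frozenset(self.in_proximity_of)

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def with_proximity(self, partners: Iterable[str]) -> "Utterance":
        return replace(self, in_proximity_of=frozenset(partners))


@dataclass
class Transcript:
    """Utterances of one recording, sorted by onset (stable tie order)."""

    recording_id: str
    focal_person_id: str | None
    utterances: list[Utterance]
    provenance: str = "reference"  # "reference" or "predicted"

    def __post_init__(self) -> None:
        if self.provenance not in ("reference", "predicted"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        for u in self.utterances:
            if u.recording_id != self.recording_id:
                raise ValidationError(
                    f"utterance {u.utterance_id!r} has recording_id "
                    f"{u.recording_id!r} != {self.recording_id!r}"
                )
        self.utterances = sorted(self.utterances, key=lambda u: u.onset)

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self):
        return iter(self.utterances)

    @property
    def span(self) -> tuple[float, float]:
        """(min onset, max offset) over all utterances."""
        if not self.utterances:
            raise ValidationError("empty transcript has no span")
        return (
            min(u.onset for u in self.utterances),
            max(u.offset for u in self.utterances),
        )

    def speakers(self) -> set[str]:
        return {u.speaker_id for u in self.utterances}


@dataclass(frozen=True)
class ProximityEvent:
    """A timestamped pairwise RSSI reading; the pair is unordered."""

    timestamp: float
    id_a: str
    id_b: str
    rssi: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValidationError(f"self-pair proximity event for {self.id_a!r}")
        # normalize pair order so (a, b) == (b, a)
        if self.id_b < self.id_a:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.id_a, self.id_b))


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    ``proximity_distance`` is documentation only: the RSSI threshold is
    applied in dB directly, with no propagation model.
    """

    rssi_threshold: float = -74.0  # dB, ~1.5 m
    proximity_distance: float = 1.5  # meters (informational)
    pause_boundary: float = 0.3  # s, silence length that ends a unit
    direct_talk_window: float = 3.0  # s around a focal-child utterance
    agreement_tolerance: float = 0.25  # s, coder boundary agreement
    eval_window: float = 360.0  # s, accuracy-analysis segment length
    sync_tone_freq: float = 1000.0  # Hz
    sync_tone_bandwidth: float = 100.0  # Hz
    punctuation_boundaries: frozenset[str] = frozenset({".", "?", "!"})
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.punctuation_boundaries = frozenset(self.punctuation_boundaries)
        if self.rssi_threshold >= 0:
            raise ValidationError("rssi_threshold must be negative (dB)")
        for name in (
            "proximity_distance",
            "pause_boundary",
            "direct_talk_window",
            "agreement_tolerance",
            "eval_window",
            "sync_tone_freq",
            "sync_tone_bandwidth",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["punctuation_boundaries"] = sorted(self.punctuation_boundaries)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(**known)


# ---------------------------------------------------------------------------
# Transcript CSV
# ---------------------------------------------------------------------------

_TRANSCRIPT_COLUMNS = ["recording_id", "speaker_id", "role", "onset_s", "offset_s", "text"]


def read_transcript(
    path: str | Path,
    dialect: str = "tabular",
    *,
    provenance: str = "reference",
    focal: str | None = None,
    roles: Mapping[str, str] | None = None,
) -> Transcript:
    """Read a diarized transcript.

    ``tabular`` expects the canonical CSV header
    ``recording_id,speaker_id,role,onset_s,offset_s,text``.
    ``elan`` reads an ELAN ``.eaf`` file with one tier per speaker; the
    tier's PARTICIPANT (falling back to TIER_ID) is the speaker id and
    ``roles`` maps speaker ids to role names.

    The focal person defaults to the unique speaker with role
    ``focal_child`` when one exists.
    """
    path = Path(path)
    if dialect == "tabular":
        utterances, recording_id = _read_tabular(path)
    elif dialect == "elan":
        utterances, recording_id = _read_eaf(path, roles or {})
    else:
        raise FormatError(f"unknown transcript dialect {dialect!r}")

    if focal is None:
        focal_ids = {u.speaker_id for u in utterances if u.role is Role.FOCAL_CHILD}
        focal = next(iter(focal_ids)) if len(focal_ids) == 1 else None
    return Transcript(
        recording_id=recording_id,
        focal_person_id=focal,
        utterances=utterances,
        provenance=provenance,
    )


def _read_tabular(path: Path) -> tuple[list[Utterance], str]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _TRANSCRIPT_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        utterances: list[Utterance] = []
        recording_id = path.stem
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            try:
                onset = float(row["onset_s"])
                offset = float(row["offset_s"])
            except ValueError as exc:
                raise ValidationError(f"{path} row {i}: non-numeric time ({exc})") from None
            try:
                role = Role(row["role"])
            except ValueError:
                raise ValidationError(
                    f"{path} row {i}: unknown role {row['role']!r}"
                ) from None
            if offset < onset:
                raise ValidationError(f"{path} row {i}: offset {offset} < onset {onset}")
            recording_id = row["recording_id"]
            utterances.append(
                Utterance(
                    utterance_id=f"{recording_id}:{i - 1:05d}",
                    recording_id=recording_id,
                    speaker_id=row["speaker_id"],
                    role=role,
                    onset=onset,
                    offset=offset,
                    raw_text=row["text"],
                )
            )
    return utterances, recording_id


def _read_eaf(path: Path, roles: Mapping[str, str]) -> tuple[list[Utterance], str]:
    """Minimal ELAN EAF reader: alignable annotations, one tier per speaker."""
    tree = ET.parse(path)
    root = tree.getroot()
    slots: dict[str, float] = {}
    for ts in root.iterfind("./TIME_ORDER/TIME_SLOT"):
        value = ts.get("TIME_VALUE")
        if value is not None:
            slots[ts.get("TIME_SLOT_ID")] = int(value) / 1000.0
    recording_id = path.stem
    utterances: list[Utterance] = []
    n = 0
    for tier in root.iterfind("./TIER"):
        speaker = tier.get("PARTICIPANT") or tier.get("TIER_ID")
        role = Role(roles.get(speaker, Role.PEER))
        for ann in tier.iterfind("./ANNOTATION/ALIGNABLE_ANNOTATION"):
            ref1, ref2 = ann.get("TIME_SLOT_REF1"), ann.get("TIME_SLOT_REF2")
            if ref1 not in slots or ref2 not in slots:
                raise FormatError(f"{path}: annotation with unaligned time slot")
            text_el = ann.find("ANNOTATION_VALUE")
            n += 1
            utterances.append(
                Utterance(
                    utterance_id=f"{recording_id}:{n:05d}",
                    recording_id=recording_id,
                    speaker_id=speaker,
                    role=role,
                    onset=slots[ref1],
                    offset=slots[ref2],
                    raw_text=(text_el.text or "") if text_el is not None else "",
                )
            )
    return utterances, recording_id


def write_transcript(transcript: Transcript, path: str | Path) -> None:
    """Write the canonical transcript CSV (times at 1 ms resolution)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRANSCRIPT_COLUMNS)
        for u in transcript.utterances:
            writer.writerow(
                [
                    u.recording_id,
                    u.speaker_id,
                    u.role.value,
                    f"{u.onset:.3f}",
                    f"{u.offset:.3f}",
                    u.raw_text,
                ]
            )


# ---------------------------------------------------------------------------
# Proximity CSV
# ---------------------------------------------------------------------------

_PROXIMITY_COLUMNS = ["timestamp_s", "id_a", "id_b", "rssi_db"]


def read_proximity_log(path: str | Path) -> list[ProximityEvent]:
    """Read a pairwise RSSI log; events sorted by timestamp, pairs normalized."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _PROXIMITY_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        events: list[ProximityEvent] = []
        for i, row in enumerate(reader, start=2):
            try:
                ts = float(row["timestamp_s"])
                rssi = float(row["rssi_db"])
            except ValueError:
                raise ValidationError(f"{path} row {i}: non-numeric value") from None
            events.append(ProximityEvent(ts, row["id_a"], row["id_b"], rssi))
    events.sort(key=lambda e: e.timestamp)
    return events


def write_proximity_log(events: Sequence[ProximityEvent], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PROXIMITY_COLUMNS)
        for e in sorted(events, key=lambda e: e.timestamp):
            writer.writerow([f"{e.timestamp:.3f}", e.id_a, e.id_b, f"{e.rssi:.1f}"])


# ---------------------------------------------------------------------------
# Frequency list
# ---------------------------------------------------------------------------


def read_frequency_list(path: str | Path, n: int | None = None) -> list[str]:
    """Read a rank-ordered word list, one word per line, most common first."""
    words: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            w = line.strip().lower()
            if w and not w.startswith("#"):
                words.append(w)
            if n is not None and len(words) >= n:
                break
    return words
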