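"""Synthetic classroom corpora with known ground truth.

The generator emulates the statistical shape of a preschool classroom
recording session — one or more teachers and several children, a focal
child wearing the recorder, utterances drawn from part-of-speech slot
templates with Zipfian vocabulary, Poisson utterance timing, and a
Bluetooth-style proximity ping stream driven by a co-location schedule.
A separate corruption model produces "predicted" transcripts with known
word substitution/deletion/insertion rates, boundary jitter, and
teacher/peer speaker confusion, so the whole evaluation protocol can be
exercised against injected error rates.

Because utterance text is built from POS slot templates, part-of-speech
ground truth is known by construction: the slot lexicons and the
pseudo-word noun vocabulary are disjoint, and :func:`construction_tagger`
recovers the true tag of every generated token.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import ProximityEvent, Role, Transcript, Utterance, ValidationError, tokenize
from .indices import POS, TaggedToken

__all__ = [
    "SyntheticSpec",
    "CorruptionSpec",
    "generate_corpus",
    "corrupt_transcript",
    "construction_tagger",
    "default_schedule",
    "TEMPLATES",
]

# ---------------------------------------------------------------------------
# Slot lexicons (all disjoint; pseudo-nouns are generated to avoid them)
# ---------------------------------------------------------------------------

SLOT_LEXICONS: dict[str, tuple[str, ...]] = {
    "PRON": ("i", "you", "we", "they", "he", "she", "it"),
    "DET": ("the", "a", "my", "your", "this"),
    "AUX": ("am", "is", "are", "was", "were", "can", "will", "do", "must"),
    "VERB": ("jump", "laugh", "go", "read", "play", "look", "help", "make", "run", "sit"),
    "ADJ": ("good", "little", "tall", "big", "green", "pink", "happy", "new"),
    "CCONJ": ("and", "or", "but"),
    "SCONJ": ("if", "while", "because", "when"),
    "NUM": ("two", "three", "four", "five", "six", "seven"),
}

SLOT_POS: dict[str, POS] = {
    "PRON": POS.OTHER,
    "DET": POS.OTHER,
    "NOUN": POS.OTHER,
    "AUX": POS.AUX,
    "VERB": POS.VERB,
    "ADJ": POS.ADJ,
    "CCONJ": POS.CCONJ,
    "SCONJ": POS.SCONJ,
    "NUM": POS.NUM,
}

# Utterance templates: sequences of POS slots approximating simple
# classroom clause shapes (statements, coordinated and subordinate
# clauses, short directives).
TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("PRON", "AUX", "VERB", "DET", "NOUN"),
    ("DET", "ADJ", "NOUN", "AUX", "ADJ"),
    ("PRON", "VERB", "DET", "NOUN", "CCONJ", "PRON", "VERB", "DET", "NOUN"),
    ("PRON", "AUX", "VERB", "SCONJ", "PRON", "VERB", "DET", "NOUN"),
    ("VERB", "DET", "NOUN"),
    ("PRON", "VERB", "NUM", "NOUN"),
)

_EXTRA_CLAUSE: tuple[str, ...] = ("CCONJ", "PRON", "VERB", "DET", "NOUN")

_SYLLABLES = ("ba", "ko", "mi", "tu", "ne", "lo", "ri", "pa", "vu", "se", "da", "zu")

_ALL_LEXICON_WORDS = frozenset(w for lex in SLOT_LEXICONS.values() for w in lex)


def _pseudo_vocabulary(size: int) -> list[str]:
    """Deterministic pseudo-word noun vocabulary (rank order = list order)."""
    words: list[str] = []
    for a in _SYLLABLES:
        for b in _SYLLABLES:
            w = a + b
            if w not in _ALL_LEXICON_WORDS:
                words.append(w)
    for a in _SYLLABLES:
        for b in _SYLLABLES:
            for c in _SYLLABLES:
                if len(words) >= size:
                    return words[:size]
                w = a + b + c
                if w not in _ALL_LEXICON_WORDS:
                    words.append(w)
    if len(words) < size:
        raise ValidationError(f"vocabulary_size {size} exceeds pseudo-word capacity")
    return words[:size]


@dataclass
class SyntheticSpec:
    """Full parameterization of a synthetic classroom session.

    Defaults emulate a one-hour session with one teacher and four
    children (the first child is the focal recorder-wearer), teacher and
    child speech rates typical of a busy preschool free-play period, and
    a co-location schedule in which the focal child spends most of the
    session near the teacher and shorter stretches near a peer.
    """

    seed: int = 0
    n_teachers: int = 1
    n_children: int = 4
    session_length: float = 3600.0  # seconds
    vocabulary_size: int = 1000
    zipf_exponent: float = 1.0
    mean_utterance_words: float = 6.0
    utterance_rate: float = 8.0  # utterances / minute / speaker
    pos_template_weights: tuple[float, ...] = field(
        default_factory=lambda: tuple([1.0 / len(TEMPLATES)] * len(TEMPLATES))
    )
    proximity_ping_period: float = 1.0  # seconds
    dyad_schedule: list[tuple[tuple[str, str], float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_teachers <= 0 or self.n_children <= 0:
            raise ValidationError("need at least one teacher and one child")
        if self.session_length <= 0 or self.vocabulary_size <= 0:
            raise ValidationError("session_length and vocabulary_size must be positive")
        if self.utterance_rate <= 0 or self.proximity_ping_period <= 0:
            raise ValidationError("rates and ping period must be positive")
        w = np.asarray(self.pos_template_weights, dtype=float)
        if len(w) != len(TEMPLATES) or not np.isclose(w.sum(), 1.0) or (w < 0).any():
            raise ValidationError("pos_template_weights must be a distribution over templates")

    @property
    def teacher_ids(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_teachers)]

    @property
    def child_ids(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_children)]

    @property
    def focal_id(self) -> str:
        return self.child_ids[0]


@dataclass
class CorruptionSpec:
    """ASR/diarization error model: per-word substitution and deletion,
    per-word insertion rate, Gaussian boundary jitter, and per-utterance
    teacher/peer role confusion."""

    seed: int = 0
    p_sub: float = 0.0
    p_del: float = 0.0
    p_ins: float = 0.0
    boundary_jitter_sd: float = 0.0
    p_speaker_confusion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_del", "p_ins", "p_speaker_confusion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.p_sub + self.p_del > 1.0:
            raise ValidationError("p_sub + p_del must not exceed 1")
        if self.boundary_jitter_sd < 0:
            raise ValidationError("boundary_jitter_sd must be non-negative")


def default_schedule(spec: SyntheticSpec) -> list[tuple[tuple[str, str], float, float]]:
    """Alternating focal-child co-location blocks: long stretches near the
    teacher, shorter ones near the second child (when present)."""
    focal = spec.focal_id
    teacher = spec.teacher_ids[0]
    peer = spec.child_ids[1] if spec.n_children > 1 else None
    blocks: list[tuple[tuple[str, str], float, float]] = []
    t = 0.0
    while t < spec.session_length:
        end = min(t + 300.0, spec.session_length)
        blocks.append(((focal, teacher), t, end))
        t = end + 30.0
        if peer is not None and t < spec.session_length:
            end = min(t + 120.0, spec.session_length)
            blocks.append(((focal, peer), t, end))
            t = end + 30.0
    return blocks


def _validate_schedule(blocks) -> None:
    per_pair: dict[frozenset, list[tuple[float, float]]] = {}
    for (a, b), start, end in blocks:
        if a == b:
            raise ValidationError(f"self-pair ({a!r}, {b!r}) in dyad schedule")
        if end <= start:
            raise ValidationError("schedule block must have end > start")
        per_pair.setdefault(frozenset((a, b)), []).append((start, end))
    for pair, spans in per_pair.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValidationError(f"overlapping schedule blocks for pair {sorted(pair)}")


def generate_corpus(spec: SyntheticSpec) -> tuple[Transcript, list[ProximityEvent]]:
    """Generate a ground-truth transcript and its proximity ping stream.

    Deterministic given ``spec.seed``.  Utterance onsets follow a Poisson
    process at ``utterance_rate`` per speaker; texts are drawn from the
    POS templates with Zipfian noun sampling; proximity pings are emitted
    every ``proximity_ping_period`` for every scheduled pair, with RSSI
    above the −74 dB threshold inside co-location blocks and well below
    it outside.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = spec.dyad_schedule if spec.dyad_schedule is not None else default_schedule(spec)
    _validate_schedule(schedule)
    vocab = _pseudo_vocabulary(spec.vocabulary_size)
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    zipf_w = ranks ** (-spec.zipf_exponent)
    zipf_w /= zipf_w.sum()

    base_mean = float(np.dot(
        np.asarray(spec.pos_template_weights), [len(t) for t in TEMPLATES]
    ))
    p_extra = float(np.clip((spec.mean_utterance_words - base_mean) / len(_EXTRA_CLAUSE), 0.0, 0.95))

    speakers = [(t, Role.TEACHER) for t in spec.teacher_ids]
    speakers += [
        (c, Role.FOCAL_CHILD if c == spec.focal_id else Role.PEER)
        for c in spec.child_ids
    ]

    recording_id = "synthetic"
    raw: list[tuple[float, float, str, Role, str]] = []
    mean_gap = 60.0 / spec.utterance_rate
    for spk, role in speakers:
        t = float(rng.exponential(mean_gap))
        onsets = []
        while t < spec.session_length:
            onsets.append(t)
            t += float(rng.exponential(mean_gap))
        for i, onset in enumerate(onsets):
            words = _sample_words(rng, spec, vocab, zipf_w, p_extra)
            text = _render(words, rng)
            dur = 0.35 * len(words)
            limit = onsets[i + 1] - 0.05 if i + 1 < len(onsets) else spec.session_length
            offset = min(onset + dur, max(limit, onset + 0.1), spec.session_length)
            raw.append((onset, offset, spk, role, text))

    raw.sort(key=lambda r: r[0])
    utterances = [
        Utterance(
            utterance_id=f"{recording_id}:{i + 1:05d}",
            recording_id=recording_id,
            speaker_id=spk,
            role=role,
            onset=round(onset, 3),
            offset=round(offset, 3),
            raw_text=text,
        )
        for i, (onset, offset, spk, role, text) in enumerate(raw)
    ]
    transcript = Transcript(recording_id, spec.focal_id, utterances, "reference")

    events: list[ProximityEvent] = []
    pairs = sorted({frozenset(b[0]) for b in schedule}, key=sorted)
    for pair in pairs:
        spans = sorted((s, e) for (p, s, e) in schedule if frozenset(p) == pair)
        a, b = sorted(pair)
        t = 0.0
        while t <= spec.session_length:
            inside = any(s <= t <= e for s, e in spans)
            rssi = (-60.0 + rng.uniform(-5, 5)) if inside else (-85.0 + rng.uniform(-3, 3))
            events.append(ProximityEvent(round(t, 3), a, b, round(rssi, 1)))
            t += spec.proximity_ping_period
    events.sort(key=lambda e: (e.timestamp, e.id_a, e.id_b))
    return transcript, events


def _sample_words(rng, spec, vocab, zipf_w, p_extra) -> list[str]:
    ti = int(rng.choice(len(TEMPLATES), p=np.asarray(spec.pos_template_weights)))
    slots = list(TEMPLATES[ti])
    if rng.random() < p_extra:
        slots += list(_EXTRA_CLAUSE)
    words = []
    for slot in slots:
        if slot == "NOUN":
            words.append(vocab[int(rng.choice(len(vocab), p=zipf_w))])
        else:
            lex = SLOT_LEXICONS[slot]
            words.append(lex[int(rng.integers(len(lex)))])
    return words


def _render(words: Sequence[str], rng) -> str:
    text = " ".join(words)
    text = text[0].upper() + text[1:]
    return text + ("?" if rng.random() < 0.2 else ".")


# ---------------------------------------------------------------------------
# Construction-truth tagging
# ---------------------------------------------------------------------------

_WORD_POS: dict[str, POS] = {
    w: SLOT_POS[slot] for slot, lex in SLOT_LEXICONS.items() for w in lex
}


def construction_tagger(utterance: Utterance) -> list[TaggedToken]:
    """True POS tags of generated text, recovered from the slot lexicons.

    Pseudo-word nouns (and pronouns/determiners) are OTHER.  Valid only
    for corpora produced by :func:`generate_corpus` (or corruptions of
    them, whose replacement words come from the same corpus vocabulary).
    """
    return [
        TaggedToken(tok, tok.casefold(), _WORD_POS.get(tok.casefold(), POS.OTHER))
        for tok in utterance.tokens
    ]


# ---------------------------------------------------------------------------
# Corruption model
# ---------------------------------------------------------------------------

_EDGE = string.punctuation + "‘’“”…"


def corrupt_transcript(truth: Transcript, c: CorruptionSpec) -> Transcript:
    """Apply the error model to a ground-truth transcript.

    Per word: substitution with ``p_sub`` (replacement drawn from the
    corpus's own vocabulary), deletion with ``p_del``, and an insertion
    after it with rate ``p_ins``.  Terminal punctuation of a deleted word
    migrates to the previous surviving word so boundary punctuation is
    not silently lost.  Onsets/offsets receive zero-mean Gaussian jitter;
    utterances whose words are all deleted are dropped.  Deterministic
    given ``c.seed``.
    """
    rng = np.random.default_rng(c.seed)
    vocab = sorted({t.casefold() for u in truth.utterances for t in u.tokens})
    out: list[Utterance] = []
    for u in truth.utterances:
        units = _corrupt_units(u.raw_text.split(), c, rng, vocab)
        onset, offset = u.onset, u.offset
        if c.boundary_jitter_sd > 0:
            onset = max(0.0, u.onset + float(rng.normal(0, c.boundary_jitter_sd)))
            offset = max(onset + 0.05, u.offset + float(rng.normal(0, c.boundary_jitter_sd)))
        role = u.role
        if c.p_speaker_confusion > 0 and rng.random() < c.p_speaker_confusion:
            if role is Role.TEACHER:
                role = Role.PEER
            elif role is Role.PEER:
                role = Role.TEACHER
        if not units and u.tokens:
            continue  # fully deleted
        text = " ".join(units) if units else u.raw_text
        if not tokenize(text) and u.tokens:
            continue
        out.append(
            replace(
                u,
                raw_text=text,
                tokens=None,
                onset=round(onset, 3),
                offset=round(offset, 3),
                role=role,
                word_timings=None,
            )
        )
    return Transcript(truth.recording_id, truth.focal_person_id, out, "predicted")


def _corrupt_units(units: list[str], c: CorruptionSpec, rng, vocab: list[str]) -> list[str]:
    result: list[str] = []
    for unit in units:
        core = unit.strip(_EDGE)
        if not core:
            result.append(unit)
            continue
        head, tail = _split_edges(unit, core)
        r = rng.random()
        if r < c.p_del:
            if tail and result:
                result[-1] = result[-1] + tail  # keep boundary punctuation
        elif r < c.p_del + c.p_sub:
            repl = vocab[int(rng.integers(len(vocab)))] if vocab else core
            if core[:1].isupper():
                repl = repl[:1].upper() + repl[1:]
            result.append(head + repl + tail)
        else:
            result.append(unit)
        if c.p_ins > 0 and rng.random() < c.p_ins and vocab:
            result.append(vocab[int(rng.integers(len(vocab)))])
    return result


def _split_edges(unit: str, core: str) -> tuple[str, str]:
    i = unit.find(core)
    return unit[:i], unit[i + len(core):]
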