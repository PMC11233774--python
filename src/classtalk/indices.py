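"""The 13 dyadic linguistic indices, with a pluggable POS tagger.

Indices (abbreviations used throughout, in canonical column order):

====  =========================================================
UT    number of utterances
WD    number of words (non-punctuation tokens)
AV    number of auxiliary verbs (incl. copula BE)
CC    number of coordinating conjunctions
SC    number of subordinating conjunctions
VB    number of main (content) verbs
AJ    number of adjectives
UW    number of unique words (case-folded types)
RW    number of rare words (outside the common-word list and its
      inflected forms; never proper names or numbers)
MLU   mean length of utterance = WD / UT (missing when UT = 0)
TTR   type-token ratio = UW / WD (missing when WD = 0)
CT    conversational turns (speaker alternations in the dyad stream)
SD    speech duration, seconds
====  =========================================================

POS tagging goes through a tagger interface: any callable mapping an
utterance to a list of :class:`TaggedToken`.  The default is a bundled
rule-based tagger (closed-class lexicons for AUX/CCONJ/SCONJ, digit and
number-word NUM, capitalization-based PROPN, lexicon plus suffix
heuristics for VERB/ADJ); an external statistical tagger can be adapted
through the same interface via the Universal-POS mapping in ``UPOS_MAP``.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .io import Transcript, Utterance, ValidationError, read_frequency_list

__all__ = [
    "POS",
    "TaggedToken",
    "IndexVector",
    "FrequencyList",
    "RuleBasedTagger",
    "TaggingError",
    "INDEX_NAMES",
    "tag_tokens",
    "classify_rare",
    "count_turns",
    "compute_index_vector",
    "dyadic_table",
    "speech_duration_by_role",
    "write_dyadic_table",
    "packaged_frequency_list",
    "inflections",
]

INDEX_NAMES = ["UT", "WD", "AV", "CC", "SC", "VB", "AJ", "UW", "RW", "MLU", "TTR", "CT", "SD"]


class POS(str, enum.Enum):
    AUX = "AUX"
    VERB = "VERB"
    ADJ = "ADJ"
    CCONJ = "CCONJ"
    SCONJ = "SCONJ"
    PROPN = "PROPN"
    NUM = "NUM"
    OTHER = "OTHER"


# Adapter table for external taggers emitting full Universal POS tags.
UPOS_MAP: Mapping[str, POS] = {
    "AUX": POS.AUX,
    "VERB": POS.VERB,
    "ADJ": POS.ADJ,
    "CCONJ": POS.CCONJ,
    "CONJ": POS.CCONJ,
    "SCONJ": POS.SCONJ,
    "PROPN": POS.PROPN,
    "NUM": POS.NUM,
}


@dataclass(frozen=True)
class TaggedToken:
    surface: str
    folded: str
    pos: POS
    is_word: bool = True

    def __post_init__(self) -> None:
        if self.folded != self.surface.casefold():
            raise ValidationError("folded must be the case-fold of surface")


class TaggingError(RuntimeError):
    def __init__(self, utterance_id: str, cause: Exception):
        super().__init__(f"tagging failed on utterance {utterance_id!r}: {cause}")
        self.utterance_id = utterance_id


class RuleBasedTagger:
    """Deterministic closed-class/heuristic tagger.

    Closed classes are looked up case-insensitively.  A capitalized token
    that is not utterance-initial and matches no closed class is a proper
    noun.  Purely numeric tokens and number words are NUM.  Content verbs
    and adjectives are recognized from small lexicons plus suffix
    heuristics (-ing/-ed for verbs; -ful/-ous/-ish for adjectives).
    Everything else is OTHER (nouns, pronouns, determiners, adverbs...).
    """

    AUX = frozenset(
        "am is are was were be been being do does did have has had having "
        "will would shall should can could may might must".split()
    )
    CCONJ = frozenset("and or but nor".split())
    SCONJ = frozenset(
        "that if while because although though since unless until when "
        "whenever whether after before once".split()
    )
    NUM_WORDS = frozenset(
        "zero one two three four five six seven eight nine ten eleven twelve "
        "thirteen fourteen fifteen sixteen seventeen eighteen nineteen twenty "
        "thirty forty fifty sixty seventy eighty ninety hundred thousand million".split()
    )
    VERB = frozenset(
        "jump laugh go read use need know want see look make play come get "
        "say tell think run eat sit give take put like help build draw sing "
        "open close find hold wash paint cut share clean".split()
    )
    ADJ = frozenset(
        "good little tall big small green pink red blue yellow happy sad "
        "right nice new old hot cold funny pretty soft loud quiet clean dirty "
        "fast slow wet dry".split()
    )

    def __call__(self, utterance: Utterance) -> list[TaggedToken]:
        tagged = []
        for i, surface in enumerate(utterance.tokens):
            folded = surface.casefold()
            tagged.append(TaggedToken(surface, folded, self._tag(surface, folded, i)))
        return tagged

    def _tag(self, surface: str, folded: str, position: int) -> POS:
        if folded in self.AUX:
            return POS.AUX
        if folded in self.CCONJ:
            return POS.CCONJ
        if folded in self.SCONJ:
            return POS.SCONJ
        if folded in self.NUM_WORDS or _is_numeric(surface):
            return POS.NUM
        if folded in self.VERB:
            return POS.VERB
        if folded in self.ADJ:
            return POS.ADJ
        if position > 0 and surface[:1].isupper():
            return POS.PROPN
        if len(folded) > 4 and (folded.endswith("ing") or folded.endswith("ed")):
            return POS.VERB
        if len(folded) > 4 and folded.endswith(("ful", "ous", "ish")):
            return POS.ADJ
        return POS.OTHER


def _is_numeric(surface: str) -> bool:
    s = surface.replace(",", "").replace(".", "", 1)
    return bool(s) and s.isdigit()


_DEFAULT_TAGGER = RuleBasedTagger()

Tagger = Callable[[Utterance], list[TaggedToken]]


def tag_tokens(utterance: Utterance, tagger: Tagger | None = None) -> list[TaggedToken]:
    """Tag one utterance, wrapping tagger failures with the utterance id."""
    tagger = tagger or _DEFAULT_TAGGER
    try:
        tagged = tagger(utterance)
    except Exception as exc:  # noqa: BLE001 - contract: carry utterance_id
        raise TaggingError(utterance.utterance_id, exc) from exc
    if len(tagged) != len(utterance.tokens):
        raise TaggingError(
            utterance.utterance_id,
            ValueError(f"tagger returned {len(tagged)} tags for {len(utterance.tokens)} tokens"),
        )
    return tagged


# ---------------------------------------------------------------------------
# Rare words
# ---------------------------------------------------------------------------

_VOWELS = set("aeiou")


def inflections(word: str) -> set[str]:
    """Regular inflected forms of ``word``: plural/3sg, past, progressive,
    comparative and superlative, with e-drop, y→i and final-consonant
    doubling rules."""
    w = word.lower()
    forms = {w}
    if not w.isalpha():
        return forms
    # plural / third person singular
    if w.endswith(("s", "x", "z", "ch", "sh")):
        forms.add(w + "es")
    elif len(w) > 1 and w.endswith("y") and w[-2] not in _VOWELS:
        forms.add(w[:-1] + "ies")
    else:
        forms.add(w + "s")
    # suffixes beginning with a vowel
    if w.endswith("e") and not w.endswith("ee"):
        stem = w[:-1]
        forms |= {w + "d", stem + "ing", w + "r", w + "st"}
    elif len(w) > 1 and w.endswith("y") and w[-2] not in _VOWELS:
        stem = w[:-1]
        forms |= {stem + "ied", w + "ing", stem + "ier", stem + "iest"}
    else:
        stem = w
        if (
            len(w) >= 3
            and w[-1] not in _VOWELS | set("wxy")
            and w[-2] in _VOWELS
            and w[-3] not in _VOWELS
        ):
            stem = w + w[-1]  # CVC: double the final consonant
        forms |= {stem + "ed", stem + "ing", stem + "er", stem + "est"}
    return forms


class FrequencyList:
    """The N most common word forms plus their inflected closure.

    A word is *rare* when its case-folded form is outside the closure and
    it is neither a proper name nor a number.
    """

    def __init__(self, common_words: Sequence[str], n: int = 10_000):
        self.common_words = [w.lower() for w in common_words[:n]]
        closure: set[str] = set()
        for w in self.common_words:
            closure |= inflections(w)
        self.inflected_closure = frozenset(closure)

    @classmethod
    def from_file(cls, path, n: int = 10_000) -> "FrequencyList":
        return cls(read_frequency_list(path), n=n)

    def __contains__(self, folded: str) -> bool:
        return folded in self.inflected_closure

    def __len__(self) -> int:
        return len(self.common_words)


def packaged_frequency_list(n: int = 10_000) -> FrequencyList:
    """The compact common-word list shipped with the package.

    Intended for tests and examples; production analyses should supply a
    corpus-derived 10,000-word list via :meth:`FrequencyList.from_file`.
    """
    ref = importlib.resources.files("classtalk.data").joinpath("common_words.txt")
    words = [
        w.strip().lower()
        for w in ref.read_text(encoding="utf-8").splitlines()
        if w.strip() and not w.startswith("#")
    ]
    return FrequencyList(words, n=n)


def classify_rare(token: TaggedToken, freq: FrequencyList) -> bool:
    """True iff the token is a rare word."""
    if token.pos in (POS.PROPN, POS.NUM):
        return False
    return token.folded not in freq


# ---------------------------------------------------------------------------
# Index computation
# ---------------------------------------------------------------------------


def count_turns(dyad_utterances: Sequence[Utterance]) -> int:
    """Back-and-forth alternations: adjacent utterance pairs with
    different speakers, in a stream of at most two speakers."""
    speakers = [u.speaker_id for u in dyad_utterances]
    if len(set(speakers)) > 2:
        raise ValidationError(
            f"count_turns expects at most two speakers, got {sorted(set(speakers))}"
        )
    return _alternations(speakers)


def _alternations(speakers: Sequence[str]) -> int:
    return sum(1 for a, b in zip(speakers, speakers[1:]) if a != b)


@dataclass
class IndexVector:
    """The 13 indices for one (sender, receiver, scope).

    MLU and TTR are ``None`` (missing, never zero) when their denominators
    are zero; evaluation excludes missing values from its windows.
    """

    UT: int = 0
    WD: int = 0
    AV: int = 0
    CC: int = 0
    SC: int = 0
    VB: int = 0
    AJ: int = 0
    UW: int = 0
    RW: int = 0
    MLU: float | None = None
    TTR: float | None = None
    CT: int = 0
    SD: float = 0.0

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def compute_index_vector(
    utterances: Sequence[Utterance],
    tagged: Sequence[Sequence[TaggedToken]],
    freq: FrequencyList | None = None,
    dyad_stream: Sequence[Utterance] | None = None,
) -> IndexVector:
    """Aggregate the 13 indices over ``utterances``.

    ``tagged`` must align 1:1 with ``utterances``.  Vocalization-only rows
    (empty token lists) are skipped by every index.  ``CT`` is counted
    over ``dyad_stream`` when given (the merged two-speaker stream of a
    dyad), otherwise over the speaker sequence of ``utterances`` itself.
    When ``freq`` is None, rare-word classification is disabled (RW = 0).
    """
    if len(tagged) != len(utterances):
        raise ValidationError("tagged must align 1:1 with utterances")
    v = IndexVector()
    types: set[str] = set()
    pos_counts = {POS.AUX: 0, POS.CCONJ: 0, POS.SCONJ: 0, POS.VERB: 0, POS.ADJ: 0}
    spoken: list[Utterance] = []
    for u, toks in zip(utterances, tagged):
        if not u.tokens:
            continue  # vocalization-only
        spoken.append(u)
        v.UT += 1
        v.WD += len(u.tokens)
        v.SD += u.duration
        for t in toks:
            if t.pos in pos_counts:
                pos_counts[t.pos] += 1
            types.add(t.folded)
            if freq is not None and classify_rare(t, freq):
                v.RW += 1
    v.AV = pos_counts[POS.AUX]
    v.CC = pos_counts[POS.CCONJ]
    v.SC = pos_counts[POS.SCONJ]
    v.VB = pos_counts[POS.VERB]
    v.AJ = pos_counts[POS.ADJ]
    v.UW = len(types)
    v.MLU = v.WD / v.UT if v.UT > 0 else None
    v.TTR = v.UW / v.WD if v.WD > 0 else None
    if dyad_stream is not None:
        v.CT = count_turns([u for u in dyad_stream if u.tokens])
    else:
        v.CT = _alternations([u.speaker_id for u in spoken])
    return v


def dyadic_table(
    transcript: Transcript,
    freq: FrequencyList | None = None,
    tagger: Tagger | None = None,
    *,
    gating: bool = True,
    turn_max_gap: float | None = None,
) -> dict[tuple[str, str], IndexVector]:
    """Index vectors per ordered (sender, receiver) pair.

    With proximity gating (default), a sender's utterance contributes to
    the dyad (sender → receiver) iff the receiver is in its
    ``in_proximity_of`` set; an utterance heard by k partners contributes
    to k dyads.  With gating disabled, every other speaker in the
    transcript is a receiver of every utterance.

    CT is computed over the dyad's merged two-way stream; consecutive
    utterances further apart than ``turn_max_gap`` seconds (when set) do
    not count as an alternation.
    """
    by_dyad: dict[tuple[str, str], list[Utterance]] = {}
    all_speakers = transcript.speakers()
    for u in transcript.utterances:
        receivers = u.in_proximity_of if gating else all_speakers - {u.speaker_id}
        for r in receivers:
            if r == u.speaker_id:
                continue
            by_dyad.setdefault((u.speaker_id, r), []).append(u)
    table: dict[tuple[str, str], IndexVector] = {}
    for (s, r), utts in sorted(by_dyad.items()):
        stream = sorted(
            utts + by_dyad.get((r, s), []), key=lambda u: (u.onset, u.utterance_id)
        )
        tagged = [tag_tokens(u, tagger) for u in utts]
        v = compute_index_vector(utts, tagged, freq, dyad_stream=stream)
        if turn_max_gap is not None:
            v.CT = _gapped_turns(stream, turn_max_gap)
        table[(s, r)] = v
    return table


def _gapped_turns(stream: Sequence[Utterance], max_gap: float) -> int:
    n = 0
    spoken = [u for u in stream if u.tokens]
    for a, b in zip(spoken, spoken[1:]):
        if a.speaker_id != b.speaker_id and (b.onset - a.offset) <= max_gap:
            n += 1
    return n


def speech_duration_by_role(transcript: Transcript) -> dict[str, float]:
    """Total speech duration in seconds per speaker role (skipping
    vocalization-only rows, like every other index)."""
    totals: dict[str, float] = {}
    for u in transcript.utterances:
        if not u.tokens:
            continue
        totals[u.role.value] = totals.get(u.role.value, 0.0) + u.duration
    return totals


def write_dyadic_table(table: Mapping[tuple[str, str], IndexVector], path) -> None:
    """Dyadic table as CSV: sender, receiver, then the 13 index columns."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sender", "receiver", *INDEX_NAMES])
        for (s, r), v in sorted(table.items()):
            row = [s, r]
            for name in INDEX_NAMES:
                val = getattr(v, name)
                if val is None:
                    row.append("")
                elif isinstance(val, float):
                    row.append(f"{val:.6g}")
                else:
                    row.append(val)
            writer.writerow(row)
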