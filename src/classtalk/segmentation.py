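"""Re-segmentation of utterances into C-unit approximations, and the
temporal direct-talk selector.

A C-unit (communication unit) is one independent clause plus its dependent
clauses and modifiers.  Transcripts produced by ASR often pack several
C-units into one diarized segment; :func:`resegment` splits them at
sentence-final punctuation (and, when word timings are available, at
sufficiently long inter-word pauses), distributing the parent time span
proportionally to token counts so total speech duration is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io import AnalysisConfig, Transcript, Utterance, ValidationError, tokenize

__all__ = ["SegmentationRule", "resegment", "select_direct_talk"]


@dataclass
class SegmentationRule:
    """Boundary definition for C-unit approximation.

    Commas and ellipses are deliberately not boundaries: they routinely
    join dependent material inside one C-unit.  A pause of at least
    ``pause_boundary`` seconds between words also ends a unit when word
    timings are present and ``use_word_timings`` is set.
    """

    punctuation_boundaries: frozenset[str] = field(
        default_factory=lambda: frozenset({".", "?", "!"})
    )
    pause_boundary: float = 0.3
    use_word_timings: bool = False

    def __post_init__(self) -> None:
        self.punctuation_boundaries = frozenset(self.punctuation_boundaries)
        if not self.punctuation_boundaries:
            raise ValidationError("punctuation_boundaries must be non-empty")
        if self.pause_boundary <= 0:
            raise ValidationError("pause_boundary must be positive")

    @classmethod
    def from_config(cls, cfg: AnalysisConfig, use_word_timings: bool = False):
        return cls(cfg.punctuation_boundaries, cfg.pause_boundary, use_word_timings)


def _unit_ends_with_boundary(unit: str, boundaries: frozenset[str]) -> bool:
    # trailing closing quotes/brackets may follow the terminal mark
    stripped = unit.rstrip("'\")]”’")
    return bool(stripped) and stripped[-1] in boundaries


def _split_units(raw_text: str, rule: SegmentationRule) -> list[list[str]]:
    """Group whitespace units of raw_text into boundary-terminated pieces."""
    pieces: list[list[str]] = []
    current: list[str] = []
    for unit in raw_text.split():
        current.append(unit)
        if _unit_ends_with_boundary(unit, rule.punctuation_boundaries):
            pieces.append(current)
            current = []
    if current:
        pieces.append(current)
    return pieces


def resegment(transcript: Transcript, rule: SegmentationRule | None = None) -> Transcript:
    """Split each utterance at sentence-final boundary punctuation.

    Pieces inherit speaker and role; their onsets/offsets partition the
    parent span proportionally to word-token counts (or follow word
    timings when available and enabled).  Pieces with no word tokens
    (punctuation-only fragments) are dropped.  Idempotent: pieces end at
    boundaries, so a second pass is a no-op.
    """
    rule = rule or SegmentationRule()
    out: list[Utterance] = []
    for u in transcript.utterances:
        pieces = _split_units(u.raw_text, rule)
        if rule.use_word_timings and u.word_timings and len(u.word_timings) == len(u.tokens):
            pieces = _resplit_by_pauses(pieces, u, rule)
        pieces = [p for p in pieces if tokenize(" ".join(p))]
        if len(pieces) <= 1:
            out.append(u)
            continue
        counts = [len(tokenize(" ".join(p))) for p in pieces]
        total = sum(counts)
        t = u.onset
        cum = 0
        for i, (piece, c) in enumerate(zip(pieces, counts)):
            cum += c
            end = u.offset if i == len(pieces) - 1 else u.onset + u.duration * cum / total
            out.append(
                replace(
                    u,
                    utterance_id=f"{u.utterance_id}#{i + 1}",
                    raw_text=" ".join(piece),
                    tokens=None,
                    onset=t,
                    offset=end,
                    word_timings=None,
                )
            )
            t = end
    return replace(transcript, utterances=out)


def _resplit_by_pauses(
    pieces: list[list[str]], u: Utterance, rule: SegmentationRule
) -> list[list[str]]:
    """Additionally break pieces at inter-word gaps >= pause_boundary."""
    # map word-token index -> whitespace unit index
    unit_tokens: list[int] = []  # token count per unit, flattened over pieces
    flat_units: list[str] = [w for p in pieces for w in p]
    piece_bounds = set()
    acc = 0
    for p in pieces[:-1]:
        acc += len(p)
        piece_bounds.add(acc)
    tok_i = 0
    unit_of_token: list[int] = []
    for ui, unit in enumerate(flat_units):
        for _ in tokenize(unit):
            unit_of_token.append(ui)
            tok_i += 1
    break_after_unit = set()
    for i in range(len(u.word_timings) - 1):
        gap = u.word_timings[i + 1][0] - u.word_timings[i][1]
        if gap >= rule.pause_boundary and i < len(unit_of_token) - 1:
            ua, ub = unit_of_token[i], unit_of_token[i + 1]
            if ub > ua:
                break_after_unit.add(ua + 1)
    cuts = sorted(piece_bounds | break_after_unit)
    result: list[list[str]] = []
    prev = 0
    for c in cuts:
        if c > prev:
            result.append(flat_units[prev:c])
            prev = c
    if prev < len(flat_units):
        result.append(flat_units[prev:])
    return result


def select_direct_talk(
    transcript: Transcript, focal: str, cfg: AnalysisConfig | None = None
) -> Transcript:
    """Keep the focal child's own utterances plus teacher/peer utterances
    whose onset lies within the direct-talk window of focal speech.

    The distance is measured to the nearest boundary (onset or offset) of
    any focal-child utterance; onsets falling inside a focal utterance
    count as distance zero.  Output is a subset in original order, and
    enlarging the window is monotone.
    """
    cfg = cfg or AnalysisConfig()
    focal_spans = [
        (u.onset, u.offset) for u in transcript.utterances if u.speaker_id == focal
    ]
    if not focal_spans:
        raise ValidationError(f"focal participant {focal!r} absent from transcript")
    kept = []
    for u in transcript.utterances:
        if u.speaker_id == focal:
            kept.append(u)
            continue
        d = min(_distance_to_span(u.onset, s) for s in focal_spans)
        if d <= cfg.direct_talk_window:
            kept.append(u)
    return replace(transcript, utterances=kept)


def _distance_to_span(t: float, span: tuple[float, float]) -> float:
    lo, hi = span
    if lo <= t <= hi:
        return 0.0
    return min(abs(t - lo), abs(t - hi))
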