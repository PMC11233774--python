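from __future__ import annotations

import pytest

from classtalk.io import AnalysisConfig, Role, Transcript, Utterance


def make_utt(
    speaker: str,
    onset: float,
    offset: float,
    text: str,
    role: str = "peer",
    rec: str = "rec1",
    uid: str | None = None,
    prox: frozenset[str] = frozenset(),
) -> Utterance:
    return Utterance(
        utterance_id=uid or f"{rec}:{speaker}:{onset:.3f}",
        recording_id=rec,
        speaker_id=speaker,
        role=Role(role),
        onset=onset,
        offset=offset,
        raw_text=text,
        in_proximity_of=prox,
    )


def make_transcript(utts, focal="C1", rec="rec1", provenance="reference") -> Transcript:
    return Transcript(rec, focal, list(utts), provenance)


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def classroom_transcript() -> Transcript:
    """Small hand-built classroom scene: focal child C1, teacher T1, peer C2."""
    return make_transcript(
        [
            make_utt("C1", 0.0, 2.0, "I am going to read you something off of my cards.", "focal_child"),
            make_utt("T1", 3.0, 5.0, "You are right.", "teacher"),
            make_utt("C1", 6.0, 7.5, "You can use the mirror if you need it.", "focal_child"),
            make_utt("C2", 8.0, 9.0, "I have pink scissors.", "peer"),
            make_utt("T1", 10.0, 11.0, "Good job.", "teacher"),
        ]
    )
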