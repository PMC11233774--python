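"""Proximity processing: sync-tone detection, RSSI interval construction,
and utterance-to-proximity matching.

Bluetooth beacons report pairwise RSSI readings on a nominal ping cadence.
Readings at or above the configured threshold (default −74 dB, roughly
1.5 m separation) are merged into within-threshold intervals per dyad;
each utterance is then matched against the intervals of the focal person
to record who was in earshot when it was spoken.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import AnalysisConfig, ProximityEvent, Transcript, ValidationError

__all__ = [
    "ProximityInterval",
    "ToneNotFoundError",
    "ConfigurationError",
    "detect_sync_tone",
    "build_proximity_intervals",
    "attach_proximity",
    "write_intervals",
]


class ToneNotFoundError(RuntimeError):
    """No sustained in-band energy burst was found in the signal."""


class ConfigurationError(ValueError):
    """Detector configuration incompatible with the signal (e.g. Nyquist)."""


@dataclass(frozen=True)
class ProximityInterval:
    """A maximal time span during which a dyad was within threshold."""

    pair: frozenset[str]
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"interval end {self.end} <= start {self.start}")
        if len(self.pair) != 2:
            raise ValidationError("interval pair must contain exactly two ids")

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


def detect_sync_tone(
    samples: np.ndarray,
    sample_rate: float,
    cfg: AnalysisConfig,
    *,
    k: float = 6.0,
    sustain: float = 0.1,
    frame: float = 0.02,
    hop: float = 0.01,
    floor_frac: float = 0.01,
) -> float:
    """Locate the onset (seconds) of the synchronization tone.

    The signal is band-pass filtered around ``cfg.sync_tone_freq`` with
    width ``cfg.sync_tone_bandwidth`` (zero-phase, so no group delay bias),
    divided into frames, and the earliest run of frames whose energy
    exceeds ``k`` times the median frame energy for at least ``sustain``
    seconds is reported.  The median-based threshold adapts to the noise
    floor but assumes the tone occupies a minority of the analyzed span.
    An absolute floor of ``floor_frac`` times the broadband signal power
    guards against filter edge transients when no in-band energy exists.
    """
    samples = np.asarray(samples, dtype=float)
    f_hi = cfg.sync_tone_freq + cfg.sync_tone_bandwidth / 2.0
    f_lo = cfg.sync_tone_freq - cfg.sync_tone_bandwidth / 2.0
    if sample_rate <= 2.0 * f_hi:
        raise ConfigurationError(
            f"sample_rate {sample_rate} Hz violates Nyquist for band edge {f_hi} Hz"
        )
    if f_lo <= 0:
        raise ConfigurationError("band extends to non-positive frequency")
    if samples.size < 0.5 * sample_rate:
        raise ConfigurationError("signal shorter than 0.5 s")

    sos = sps.butter(4, [f_lo, f_hi], btype="bandpass", fs=sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, samples)

    frame_n = max(1, int(round(frame * sample_rate)))
    hop_n = max(1, int(round(hop * sample_rate)))
    n_frames = 1 + max(0, (filtered.size - frame_n) // hop_n)
    if n_frames < 2:
        raise ConfigurationError("signal too short for framing")
    idx = np.arange(frame_n)[None, :] + hop_n * np.arange(n_frames)[:, None]
    energy = np.mean(filtered[idx] ** 2, axis=1)

    threshold = max(k * np.median(energy), floor_frac * np.mean(samples**2))
    above = energy > threshold
    need = max(1, int(np.ceil(sustain / hop)))
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            return (i - need + 1) * hop
    raise ToneNotFoundError(
        f"no frame run of {need} frames exceeded {k} x median energy"
    )


def build_proximity_intervals(
    events: Sequence[ProximityEvent],
    cfg: AnalysisConfig,
    ping_period: float,
) -> list[ProximityInterval]:
    """Merge above-threshold RSSI readings into per-dyad intervals.

    Readings with ``rssi >= cfg.rssi_threshold`` are kept.  Consecutive
    kept readings for the same pair are merged when their gap is at most
    twice the ping period — tolerating one missed Bluetooth ping without
    fragmenting an interaction.  An isolated reading yields an interval of
    one ping period centered on its timestamp; merged runs are padded by
    half a ping period on each side.
    """
    if ping_period <= 0:
        raise ValidationError("ping_period must be positive")
    kept: dict[frozenset[str], list[float]] = {}
    for e in events:
        if e.rssi >= cfg.rssi_threshold:
            kept.setdefault(e.pair, []).append(e.timestamp)
    half = ping_period / 2.0
    intervals: list[ProximityInterval] = []
    for pair, times in kept.items():
        times.sort()
        run_start = times[0]
        prev = times[0]
        for t in times[1:]:
            if t - prev <= 2.0 * ping_period:
                prev = t
            else:
                intervals.append(ProximityInterval(pair, run_start - half, prev + half))
                run_start = prev = t
        intervals.append(ProximityInterval(pair, run_start - half, prev + half))
    intervals.sort(key=lambda iv: (sorted(iv.pair), iv.start))
    return intervals


def attach_proximity(
    transcript: Transcript,
    intervals: Sequence[ProximityInterval],
    focal: str,
) -> Transcript:
    """Fill each utterance's ``in_proximity_of`` from the focal person's intervals.

    Membership is decided at the utterance onset and is speaker-relative:
    for each interval involving the focal person whose span contains the
    onset and whose pair contains the utterance's speaker, the pair's
    other member is recorded.  A focal-child utterance thus lists the
    partners near the focal child; a teacher utterance near the focal
    child lists the focal child — the receiver of that dyad.  Idempotent —
    the sets are recomputed from scratch.
    """
    focal_ivs = [iv for iv in intervals if focal in iv.pair]
    new_utts = []
    for u in transcript.utterances:
        partners = {
            next(iter(iv.pair - {u.speaker_id}))
            for iv in focal_ivs
            if u.speaker_id in iv.pair and iv.contains(u.onset)
        }
        new_utts.append(u.with_proximity(partners))
    return replace(transcript, utterances=new_utts)


def write_intervals(intervals: Sequence[ProximityInterval], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b", "start_s", "end_s"])
        for iv in intervals:
            a, b = sorted(iv.pair)
            writer.writerow([a, b, f"{iv.start:.3f}", f"{iv.end:.3f}"])
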