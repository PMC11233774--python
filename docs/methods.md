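# Methods

This note documents the models, conventions and numerical choices behind
`classtalk`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Domain model

The atom is the **utterance**: one diarized, timestamped speech unit
with raw text (punctuation retained) and a derived token list. Tokens
come from a single deterministic tokenizer — whitespace split, edge
punctuation stripped, internal apostrophes preserved ("don't" is one
token) — so every consumer (type counts, rare-word lookup, WER) sees
identical surface forms. Case is preserved at the source and folded
inside consumers. Utterances with an empty token list are
vocalization-only rows; **every** index skips them, including the
utterance count and speech duration, on the grounds that they carry no
linguistic content. Timestamps are seconds at 1 ms resolution, which is
what the 250 ms agreement tolerance and 0.3 s pause boundary require.

## Proximity

RSSI readings are symmetric pair observations; either direction of an
exchange counts. Readings at or above the threshold (default −74 dB,
documented as ≈ 1.5 m; no RSSI-to-distance model is applied) are merged
into per-dyad intervals: consecutive readings ≤ 2 ping periods apart
join one interval (tolerating a single missed Bluetooth ping), an
isolated reading becomes one ping period centered on itself, and merged
runs are padded by half a ping period per side. Lowering the threshold
can only grow total in-range time (tested as a monotonicity property).

Utterance ↔ proximity matching is decided at the utterance **onset** —
deterministic and robust to offset jitter; a fractional-overlap rule was
considered and rejected because it makes membership depend on two noisy
boundaries instead of one. Matching is speaker-relative over the focal
person's intervals: a focal utterance lists the partners in range; a
teacher utterance in range of the focal child lists the focal child,
which is precisely the receiver of that dyad.

The sync-tone detector band-passes around the configured tone frequency
(default 1 kHz ± 50 Hz, 4th-order Butterworth applied zero-phase),
frames energies (20 ms frames, 10 ms hop) and reports the first run of
≥ 100 ms above an adaptive threshold of k = 6 × median frame energy.
The median adapts to the noise floor but assumes the tone occupies a
minority of the span; an absolute floor of 1% of broadband signal power
rejects filter edge transients when no in-band energy exists. Tone
frequency, bandwidth, k and the sustain time are conventions of this
implementation and configurable.

## Segmentation

A C-unit is one independent clause with its dependent clauses and
modifiers. Without a parser, sentence-final punctuation (`.?!`) is the
best proxy: commas and ellipses are *not* boundaries because they
routinely join dependent material inside one C-unit. When word timings
are present, an inter-word silence of at least the pause boundary
(default 0.3 s) also terminates a unit; the "less than 0.3 s" reading
of the pause rule would split nearly every word pair, so the minimum-
pause direction is implemented and the boundary set and direction are
configurable. Split pieces inherit speaker and role, and their
timestamps partition the parent span proportionally to token counts
(exactly conserving per-speaker speech duration; tested to 1 ms).
Punctuation-only fragments are dropped. The operation is idempotent.

Direct talk implements the temporal criterion only: a teacher/peer
utterance is kept when its onset lies within 3 s (configurable) of the
nearest boundary — onset or offset — of any focal-child utterance, with
onsets inside a focal span at distance zero. The semantic criteria of
direct-talk coding (topical relatedness, naming, question form) are
human judgments and out of scope; physical orientation is approximated
upstream by proximity gating.

## Indices

POS tagging is pluggable. The bundled default is a deterministic
rule-based tagger: closed-class lexicons for auxiliaries (including
copula BE), coordinating and subordinating conjunctions; digits and
number words for NUM; capitalized non-initial tokens as proper nouns;
small content-verb and adjective lexicons plus conservative suffix
heuristics; everything else OTHER. An external statistical tagger can
be adapted through the same interface with the Universal-POS mapping.
The synthetic generator's slot templates make construction-truth tags
available independently of any tagger, so index arithmetic is tested
without tagger noise.

Unique words are case-folded surface forms — no lemmatization, since
the type definition is "appeared at least once" with no lemma
convention. Rare words are folded forms outside the inflected closure
of the common-word list, excluding proper nouns and numbers. The
closure affixes {-s/-es, -ed/-d, -ing, -er, -est} with e-drop, y→i and
CVC final-consonant doubling. A compact packaged list (~600 words)
ships for tests and examples; real analyses should supply a
corpus-derived 10,000-word list (`FrequencyList.from_file`), as the
choice of list materially changes RW.

Conversational turns count adjacent speaker alternations in a dyad's
merged, time-ordered stream, with no maximum gap by default (none is
part of the index definition); `turn_max_gap` optionally suppresses
alternations across long silences. MLU and TTR with zero denominators
are *missing*, never zero — carrying zeros into the evaluation windows
would silently bias ERR_median downward for sparse speaker types.

In the dyadic table an utterance heard by k partners contributes to k
dyads, so a sender's summed WD across dyads can exceed the sender's
gated WD (equality iff every utterance has exactly one receiver).

## Evaluation

Windows are half-open [start, start + W) anchored at the recording span
start, W = 360 s by default; the final partial window is kept and
flagged, because the sparsest speaker type may contribute only a few
minutes in total and dropping the remainder would discard it. Windows
with a zero reference value — for which the relative error is undefined
— are excluded per index from both the median and the correlation
vectors (pairwise exclusion), and the exclusion counts are reported.
Correlations use Pearson R with the two-sided t-test p-value at
α = 0.05; identical constant vectors are reported as R = 1 by
convention, non-identical constant vectors as undefined. Normality of
each error distribution is assessed with a KS test on standardized
errors and recorded, not acted on — it documents why the median, not
the mean, summarizes the errors.

WER uses uniform-cost Wagner–Fischer alignment on case-folded tokens;
N_ref is the reference length, so values above 100% are possible with
heavy insertion. The empty-reference/non-empty-hypothesis case is
degenerate and defined as 100 × |hypothesis|. Medians over even counts
are the mean of the central pair. The implementation is checked against
two independent oracles: exhaustively against a memoized recursive
Levenshtein recurrence for all pairs of length ≤ 6 over a 3-symbol
alphabet, and against edlib on randomized longer pairs.

Boundary agreement greedily pairs same-speaker utterances by smallest
onset distance and scores the fraction of reference utterances whose
matched onset (resp. offset) deviation is within 250 ms; unmatched
reference utterances count as disagreement.

Convergence curves report cumulative ERR_median and R for k = 3..n
windows with a flatness diagnostic (range of ERR_median over the last
quarter of the curve, minimum two points).

The transcription-cost estimator is the plain proportionality
n_children × (minutes_per_child / 10) × hours_per_10min.

## Synthetic corpus

The generator emulates a one-hour session: one teacher, four children,
focal child C1, per-speaker Poisson utterance timing at 8 utterances/min
(speech durations of 0.35 s per word, clipped so a speaker does not
overlap themselves), utterance text from six POS slot templates —
simple statements, coordinated and subordinate clauses, short
directives — optionally extended by a coordinated clause with the
probability needed to hit the target mean utterance length (default 6
words). Nouns are pseudo-words sampled from a rank-frequency Zipf law
(exponent 1.0, 1,000 types by default); all other slots draw uniformly
from small closed lexicons disjoint from the pseudo-vocabulary, which
is what makes construction-truth tags recoverable. Proximity pings are
emitted every second for each scheduled pair, with RSSI ≈ −60 dB inside
co-location blocks and ≈ −85 dB outside; the default schedule keeps the
focal child near the teacher in 5-minute blocks separated by shorter
peer blocks, echoing the teacher-heavy/peer-light composition typical
of recorded direct talk.

What the generator does **not** emulate: acoustic noise, overlapping
speech within a speaker, realistic English syntax or semantics,
developmental vocabulary trajectories, RSSI fading/multipath, or clock
drift beyond a single offset. Passing tests therefore demonstrate the
correctness of the *measurement arithmetic and protocol* under known
error rates — not ASR quality on real classroom audio.

The corruption model applies, per word: substitution with p_sub
(replacement drawn from the corpus's own vocabulary, preserving
capitalization and trailing punctuation), deletion with p_del (terminal
punctuation migrates to the previous surviving word), then insertion
with rate p_ins; utterances losing all words are dropped. Boundaries
receive zero-mean Gaussian jitter (offsets clamped ≥ onset + 50 ms);
teacher/peer roles swap with p_speaker_confusion. Everything is
deterministic given the corruption seed.

## Problem sizes and determinism

The acceptance script and tests use sessions of 15–30 minutes with
~2,000–3,000 utterances (≈ 5,000–9,000 words), five to eight evaluation
windows, 1,000 randomized index fixtures, and the full 1.19-million-pair
exhaustive WER grid — sizes chosen so each statistical check has enough
data for its 99% binomial interval while a complete run stays
interactive on one CPU. All randomness flows from explicit
`numpy.random.default_rng` seeds; two runs of
simulate + process + evaluate with the same seed produce byte-identical
data files, witnessed by the SHA-256 digest maps in the run manifests
(the manifest itself additionally records a wall-clock timestamp).

## Known limitations

- The rule-based tagger is deliberately coarse ("have"/"do" are always
  AUX; adjectives rely on a small lexicon); production analyses should
  plug in a statistical tagger through the tagger interface.
- The packaged common-word list is a compact stand-in; RW values from
  it are not comparable to analyses using a full 10,000-word list.
- Greedy boundary pairing is not an optimal bipartite matching; with
  dense, heavily jittered utterance streams it can under-report
  agreement slightly.
- ELAN support covers alignable annotations on one tier per speaker;
  reference-annotation tiers and controlled vocabularies are ignored.
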