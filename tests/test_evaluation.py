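"""Windowing, Eq.-style relative errors, WER, boundary agreement,
convergence diagnostics, and the transcription-cost estimator."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from classtalk.evaluation import (
    NotEvaluableError,
    UndefinedReferenceError,
    boundary_agreement,
    convergence_curve,
    estimate_transcription_cost,
    evaluate,
    make_windows,
    median_wer,
    relative_error,
    summarize_accuracy,
    word_error_rate,
)
from classtalk.indices import INDEX_NAMES, IndexVector
from classtalk.io import AnalysisConfig, ValidationError
from classtalk.evaluation import EvalWindow

from conftest import make_transcript, make_utt


class TestRelativeError:
    def test_exact_match_is_zero(self):
        assert relative_error(10, 10) == 0.0

    def test_double_is_hundred_percent(self):
        assert relative_error(8, 16) == 100.0

    def test_zero_reference_signals(self):
        with pytest.raises(UndefinedReferenceError):
            relative_error(0, 5)

    @given(st.floats(0.01, 1e6), st.floats(0, 1e6))
    @settings(max_examples=300, deadline=None)
    def test_matches_closed_form(self, xr, xp):
        assert relative_error(xr, xp) == pytest.approx(abs(xr - xp) / xr * 100.0)

    @given(st.floats(0.01, 1e4), st.floats(0, 1e4), st.floats(0.01, 100))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, xr, xp, c):
        assert relative_error(c * xr, c * xp) == pytest.approx(
            relative_error(xr, xp), rel=1e-9, abs=1e-9
        )

    def test_not_symmetric_in_arguments(self):
        assert relative_error(10, 20) == 100.0
        assert relative_error(20, 10) == 50.0

    def test_zero_iff_equal(self):
        assert relative_error(3.5, 3.5) == 0.0
        assert relative_error(3.5, 3.6) > 0.0


class TestWordErrorRate:
    def test_identity_is_zero(self):
        toks = "the cat sat on the mat".split()
        assert word_error_rate(toks, toks) == 0.0

    def test_single_deletion(self):
        ref = "the cat sat on the mat".split()
        hyp = "the cat sat the mat".split()
        assert word_error_rate(ref, hyp) == pytest.approx(100 / 6)

    def test_substitution_plus_deletion(self):
        assert word_error_rate("a b c d".split(), "a x c".split()) == pytest.approx(50.0)

    def test_case_folded_before_alignment(self):
        assert word_error_rate(["The", "Cat"], ["the", "cat"]) == 0.0

    def test_empty_vs_empty(self):
        assert word_error_rate([], []) == 0.0

    def test_empty_reference_degenerate(self):
        assert word_error_rate([], ["a", "b"]) == 200.0

    def test_can_exceed_100_with_insertions(self):
        assert word_error_rate(["a"], ["a", "b", "c"]) == 200.0

    def test_matches_edlib_oracle_randomized(self):
        """Independent oracle: edlib Levenshtein on token lists mapped to
        characters."""
        import edlib

        rng = np.random.default_rng(21)
        alphabet = ["a", "b", "c", "d"]
        for _ in range(500):
            ref = [alphabet[i] for i in rng.integers(0, 4, rng.integers(1, 12))]
            hyp = [alphabet[i] for i in rng.integers(0, 4, rng.integers(0, 12))]
            expected = edlib.align("".join(hyp), "".join(ref))["editDistance"]
            assert word_error_rate(ref, hyp) == pytest.approx(expected / len(ref) * 100)

    def test_matches_recursive_enumeration_oracle(self):
        """Brute-force recursion over all edit scripts on tiny inputs."""

        def brute(r, h):
            if not r:
                return len(h)
            if not h:
                return len(r)
            return min(
                brute(r[1:], h[1:]) + (r[0] != h[0]),
                brute(r, h[1:]) + 1,
                brute(r[1:], h) + 1,
            )

        rng = np.random.default_rng(8)
        for _ in range(60):
            r = ["xyz"[i] for i in rng.integers(0, 3, rng.integers(1, 5))]
            h = ["xyz"[i] for i in rng.integers(0, 3, rng.integers(0, 5))]
            assert word_error_rate(r, h) == pytest.approx(brute(r, h) / len(r) * 100)


class TestMedianWer:
    def test_single_segment(self):
        assert median_wer([("a b".split(), "a c".split())]) == pytest.approx(50.0)

    def test_odd_count_median(self):
        segs = [
            ("a".split(), "a".split()),          # 0
            ("a b".split(), "a c".split()),      # 50
            ("a".split(), "b".split()),          # 100
        ]
        assert median_wer(segs) == pytest.approx(50.0)

    def test_even_count_mean_of_central_pair(self):
        wers = {10.0: ("a b c d e f g h i j".split(), "x b c d e f g h i j".split())}
        # construct segments with WERs 10, 20, 30, 1000 directly via median math
        vals = [10.0, 20.0, 30.0, 1000.0]
        assert float(np.median(vals)) == 25.0  # convention check for documentation
        segs = [
            ("a b c d e f g h i j".split(), "x b c d e f g h i j".split()),  # 10
            ("a b c d e".split(), "x b c d e".split()),                      # 20
            ("a b c d e f g h i j".split(), "x y z d e f g h i j".split()),  # 30
            ("a".split(), "b c d e f g h i j k l".split()),                  # 1000
        ]
        assert median_wer(segs) == pytest.approx(25.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            median_wer([])

    def test_order_invariant(self):
        segs = [
            ("a b".split(), "a b".split()),
            ("a b".split(), "a c".split()),
            ("a".split(), "b".split()),
        ]
        assert median_wer(segs) == median_wer(list(reversed(segs)))


class TestMakeWindows:
    def _transcripts(self, span_s, text="hello there", step=30.0):
        utts = []
        t = 0.0
        while t < span_s:
            utts.append(make_utt("T1", t, min(t + 2.0, span_s), text, "teacher"))
            t += step
        ref = make_transcript(utts, focal=None)
        pred = make_transcript(list(utts), focal=None, provenance="predicted")
        return ref, pred

    def test_exact_tiling(self, cfg):
        ref, pred = self._transcripts(720.0)
        # last utterance offset is 692, span = 692 s -> 2 windows
        windows = make_windows(ref, pred, cfg)
        assert len(windows) == 2
        assert not windows[0].partial

    def test_partial_final_window_kept_and_flagged(self, cfg):
        # the study's teacher-talk corpus length: 47.42 min = 2845.2 s
        ref, pred = self._transcripts(2845.2, step=10.0)
        windows = make_windows(ref, pred, cfg)
        assert len(windows) == 8  # ceil(47.42 / 6)
        assert windows[-1].partial
        assert not any(w.partial for w in windows[:-1])
        # 7 full six-minute windows + one 5.42-minute remainder
        assert (windows[-1].end - windows[-1].start) / 60 < 6.0

    def test_onset_on_boundary_goes_to_later_window(self, cfg):
        utts = [
            make_utt("T1", 0.0, 1.0, "first", "teacher"),
            make_utt("T1", 360.0, 361.0, "second", "teacher"),
        ]
        ref = make_transcript(utts, focal=None)
        windows = make_windows(ref, ref, cfg)
        assert windows[0].X_r.UT == 1
        assert windows[1].X_r.UT == 1

    def test_empty_both_rejected(self, cfg):
        ref = make_transcript([], focal=None)
        with pytest.raises(ValidationError):
            make_windows(ref, ref, cfg)


def _const_windows(pairs):
    """EvalWindows from a list of (X_r dict, X_p dict) index values."""
    out = []
    for j, (xr, xp) in enumerate(pairs, start=1):
        out.append(
            EvalWindow(j, (j - 1) * 360.0, j * 360.0, IndexVector(**xr), IndexVector(**xp))
        )
    return out


class TestSummarizeAccuracy:
    def test_perfect_prediction(self):
        ws = _const_windows([
            ({"UT": k, "WD": 3 * k}, {"UT": k, "WD": 3 * k}) for k in (2, 5, 9, 4)
        ])
        rep = summarize_accuracy(ws)
        assert rep.per_index["UT"].err_median == 0.0
        assert rep.per_index["UT"].r == pytest.approx(1.0)
        assert rep.per_index["WD"].err_median == 0.0

    def test_doubling_gives_100_and_r_1(self):
        ws = _const_windows([
            ({"WD": k}, {"WD": 2 * k}) for k in (3, 7, 11, 5)
        ])
        a = summarize_accuracy(ws).per_index["WD"]
        assert a.err_median == pytest.approx(100.0)
        assert a.r == pytest.approx(1.0)  # correlation is scale-blind

    def test_median_robust_to_outlier(self):
        # errors 10, 20, 1000 percent
        ws = _const_windows([
            ({"WD": 100}, {"WD": 110}),
            ({"WD": 100}, {"WD": 120}),
            ({"WD": 10}, {"WD": 110}),
        ])
        assert summarize_accuracy(ws).per_index["WD"].err_median == pytest.approx(20.0)

    def test_zero_reference_windows_excluded_and_counted(self):
        ws = _const_windows([
            ({"WD": 0}, {"WD": 5}),
            ({"WD": 10}, {"WD": 10}),
            ({"WD": 20}, {"WD": 10}),
        ])
        a = summarize_accuracy(ws).per_index["WD"]
        assert a.n_excluded_zero_ref == 1
        assert a.err_median == pytest.approx(25.0)  # median of {0, 50}

    def test_missing_ratio_indices_excluded(self):
        # UT=0 windows carry MLU=None; they must not poison the summary
        ws = _const_windows([
            ({"MLU": None}, {"MLU": None}),
            ({"MLU": 5.0}, {"MLU": 5.0}),
            ({"MLU": 4.0}, {"MLU": 2.0}),
        ])
        a = summarize_accuracy(ws).per_index["MLU"]
        assert a.n_excluded_missing == 1
        assert a.err_median == pytest.approx(25.0)

    def test_all_undefined_marked_not_evaluable(self):
        ws = _const_windows([({"CC": 0}, {"CC": 2}), ({"CC": 0}, {"CC": 0})])
        a = summarize_accuracy(ws).per_index["CC"]
        assert not a.evaluable
        assert a.err_median is None

    def test_anticorrelated_r_minus_one(self):
        ws = _const_windows([({"WD": k}, {"WD": 30 - k}) for k in (3, 7, 11, 5)])
        assert summarize_accuracy(ws).per_index["WD"].r == pytest.approx(-1.0)

    def test_err_median_window_order_invariant(self):
        ws = _const_windows([({"WD": 10}, {"WD": k}) for k in (11, 15, 9, 30)])
        a = summarize_accuracy(ws).per_index["WD"].err_median
        b = summarize_accuracy(list(reversed(ws))).per_index["WD"].err_median
        assert a == b


class TestBoundaryAgreement:
    def _shifted(self, shift):
        utts = [
            make_utt("T1", 10.0 + 20 * i, 12.0 + 20 * i, f"utt {i}", "teacher")
            for i in range(5)
        ]
        ref = make_transcript(utts, focal=None)
        pred = make_transcript(
            [make_utt(u.speaker_id, u.onset + shift, u.offset + shift, u.raw_text, "teacher")
             for u in utts],
            focal=None, provenance="predicted",
        )
        return ref, pred

    def test_identical_transcripts(self, cfg):
        ref, _ = self._shifted(0.0)
        assert boundary_agreement(ref, ref, cfg) == (100.0, 100.0)

    def test_200ms_shift_within_tolerance(self, cfg):
        onset_pct, offset_pct = boundary_agreement(*self._shifted(0.2), cfg)
        assert onset_pct == 100.0 and offset_pct == 100.0

    def test_300ms_shift_outside_tolerance(self, cfg):
        onset_pct, offset_pct = boundary_agreement(*self._shifted(0.3), cfg)
        assert onset_pct == 0.0 and offset_pct == 0.0

    def test_unmatched_reference_counts_as_disagreement(self, cfg):
        ref, pred = self._shifted(0.0)
        pred_half = make_transcript(pred.utterances[:2], focal=None, provenance="predicted")
        onset_pct, _ = boundary_agreement(ref, pred_half, cfg)
        assert onset_pct == pytest.approx(100.0 * 2 / 5)

    def test_empty_rejected(self, cfg):
        ref, _ = self._shifted(0.0)
        with pytest.raises(ValidationError):
            boundary_agreement(ref, make_transcript([], focal=None), cfg)


class TestConvergence:
    def test_perfect_curve_flat_at_zero(self):
        ws = _const_windows([({"WD": k}, {"WD": k}) for k in (3, 5, 7, 9, 11, 13)])
        curve, flatness = convergence_curve(ws, "WD")
        assert [k for k, _, _ in curve] == [3, 4, 5, 6]
        assert all(e == 0.0 for _, e, _ in curve)
        assert flatness == 0.0

    def test_noise_curve_settles(self):
        rng = np.random.default_rng(17)
        ws = _const_windows([
            ({"WD": 100}, {"WD": int(100 * (1 + 0.2 * rng.standard_normal()))})
            for _ in range(40)
        ])
        curve, flatness = convergence_curve(ws, "WD")
        errs = [e for _, e, _ in curve]
        # cumulative medians move less over the last quarter than the first
        first_q = max(errs[:10]) - min(errs[:10])
        assert flatness <= first_q + 1e-9

    def test_two_windows_not_evaluable(self):
        ws = _const_windows([({"WD": 1}, {"WD": 1}), ({"WD": 2}, {"WD": 2})])
        with pytest.raises(NotEvaluableError):
            convergence_curve(ws, "WD")

    def test_unknown_index_rejected(self):
        ws = _const_windows([({"WD": 1}, {"WD": 1})] * 3)
        with pytest.raises(ValidationError):
            convergence_curve(ws, "XX")


class TestTranscriptionCost:
    def test_classroom_example(self):
        assert estimate_transcription_cost(18, 60, 4) == pytest.approx(432.0)

    def test_unit_case(self):
        assert estimate_transcription_cost(1, 10, 4) == pytest.approx(4.0)

    def test_timestamp_and_transcribe_rate(self):
        assert estimate_transcription_cost(6, 10, 5) == pytest.approx(30.0)

    @pytest.mark.parametrize("args", [(0, 10, 4), (5, -1, 4), (5, 10, 0)])
    def test_nonpositive_rejected(self, args):
        with pytest.raises(ValidationError):
            estimate_transcription_cost(*args)


class TestEvaluateTopLevel:
    def test_self_comparison_is_perfect(self, cfg, classroom_transcript):
        pred = make_transcript(
            list(classroom_transcript.utterances), provenance="predicted"
        )
        rep = evaluate(classroom_transcript, pred, cfg)
        for name in INDEX_NAMES:
            a = rep.per_index[name]
            if a.evaluable:
                assert a.err_median == 0.0
        assert all(v == 0.0 for v in rep.mwer.values())
        assert rep.onset_agreement_pct == 100.0

    def test_mismatched_recording_ids_rejected(self, cfg, classroom_transcript):
        other = make_transcript(
            [make_utt("T1", 0, 1, "hi", "teacher", rec="rec2")],
            rec="rec2", provenance="predicted",
        )
        with pytest.raises(ValidationError):
            evaluate(classroom_transcript, other, cfg)
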