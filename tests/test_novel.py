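"""Hairpin candidate excision, criteria funnel and nucleotide bias."""

from __future__ import annotations

import numpy as np
import pytest

from trichomir._seq import revcomp
from trichomir.novel import (
    CandidateWindow,
    NovelConfig,
    bias_summary,
    evaluate_hairpin,
    extract_precursor_candidates,
    nucleotide_bias,
    predict_novel,
)
from trichomir.tag_mapping import TagHit

CFG = NovelConfig()


def _stem_precursor(mature: str, ext: int = 18) -> tuple[str, int]:
    """Perfect-stem hairpin with the mature at the 5' arm start; returns
    (precursor, mature offset)."""
    rng = np.random.default_rng(len(mature))
    extension = "".join("ACGU"[i] for i in rng.integers(0, 4, ext))
    stem5 = mature + extension
    return stem5 + "GAAACAAC" + revcomp(stem5), 0


def _window(seq: str, tag: str, off: int) -> CandidateWindow:
    return CandidateWindow(
        transcript_id="t", start=0, end=len(seq), tag=tag,
        tag_start=off, tag_end=off + len(tag), seq=seq,
    )


MATURE = "UGAGGUAGUAGGUUGUAUAGU"  # 21 nt


class TestExtraction:
    def _hit(self, start, length=21, tid="t1", strand="+"):
        tag = "ACGU" * 6
        return TagHit(tag[:length], tid, start, start + length, strand, 0)

    def test_two_flanked_windows_per_hit(self):
        transcriptome = {"t1": "A" * 1000}
        wins, skipped = extract_precursor_candidates([self._hit(400)], transcriptome)
        assert len(wins) == 2 and not skipped
        spans = {(w.start, w.end) for w in wins}
        assert spans == {(400 - CFG.flank, 421 + CFG.short_flank), (400 - CFG.short_flank, 421 + CFG.flank)}

    def test_window_clipped_at_transcript_start(self):
        transcriptome = {"t1": "A" * 1000}
        wins, _ = extract_precursor_candidates([self._hit(5)], transcriptome)
        assert all(w.start >= 0 for w in wins)
        assert min(w.start for w in wins) == 0

    def test_oversized_tag_skipped_with_reason(self):
        hit = TagHit("A" * 26, "t1", 100, 126, "+", 0)
        wins, skipped = extract_precursor_candidates([hit], {"t1": "A" * 1000})
        assert wins == [] and skipped[0][1] == "tag-length"

    def test_antisense_hit_skipped(self):
        hit = TagHit("ACGU" * 6, "t1", 100, 124, "-", 0)
        wins, skipped = extract_precursor_candidates([hit], {"t1": "A" * 1000})
        assert wins == [] and skipped[0][1] == "antisense"

    def test_windows_capped_at_max_precursor_length(self):
        cfg = NovelConfig(flank=400, max_precursor_len=350)
        wins, _ = extract_precursor_candidates([self._hit(500)], {"t1": "A" * 2000}, cfg)
        assert all(w.end - w.start <= 350 for w in wins)


class TestHairpinCriteria:
    def test_planted_precursor_accepted_on_correct_arm(self):
        pre, off = _stem_precursor(MATURE)
        cand = evaluate_hairpin(_window(pre, MATURE, off), support=10)
        assert cand.accepted and cand.reason == "none"
        assert cand.arm == "5p"
        assert cand.fold.energy <= -18.0
        assert cand.star_interval is not None

    def test_low_support_rejected_after_structure_checks(self):
        pre, off = _stem_precursor(MATURE)
        cand = evaluate_hairpin(_window(pre, MATURE, off), support=4)
        assert not cand.accepted and cand.reason == "support"

    def test_mature_straddling_terminal_loop_rejected(self):
        pre, _ = _stem_precursor(MATURE)
        # a 21-nt tag centered on the 8-nt terminal loop
        loop_start = len(pre) // 2 - 4
        tag = pre[loop_start - 7 : loop_start - 7 + 21]
        cand = evaluate_hairpin(_window(pre, tag, loop_start - 7), support=10)
        assert not cand.accepted and cand.reason == "in-loop"

    def test_unstructured_window_rejected_no_hairpin(self):
        seq = ("AAAAAC" * 30)[:150]
        cand = evaluate_hairpin(_window(seq, seq[30:51], 30), support=10)
        assert not cand.accepted and cand.reason == "no-hairpin"

    def test_mature_on_3p_arm_detected(self):
        pre5, _ = _stem_precursor(MATURE)
        mature_rc_start = pre5.find(revcomp(MATURE))
        cand = evaluate_hairpin(_window(pre5, revcomp(MATURE), mature_rc_start), support=10)
        assert cand.accepted and cand.arm == "3p"

    def test_tag_outside_window_rejected(self):
        pre, _ = _stem_precursor(MATURE)
        with pytest.raises(ValueError):
            evaluate_hairpin(_window(pre, MATURE, len(pre) - 5), support=10)


class TestPredictNovel:
    def test_duplicate_matures_collapse(self):
        pre, off = _stem_precursor(MATURE)
        transcriptome = {"t1": "U" * 100 + pre + "A" * 100, "t2": "C" * 80 + pre + "G" * 120}
        hits = [
            TagHit(MATURE, "t1", 100 + off, 100 + off + len(MATURE), "+", 0),
            TagHit(MATURE, "t2", 80 + off, 80 + off + len(MATURE), "+", 0),
        ]
        novel, candidates, _ = predict_novel(hits, transcriptome, {MATURE: 12})
        assert len(novel) == 1
        assert novel[0].mature == MATURE and novel[0].support == 12
        assert len(novel[0].candidates) >= 2
        # every candidate carries a machine-readable outcome
        assert all(c.reason == "none" if c.accepted else c.reason != "none" for c in candidates)

    def test_evaluation_order_invariance(self):
        pre, off = _stem_precursor(MATURE)
        transcriptome = {"t1": "U" * 60 + pre + "A" * 60}
        hit = TagHit(MATURE, "t1", 60 + off, 60 + off + len(MATURE), "+", 0)
        other = TagHit("ACGU" * 6, "t1", 10, 34, "+", 0)
        n1, _, _ = predict_novel([hit, other], transcriptome, {MATURE: 9, "ACGU" * 6: 9})
        n2, _, _ = predict_novel([other, hit], transcriptome, {MATURE: 9, "ACGU" * 6: 9})
        assert [n.mature for n in n1] == [n.mature for n in n2]


class TestNucleotideBias:
    def test_uniform_u_start(self):
        mat = nucleotide_bias(["U" + "ACG" * 6] * 10)
        assert mat[0, 3] == 1.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        seqs = ["".join("ACGU"[i] for i in rng.integers(0, 4, rng.integers(20, 23))) for _ in range(40)]
        mat = nucleotide_bias(seqs)
        assert np.allclose(mat.sum(axis=1), 1.0)

    def test_summary_reports_key_positions(self):
        seqs = ["UACGUACGUAACGUACGUACG"] * 4
        s = bias_summary(seqs)
        assert s["pos1_U"] == 1.0 and s["pos10_A"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_bias([])
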