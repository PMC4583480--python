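"""Six-rule target scoring, with a brute-force all-windows oracle."""

from __future__ import annotations

import numpy as np
import pytest

from trichomir._seq import revcomp
from trichomir.targets import (
    align_duplex,
    check_rules,
    predict_targets,
    render_alignment,
    score_duplex,
)

MIRNA = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt, mixed composition
L = len(MIRNA)


def _site(mm=(), gu=()):
    """Site with designed states at 1-based miRNA positions."""
    site = list(revcomp(MIRNA))
    for pos in mm:
        site[L - pos] = MIRNA[pos - 1]  # base facing itself never pairs
    for pos in gu:
        base = MIRNA[pos - 1]
        site[L - pos] = {"G": "U", "U": "G"}[base]
    return "".join(site)


def _hit(site):
    alns = align_duplex("m", MIRNA, "t", site, score_cutoff=float("inf"))
    aln = next(a for a in alns if a.start == 0 and a.end == len(site))
    return score_duplex(aln, site)


def brute_force_windows(mirna: str, transcript: str, cutoff: float):
    """Independent per-window scorer: plain python, no vectorization."""
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "U"), ("U", "G")}
    m = len(mirna)
    out = {}
    for s in range(len(transcript) - m + 1):
        window = transcript[s : s + m]
        score = 0.0
        for i in range(m):
            pair = (mirna[i], window[m - 1 - i])
            if pair in wc:
                continue
            score += 0.5 if pair in gu else 1.0
        if score < cutoff:
            out[s] = score
    return out


class TestAlignDuplex:
    def test_perfect_complement_single_alignment(self):
        transcript = "ACGU" * 10 + revcomp(MIRNA) + "GGCC" * 10
        alns = align_duplex("m", MIRNA, "t", transcript)
        exact = [a for a in alns if a.score == 0.0]
        assert len(exact) == 1 and exact[0].start == 40
        assert set(exact[0].states) == {"WC"}

    def test_no_window_under_cutoff_is_empty(self):
        assert align_duplex("m", "G" * 21, "t", "G" * 200) == []

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            align_duplex("m", "ACGUACGUACGU", "t", "ACGU" * 30)

    def test_agrees_with_brute_force_on_2kb_transcript(self):
        rng = np.random.default_rng(41)
        transcript = "".join("ACGU"[i] for i in rng.integers(0, 4, 2000))
        # plant a near-perfect site so at least one window survives the cutoff
        transcript = transcript[:700] + _site(mm=(16,)) + transcript[700 + L :]
        got = {a.start: a.score for a in align_duplex("m", MIRNA, "t", transcript)}
        assert got == brute_force_windows(MIRNA, transcript, 4.0)
        assert 700 in got


class TestRules:
    def test_perfect_site_passes_everything(self):
        hit = _hit(_site())
        assert hit.accepted and hit.rules == (True,) * 6
        assert hit.alignment.score == 0.0 and hit.mfe_ratio == pytest.approx(1.0)

    def test_mismatch_at_position_ten_fails_only_rule_four(self):
        hit = _hit(_site(mm=(10,)))
        assert not hit.accepted
        assert hit.rules[3] is False
        assert all(hit.rules[i] for i in (0, 1, 2, 4, 5))

    def test_eight_wobbles_reach_score_four_failing_rule_one(self):
        mirna = "ACCAGCUCCCAC" + "GUGUGUGUG"  # G/U-rich 3' half
        n = len(mirna)
        site = list(revcomp(mirna))
        for pos in range(13, 21):  # eight wobbles at positions 13-20
            site[n - pos] = {"G": "U", "U": "G"}[mirna[pos - 1]]
        site = "".join(site)
        alns = align_duplex("m", mirna, "t", site, score_cutoff=float("inf"))
        aln = next(a for a in alns if a.start == 0 and a.end == n)
        assert aln.score == pytest.approx(4.0)  # 8 x 0.5
        hit = score_duplex(aln, site)
        assert hit.rules[0] is False
        # and below the cutoff the window is not even emitted
        assert all(a.score < 4.0 for a in align_duplex("m", mirna, "t", site))

    def test_three_adjacent_mismatches_fail_rule_two(self):
        hit = _hit(_site(mm=(15, 16, 17)))
        assert hit.rules[1] is False and hit.rules[0] is True

    def test_adjacent_seed_mismatches_fail_rule_three(self):
        hit = _hit(_site(mm=(5, 6)))
        assert hit.rules[2] is False
        assert hit.rules[1] is True  # run of two is tolerated globally

    def test_seed_score_above_two_point_five_fails_rule_five(self):
        mirna = "UAGACGCGACAUCAUUCCAAU"  # G at positions 6 and 8
        n = len(mirna)
        site = list(revcomp(mirna))
        for pos in (2, 4):  # two mismatches, non-adjacent, outside 10-11
            site[n - pos] = mirna[pos - 1]
        for pos in (6, 8):  # two wobbles: seed score 2 + 2*0.5 = 3 > 2.5
            site[n - pos] = "U"
        site = "".join(site)
        alns = align_duplex("m", mirna, "t", site, score_cutoff=float("inf"))
        hit = score_duplex(next(a for a in alns if a.start == 0), site)
        assert hit.alignment.seed_score == pytest.approx(3.0)
        assert hit.rules[4] is False
        assert hit.rules[0] and hit.rules[1] and hit.rules[2] and hit.rules[3]

    def test_wobble_at_position_ten_passes_rule_four(self):
        # position 10 of this miRNA is C; use a shifted mature with U at 10
        mirna = "UGGAGCUCCUUUCAUUCCAAU"
        site = list(revcomp(mirna))
        site[len(mirna) - 10] = "G"  # U:G wobble at position 10
        alns = align_duplex("m", mirna, "t", "".join(site), score_cutoff=float("inf"))
        aln = next(a for a in alns if a.start == 0)
        assert aln.states[9] == "GU"
        hit = score_duplex(aln, "".join(site))
        assert hit.rules[3] is True

    def test_wc_to_mismatch_never_rescues_a_rejected_site(self):
        """Monotonicity: adding a mismatch to a rejected duplex keeps it rejected."""
        rng = np.random.default_rng(43)
        rejected = _hit(_site(mm=(10,)))
        assert not rejected.accepted
        for _ in range(20):
            pos = int(rng.integers(1, L + 1))
            hit = _hit(_site(mm=tuple({10, pos})))
            assert not hit.accepted


class TestPredictTargets:
    def test_exact_sites_found_and_counted(self):
        transcriptome = {
            "t1": "ACGU" * 25 + revcomp(MIRNA) + "UGCA" * 25,
            "t2": "CAGU" * 50,
        }
        hits, counts = predict_targets({"mirX": MIRNA}, transcriptome)
        accepted = [h for h in hits if h.accepted]
        assert counts == {"mirX": len(accepted)}
        assert any(h.alignment.transcript_id == "t1" and h.alignment.start == 100 for h in accepted)

    def test_mirna_without_targets_absent_from_counts(self):
        _, counts = predict_targets({"mirY": "G" * 21}, {"t1": "G" * 300})
        assert counts == {}

    def test_render_alignment_shape(self):
        site = _site()
        hit = _hit(site)
        text = render_alignment(hit, site)
        assert MIRNA in text and "|" in text
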