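"""Mismatch-bounded mapping (with a brute-force Hamming oracle) and the
category partition."""

from __future__ import annotations

import numpy as np
import pytest

from trichomir._seq import revcomp
from trichomir.preprocess import collapse_tags
from trichomir.tag_mapping import (
    CATEGORY_PRIORITY,
    annotate_tags,
    build_index,
    map_tags,
)


def _random_seq(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


def brute_force_hits(tag: str, transcripts: dict[str, str], max_mm: int):
    """Independent exhaustive Hamming scan over every window, both strands."""
    found = set()
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        for tid, seq in transcripts.items():
            for start in range(len(seq) - len(query) + 1):
                window = seq[start : start + len(query)]
                d = sum(a != b for a, b in zip(query, window))
                if d <= max_mm:
                    found.add((tid, start, strand, d))
    return found


class TestIndex:
    def test_seed_positions_single_transcript(self):
        idx = build_index({"t1": "A" * 50 + "CGU" * 17}, k=8)
        # L - k + 1 positions for a 101-nt transcript
        assert idx.n_seed_positions == len(idx.transcripts["t1"]) - 8 + 1

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            build_index({})

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            build_index([type("R", (), {"id": "a", "seq": "ACGU" * 10})()] * 2)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(5)
    transcripts = {f"t{i}": _random_seq(rng, 1000) for i in range(5)}
    return transcripts, rng


class TestMapping:

    def test_exact_substring_maps_sense(self, toy):
        transcripts, _ = toy
        tag = transcripts["t2"][100:122]
        idx = build_index(transcripts)
        hits = [h for h in map_tags([tag], idx, 0) if h.strand == "+"]
        assert any(h.transcript_id == "t2" and h.start == 100 and h.mismatches == 0 for h in hits)

    def test_three_mismatches_not_reported_at_max_one(self, toy):
        transcripts, _ = toy
        tag = list(transcripts["t0"][50:72])
        for i in (3, 9, 15):
            tag[i] = {"A": "C", "C": "G", "G": "U", "U": "A"}[tag[i]]
        tag = "".join(tag)
        idx = build_index(transcripts)
        hits = map_tags([tag], idx, max_mismatch=1)
        assert not any(h.transcript_id == "t0" and h.start == 50 for h in hits)

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_agrees_with_brute_force_scan(self, toy, max_mm):
        """Pigeonhole seeding finds exactly the exhaustive-scan hit set."""
        transcripts, _ = toy
        rng = np.random.default_rng(17)
        idx = build_index(transcripts)
        tags = []
        for _ in range(20):
            tid = f"t{rng.integers(0, 5)}"
            start = int(rng.integers(0, 950))
            length = int(rng.integers(18, 26))
            tag = list(transcripts[tid][start : start + length])
            for i in rng.choice(length, size=rng.integers(0, 3), replace=False):
                tag[i] = "ACGU"[int(rng.integers(0, 4))]
            tags.append("".join(tag))
        tags.append(_random_seq(rng, 21))  # almost surely unmapped
        for tag in tags:
            got = {(h.transcript_id, h.start, h.strand, h.mismatches) for h in map_tags([tag], idx, max_mm)}
            assert got == brute_force_hits(tag, transcripts, max_mm)

    def test_non_rna_tag_skipped(self, toy):
        transcripts, _ = toy
        idx = build_index(transcripts)
        assert map_tags(["ACGTNNACGTACGTACGTACGT"], idx, 1) == []

    def test_negative_mismatch_rejected(self, toy):
        idx = build_index(toy[0])
        with pytest.raises(ValueError):
            map_tags(["ACGU" * 6], idx, -1)


class TestAnnotation:
    def test_priority_rrna_over_trna(self):
        tag_seq = "ACGUACGUACGUACGUACGUACGU"
        tags = collapse_tags({"leaves": {tag_seq: 5}})
        ncrna = {"rRNA": ["GG" + tag_seq + "CC"], "tRNA": ["AA" + tag_seq + "UU"]}
        part = annotate_tags(tags, ncrna, {})
        assert part.categories[tag_seq] == "rRNA"

    def test_unmatched_tag_is_unannotated(self):
        tags = collapse_tags({"leaves": {"CCGGAAUUCCGGAAUUCCGGAA": 1}})
        part = annotate_tags(tags, {"rRNA": ["A" * 40]}, {})
        assert part.categories["CCGGAAUUCCGGAAUUCCGGAA"] == "unannotated"

    def test_mirna_assignment_wins_over_nothing(self):
        seq = "UGGAGCUCCCUUCAUUCCAAU"
        tags = collapse_tags({"leaves": {seq: 2}})
        part = annotate_tags(tags, {}, {seq: object()})
        assert part.categories[seq] == "miRNA"

    def test_partition_conserves_totals(self):
        rng = np.random.default_rng(23)
        seqs = {"leaves": {}, "trichomes": {}}
        for _ in range(30):
            s = _random_seq(rng, 22)
            seqs["leaves"][s] = int(rng.integers(1, 50))
            seqs["trichomes"][s] = int(rng.integers(0, 50))
        tags = collapse_tags(seqs)
        ncrna = {"rRNA": [list(seqs["leaves"])[0]], "snRNA": [list(seqs["leaves"])[1]]}
        part = annotate_tags(tags, ncrna, {list(seqs["leaves"])[2]: object()})
        summary = part.summary.set_index("category")
        for lib in ("leaves", "trichomes"):
            cat_total = summary.loc[list(CATEGORY_PRIORITY), f"total_{lib}"].sum()
            assert cat_total == summary.loc["total", f"total_{lib}"]
            assert cat_total == sum(seqs[lib].values())
        # each tag in exactly one category
        assert set(part.categories) == {t.seq for t in tags}
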