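"""Novel miRNA prediction from unannotated mapped tags.

For every transcriptome hit of an unannotated 18–25 nt tag, two candidate
precursor windows are excised (tag near the 5' end with a long downstream
flank, and vice versa), folded, and pushed through the hairpin criteria in a
fixed order:

(a) the fold contains at least one hairpin;
(b) the mature tag lies entirely on one arm (it never straddles the
    terminal loop);
(c) within the mature:star duplex region there is no internal loop or bulge
    larger than the configured maximum, and the mature has at most the
    configured number of unpaired bases;
(d) the folding free energy is at or below the energy threshold
    (-18 kcal/mol by default);
(e) read support of the mature tag summed over both libraries reaches the
    minimum (5 reads by default).

The first failed check is recorded as the rejection reason, giving an
auditable accept/reject funnel.  Candidates sharing one mature sequence are
collapsed into a single reported novel miRNA.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from . import rna_structure
from .rna_structure import FoldResult
from .tag_mapping import TagHit

REJECTION_REASONS = ("none", "unmapped", "no-hairpin", "in-loop", "large-bulge", "energy", "support")


@dataclass
class NovelConfig:
    min_tag_len: int = 18
    max_tag_len: int = 25
    flank: int = 150  # long-side flank when excising candidate windows
    short_flank: int = 20  # short-side flank
    max_precursor_len: int = 350
    max_bulge: int = 4  # largest tolerated loop/bulge inside the mature:star duplex
    max_unpaired_mature: int = 6
    energy_threshold: float = -18.0  # kcal/mol
    min_support: int = 5  # summed read count over both libraries


@dataclass(frozen=True)
class CandidateWindow:
    """An excised putative-precursor window around one tag hit."""

    transcript_id: str
    start: int  # window interval on the transcript, 0-based half-open
    end: int
    tag: str
    tag_start: int  # tag interval on the transcript
    tag_end: int
    seq: str

    @property
    def tag_offset(self) -> int:
        return self.tag_start - self.start


@dataclass
class HairpinCandidate:
    """An evaluated putative precursor with its accept/reject trace."""

    window: CandidateWindow
    fold: FoldResult | None
    arm: str | None  # '5p' | '3p'
    star_interval: tuple[int, int] | None  # window coordinates
    support: int
    accepted: bool
    reason: str  # one of REJECTION_REASONS; 'none' iff accepted


def extract_precursor_candidates(
    hits: Iterable[TagHit],
    transcriptome: Mapping[str, str],
    cfg: NovelConfig = NovelConfig(),
) -> tuple[list[CandidateWindow], list[tuple[TagHit, str]]]:
    """Excise up to two candidate windows per sense tag hit.

    Returns (windows, skipped) where skipped pairs each unusable hit with a
    reason.  Tags outside the 18–25 nt window cannot seed a candidate.
    """
    windows: list[CandidateWindow] = []
    skipped: list[tuple[TagHit, str]] = []
    seen: set[tuple[str, int, int, str]] = set()
    for hit in hits:
        if not (cfg.min_tag_len <= len(hit.tag) <= cfg.max_tag_len):
            skipped.append((hit, "tag-length"))
            continue
        if hit.strand != "+":
            skipped.append((hit, "antisense"))
            continue
        transcript = transcriptome[hit.transcript_id]
        for long_side in ("upstream", "downstream"):
            if long_side == "upstream":  # tag on the 3' arm
                lo, hi = hit.start - cfg.flank, hit.end + cfg.short_flank
            else:  # tag on the 5' arm
                lo, hi = hit.start - cfg.short_flank, hit.end + cfg.flank
            lo, hi = max(0, lo), min(len(transcript), hi)
            if hi - lo > cfg.max_precursor_len:
                # trim the long-flank side, keeping the tag inside the window
                if long_side == "upstream":
                    lo = hi - cfg.max_precursor_len
                else:
                    hi = lo + cfg.max_precursor_len
            key = (hit.transcript_id, lo, hi, hit.tag)
            if key in seen:
                continue
            seen.add(key)
            windows.append(
                CandidateWindow(
                    transcript_id=hit.transcript_id,
                    start=lo,
                    end=hi,
                    tag=hit.tag,
                    tag_start=hit.start,
                    tag_end=hit.end,
                    seq=transcript[lo:hi],
                )
            )
    return windows, skipped


def _hairpin_loops(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Innermost pairs (hairpin-closing pairs) of a secondary structure."""
    loops = []
    for i, j in pairs:
        if not any(i < a and b < j for a, b in pairs):
            loops.append((i, j))
    return loops


def evaluate_hairpin(
    window: CandidateWindow,
    support: int,
    cfg: NovelConfig = NovelConfig(),
) -> HairpinCandidate:
    """Apply the hairpin criteria to one candidate window."""
    ms, me = window.tag_offset, window.tag_offset + len(window.tag)
    if window.seq[ms:me] == "" or ms < 0 or me > len(window.seq):
        raise ValueError("tag interval falls outside the candidate window")

    fold = rna_structure.fold(window.seq)

    def reject(reason: str, arm: str | None = None) -> HairpinCandidate:
        return HairpinCandidate(window, fold, arm, None, support, False, reason)

    partner = {}
    for a, b in fold.pairs:
        partner[a] = b
        partner[b] = a
    if not _hairpin_loops(fold.pairs):
        return reject("no-hairpin")

    mature_positions = list(range(ms, me))
    paired = [p for p in mature_positions if p in partner]
    unpaired = len(mature_positions) - len(paired)
    if not paired:
        return reject("no-hairpin")
    partners = [partner[p] for p in paired]
    # the mature must sit entirely on one arm: all partners on one side
    if min(partners) >= me:
        arm = "5p"
    elif max(partners) < ms:
        arm = "3p"
    else:
        return reject("in-loop")
    if unpaired > cfg.max_unpaired_mature:
        return reject("large-bulge", arm)
    # bulge/internal-loop sizes between consecutive paired mature bases
    for p, q in zip(paired, paired[1:]):
        gap_mature = q - p - 1
        gap_star = abs(partner[p] - partner[q]) - 1
        if max(gap_mature, gap_star) > cfg.max_bulge:
            return reject("large-bulge", arm)
    if fold.energy > cfg.energy_threshold:
        return reject("energy", arm)
    if support < cfg.min_support:
        return reject("support", arm)

    star_lo, star_hi = min(partners), max(partners) + 1
    # conventional 2-nt 3' overhang of the star relative to the mature duplex
    if arm == "5p":
        star = (max(0, star_lo - 2), star_hi)
    else:
        star = (star_lo, min(len(window.seq), star_hi + 2))
    return HairpinCandidate(window, fold, arm, star, support, True, "none")


@dataclass
class NovelMiRNA:
    """A deduplicated accepted novel miRNA (one per mature sequence)."""

    mature: str
    arm: str
    support: int
    candidates: tuple[HairpinCandidate, ...]

    @property
    def best(self) -> HairpinCandidate:
        return min(self.candidates, key=lambda c: c.fold.energy)


def predict_novel(
    hits: Iterable[TagHit],
    transcriptome: Mapping[str, str],
    tag_support: Mapping[str, int],
    cfg: NovelConfig = NovelConfig(),
) -> tuple[list[NovelMiRNA], list[HairpinCandidate], list[tuple[TagHit, str]]]:
    """Full novel-miRNA stage: excision, evaluation, deduplication.

    ``tag_support`` maps tag sequence to its summed read count over both
    libraries.  Returns (accepted novel miRNAs, all evaluated candidates,
    skipped hits).
    """
    windows, skipped = extract_precursor_candidates(hits, transcriptome, cfg)
    candidates = [evaluate_hairpin(w, tag_support.get(w.tag, 0), cfg) for w in windows]
    by_mature: dict[str, list[HairpinCandidate]] = {}
    for c in candidates:
        if c.accepted:
            by_mature.setdefault(c.window.tag, []).append(c)
    novel = [
        NovelMiRNA(
            mature=mature,
            arm=cands[0].arm,
            support=cands[0].support,
            candidates=tuple(cands),
        )
        for mature, cands in sorted(by_mature.items())
    ]
    return novel, candidates, skipped


def nucleotide_bias(matures: Sequence[str]) -> np.ndarray:
    """Position x base frequency matrix over mature sequences.

    Row ``i`` holds the A/C/G/U frequencies at position ``i+1`` (from the 5'
    end) among the matures long enough to have that position; each row sums
    to 1.
    """
    if not matures:
        raise ValueError("no mature sequences")
    max_len = max(len(m) for m in matures)
    order = "ACGU"
    mat = np.zeros((max_len, 4))
    for pos in range(max_len):
        counts = Counter(m[pos] for m in matures if len(m) > pos)
        total = sum(counts.values())
        for j, base in enumerate(order):
            mat[pos, j] = counts.get(base, 0) / total
    return mat


def bias_summary(matures: Sequence[str]) -> dict[str, float]:
    """First-position U fraction and tenth-position A fraction."""
    mat = nucleotide_bias(matures)
    out = {"pos1_U": float(mat[0, 3])}
    if mat.shape[0] >= 10:
        out["pos10_A"] = float(mat[9, 0])
    return out
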