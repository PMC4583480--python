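"""Mismatch-bounded mapping of tags to a transcriptome, and tag annotation.

Mapping uses pigeonhole seeding: a tag matching with at most *m* mismatches
must contain at least one of *m*+1 disjoint exact seed k-mers, so exact seed
lookups followed by full Hamming verification enumerate *all* hits — the
index is exhaustive, not heuristic.  Annotation partitions the tag set into
ncRNA categories, conserved miRNA and unannotated with a fixed elimination
priority, producing the category-accounting table of a small-RNA study.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from ._seq import best_substring_match, hamming_capped, is_rna, normalize_rna, revcomp
from .io import FastaRecord
from .preprocess import UniqueTag

NCRNA_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA")
# elimination-first priority: ncRNAs are removed before miRNA detection
CATEGORY_PRIORITY = NCRNA_CATEGORIES + ("miRNA", "unannotated")


@dataclass(frozen=True)
class TagHit:
    """One placement of a tag on a transcript."""

    tag: str
    transcript_id: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' sense, '-' antisense
    mismatches: int


@dataclass
class TranscriptomeIndex:
    """Exact k-mer seed index over a transcriptome (RNA alphabet)."""

    transcripts: dict[str, str]
    k: int
    seeds: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError("empty transcriptome")
        if self.k < 4:
            raise ValueError("seed length k must be >= 4")
        if not self.seeds:
            for tid, seq in self.transcripts.items():
                for pos in range(len(seq) - self.k + 1):
                    self.seeds.setdefault(seq[pos : pos + self.k], []).append((tid, pos))

    @property
    def n_seed_positions(self) -> int:
        return sum(len(v) for v in self.seeds.values())


def build_index(transcriptome: Mapping[str, str] | Sequence[FastaRecord], k: int = 6) -> TranscriptomeIndex:
    """Build the seed index; transcript sequences are normalized to RNA."""
    if isinstance(transcriptome, Mapping):
        items = list(transcriptome.items())
    else:
        items = [(r.id, r.seq) for r in transcriptome]
    transcripts: dict[str, str] = {}
    for tid, seq in items:
        if tid in transcripts:
            raise ValueError(f"duplicate transcript id {tid!r}")
        transcripts[tid] = normalize_rna(seq)
    return TranscriptomeIndex(transcripts=transcripts, k=k)


def _map_oriented(query: str, index: TranscriptomeIndex, max_mismatch: int) -> set[tuple[str, int]]:
    """All (transcript, start) placements of ``query`` within ``max_mismatch``."""
    k = index.k
    n_seeds = max_mismatch + 1
    if n_seeds * k > len(query):
        raise ValueError(
            f"tag length {len(query)} too short for k={k} with max_mismatch={max_mismatch}"
        )
    placements: set[tuple[str, int]] = set()
    checked: set[tuple[str, int]] = set()
    for j in range(n_seeds):
        off = j * k
        for tid, pos in index.seeds.get(query[off : off + k], ()):
            start = pos - off
            key = (tid, start)
            if start < 0 or key in checked:
                continue
            checked.add(key)
            target = index.transcripts[tid]
            if start + len(query) > len(target):
                continue
            d = hamming_capped(query, target[start : start + len(query)], max_mismatch)
            if d <= max_mismatch:
                placements.add(key)
    return placements


def map_tags(
    tags: Iterable[str],
    index: TranscriptomeIndex,
    max_mismatch: int = 1,
    both_strands: bool = True,
) -> list[TagHit]:
    """All transcriptome hits of each tag with at most ``max_mismatch`` mismatches.

    Tags containing non-ACGU symbols are skipped (reported via a warning list
    on the returned hits' side would be noise; callers filter upstream).
    Deterministic order: (tag, transcript id, position, strand).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    hits: list[TagHit] = []
    for tag in tags:
        tag = normalize_rna(tag)
        if not is_rna(tag):
            continue
        for tid, start in _map_oriented(tag, index, max_mismatch):
            seq = index.transcripts[tid][start : start + len(tag)]
            hits.append(
                TagHit(tag, tid, start, start + len(tag), "+", sum(a != b for a, b in zip(tag, seq)))
            )
        if both_strands:
            rc = revcomp(tag)
            for tid, start in _map_oriented(rc, index, max_mismatch):
                seq = index.transcripts[tid][start : start + len(tag)]
                hits.append(
                    TagHit(tag, tid, start, start + len(tag), "-", sum(a != b for a, b in zip(rc, seq)))
                )
    hits.sort(key=lambda h: (h.tag, h.transcript_id, h.start, h.strand))
    return hits


def matches_reference(tag: str, references: Iterable[str], max_mismatch: int = 1) -> bool:
    """Tag matches a reference if it is an exact substring of one, or lies
    within one full-length with at most ``max_mismatch`` mismatches."""
    for ref in references:
        if tag in ref:
            return True
        if max_mismatch > 0 and best_substring_match(tag, ref, max_mismatch) is not None:
            return True
    return False


@dataclass
class CategoryPartition:
    """Per-tag category and the per-category accounting per library."""

    categories: dict[str, str]  # tag seq -> category
    summary: pd.DataFrame  # category x (unique/total per library)


def annotate_tags(
    tags: Sequence[UniqueTag],
    ncrna_reference: Mapping[str, Sequence[str]],
    mirna_assignments: Mapping[str, object],
    libraries: Sequence[str] | None = None,
    max_mismatch: int = 1,
) -> CategoryPartition:
    """Partition tags into ncRNA categories, conserved miRNA and unannotated.

    Priority order rRNA > tRNA > snRNA > snoRNA > miRNA > unannotated: a tag
    matching several references is counted once, in the highest-priority
    category, so the categories partition the tag set exactly.
    """
    if libraries is None:
        libraries = sorted({lib for t in tags for lib in t.counts})
    categories: dict[str, str] = {}
    for tag in tags:
        category = "unannotated"
        for cat in NCRNA_CATEGORIES:
            refs = [normalize_rna(r) for r in ncrna_reference.get(cat, ())]
            if refs and matches_reference(tag.seq, refs, max_mismatch):
                category = cat
                break
        if category == "unannotated" and tag.seq in mirna_assignments:
            category = "miRNA"
        categories[tag.seq] = category

    rows = []
    unique: dict[str, Counter[str]] = {lib: Counter() for lib in libraries}
    totals: dict[str, Counter[str]] = {lib: Counter() for lib in libraries}
    for tag in tags:
        cat = categories[tag.seq]
        for lib in libraries:
            n = tag.count(lib)
            if n > 0:
                unique[lib][cat] += 1
                totals[lib][cat] += n
    grand_unique = {lib: sum(unique[lib].values()) for lib in libraries}
    grand_total = {lib: sum(totals[lib].values()) for lib in libraries}
    for cat in CATEGORY_PRIORITY:
        row: dict[str, object] = {"category": cat}
        for lib in libraries:
            u, t = unique[lib][cat], totals[lib][cat]
            row[f"unique_{lib}"] = u
            row[f"unique_pct_{lib}"] = 100.0 * u / grand_unique[lib] if grand_unique[lib] else 0.0
            row[f"total_{lib}"] = t
            row[f"total_pct_{lib}"] = 100.0 * t / grand_total[lib] if grand_total[lib] else 0.0
        rows.append(row)
    total_row: dict[str, object] = {"category": "total"}
    for lib in libraries:
        total_row[f"unique_{lib}"] = grand_unique[lib]
        total_row[f"unique_pct_{lib}"] = 100.0
        total_row[f"total_{lib}"] = grand_total[lib]
        total_row[f"total_pct_{lib}"] = 100.0
    rows.append(total_row)
    return CategoryPartition(categories=categories, summary=pd.DataFrame(rows))
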