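"""Seven-step small-RNA read cleaning and tag collapsing.

Raw 49-nt single-end reads are filtered and trimmed in a fixed order, each
read accounted for in exactly one category:

1. low-quality reads (more than four bases with quality below 10, or more
   than six bases with quality below 13);
2. reads contaminated by the 5' adapter at the read start;
3. reads in which the 3' adapter cannot be located ("3' adapter null");
4. reads whose insert is empty after trimming (adapter dimers);
5. poly(A) inserts;
6. inserts shorter than 18 nt (and, kept as a distinguishable extra
   category, inserts longer than the 30-nt size-selection bound).

Survivors are trimmed to the insert, normalized to RNA alphabet and collapsed
into unique tags with per-library read counts.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, fields

from ._seq import normalize_rna

# categories in removal order; 'oversize' extends the usual accounting table
REMOVAL_CATEGORIES = (
    "low_quality",
    "adapter5_contaminant",
    "adapter3_null",
    "insert_null",
    "polya",
    "short",
    "oversize",
)


@dataclass
class CleanConfig:
    """Thresholds and adapter definitions for read cleaning."""

    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    q_low: int = 10  # a read dies with > q_low_max bases below this
    q_low_max: int = 4
    q_mid: int = 13  # ... or > q_mid_max bases below this
    q_mid_max: int = 6
    min_insert: int = 18
    max_insert: int = 30
    polya_fraction: float = 0.9
    adapter3_min_overlap: int = 7
    adapter3_max_mismatch: int = 1
    adapter5_seed: int = 5  # exact 5'-adapter prefix length flagging contamination
    phred_offset: int = 33


@dataclass
class FilterStats:
    """Read accounting in the shape of a sequencing-statistics table."""

    library: str = ""
    total_raw: int = 0
    high_quality: int = 0
    low_quality: int = 0
    adapter5_contaminant: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    polya: int = 0
    short: int = 0
    oversize: int = 0
    clean: int = 0
    unique_tags: int = 0

    def check(self) -> None:
        removed = sum(getattr(self, c) for c in REMOVAL_CATEGORIES if c != "low_quality")
        if self.high_quality != self.clean + removed:
            raise AssertionError("filter accounting broken: high_quality != clean + removals")
        if self.total_raw != self.high_quality + self.low_quality:
            raise AssertionError("filter accounting broken: raw != high_quality + low_quality")

    def as_dict(self) -> dict[str, int | str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class UniqueTag:
    """A collapsed insert sequence with per-library read counts."""

    seq: str  # RNA alphabet
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.seq)

    def count(self, library: str) -> int:
        return self.counts.get(library, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def is_low_quality(quals: Iterable[int], cfg: CleanConfig) -> bool:
    """True if either low-quality trigger fires."""
    n_low = n_mid = 0
    for q in quals:
        if q < cfg.q_low:
            n_low += 1
        if q < cfg.q_mid:
            n_mid += 1
    return n_low > cfg.q_low_max or n_mid > cfg.q_mid_max


def find_adapter3(seq: str, cfg: CleanConfig) -> int | None:
    """Locate the 3' adapter; returns the insert length (adapter start) or None.

    Best ungapped placement of the adapter (or its prefix, for placements
    running off the read end) with overlap >= ``adapter3_min_overlap`` and at
    most ``adapter3_max_mismatch`` mismatches; fewest mismatches wins,
    leftmost on ties.
    """
    adapter = cfg.adapter3
    L = len(seq)
    # fast path: exact full or prefix occurrence
    probe = adapter[: max(cfg.adapter3_min_overlap, min(len(adapter), 10))]
    pos = seq.find(probe)
    if pos != -1:
        return pos
    best: tuple[int, int] | None = None  # (mismatches, start)
    for start in range(0, L - cfg.adapter3_min_overlap + 1):
        overlap = min(len(adapter), L - start)
        mm = 0
        for a, b in zip(adapter[:overlap], seq[start : start + overlap]):
            if a != b:
                mm += 1
                if mm > cfg.adapter3_max_mismatch:
                    break
        else:
            if best is None or mm < best[0]:
                best = (mm, start)
                if mm == 0:
                    break
    return best[1] if best else None


def is_adapter5_contaminated(seq: str, cfg: CleanConfig) -> bool:
    """5' adapter prefix found exactly at the read start."""
    seed = cfg.adapter5[: cfg.adapter5_seed]
    return bool(seed) and seq.startswith(seed)


def is_polya(insert: str, cfg: CleanConfig) -> bool:
    return len(insert) > 0 and insert.count("A") / len(insert) >= cfg.polya_fraction


def classify_read(seq: str, quals: list[int], cfg: CleanConfig) -> tuple[str, str | None]:
    """Classify one read; returns (category, insert) with insert set iff clean."""
    if len(seq) != len(quals):
        raise ValueError("seq/qual length mismatch")
    if is_low_quality(quals, cfg):
        return "low_quality", None
    if is_adapter5_contaminated(seq, cfg):
        return "adapter5_contaminant", None
    insert_len = find_adapter3(seq, cfg)
    if insert_len is None:
        return "adapter3_null", None
    if insert_len == 0:
        return "insert_null", None
    insert = seq[:insert_len]
    if is_polya(insert, cfg):
        return "polya", None
    if insert_len < cfg.min_insert:
        return "short", None
    if insert_len > cfg.max_insert:
        return "oversize", None
    return "clean", insert


def clean_reads(
    reads: Iterable[tuple[str, str, list[int]]],
    cfg: CleanConfig,
    library: str,
) -> tuple[dict[str, int], FilterStats]:
    """Run the cleaning cascade over one library.

    ``reads`` yields (id, seq, qual) triples.  Returns the collapsed insert
    counts (RNA alphabet, T->U) and the per-category accounting.
    """
    stats = FilterStats(library=library)
    tag_counts: Counter[str] = Counter()
    for _rid, seq, quals in reads:
        stats.total_raw += 1
        category, insert = classify_read(seq.upper(), quals, cfg)
        if category == "low_quality":
            stats.low_quality += 1
            continue
        stats.high_quality += 1
        if category == "clean":
            stats.clean += 1
            tag_counts[normalize_rna(insert)] += 1
        else:
            setattr(stats, category, getattr(stats, category) + 1)
    stats.unique_tags = len(tag_counts)
    stats.check()
    return dict(tag_counts), stats


def collapse_tags(per_library_counts: Mapping[str, Mapping[str, int]]) -> list[UniqueTag]:
    """Merge per-library collapsed counts into a unified tag table.

    Deterministic order: by total count descending, then sequence.
    """
    merged: dict[str, dict[str, int]] = {}
    for library, counts in per_library_counts.items():
        for seq, n in counts.items():
            merged.setdefault(seq, {})[library] = merged.setdefault(seq, {}).get(library, 0) + n
    tags = [UniqueTag(seq=seq, counts=c) for seq, c in merged.items()]
    tags.sort(key=lambda t: (-t.total, t.seq))
    return tags


def length_distribution(tags: Iterable[UniqueTag], library: str) -> dict[int, tuple[int, float]]:
    """Read counts and fractions per insert length for one library."""
    tags = list(tags)
    libraries = {lib for t in tags for lib in t.counts}
    if library not in libraries:
        raise KeyError(f"unknown library {library!r}")
    by_len: Counter[int] = Counter()
    for t in tags:
        by_len[t.length] += t.count(library)
    total = sum(by_len.values())
    if total == 0:
        raise ValueError(f"library {library!r} has no reads")
    return {length: (n, n / total) for length, n in sorted(by_len.items())}
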