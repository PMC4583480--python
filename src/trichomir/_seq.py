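"""Small sequence utilities shared across the pipeline.

All pipeline-internal sequences are RNA-alphabet uppercase (ACGU); FASTA/FASTQ
inputs in DNA alphabet are normalized on the way in (T -> U).
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def is_rna(seq: str) -> bool:
    return bool(seq) and set(seq) <= RNA_ALPHABET


def revcomp(seq: str) -> str:
    """Reverse complement in RNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def hamming(a: str, b: str) -> int:
    """Hamming distance of equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def hamming_capped(a: str, b: str, cap: int) -> int:
    """Hamming distance, short-circuiting once it exceeds ``cap``.

    Returns cap+1 as soon as the distance is known to exceed the cap.
    """
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cap:
                return d
    return d


def best_substring_match(query: str, text: str, max_mismatch: int) -> tuple[int, int] | None:
    """Best ungapped placement of ``query`` inside ``text``.

    Returns ``(offset, mismatches)`` for the placement with the fewest
    mismatches (leftmost on ties) if it is within ``max_mismatch``, else None.
    """
    n, m = len(text), len(query)
    if m == 0 or m > n:
        return None
    best: tuple[int, int] | None = None
    for off in range(n - m + 1):
        d = hamming_capped(query, text[off : off + m], max_mismatch)
        if d <= max_mismatch and (best is None or d < best[1]):
            best = (off, d)
            if d == 0:
                break
    return best
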