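"""Conserved miRNA identification and per-family quantification.

Three-step strategy against a miRBase-like reference:

1. assign clean tags to miRNA families by ungapped alignment to reference
   mature miRNAs (full-length of the shorter sequence, at most two
   mismatches) or by containment within a reference precursor (at most two
   mismatches);
2. pick one representative per family — the member mature carrying the
   highest summed tag count across libraries — to form a temporary
   family reference;
3. re-align all tags to the temporary reference and sum, per family, the
   counts of every tag within two mismatches of its representative.

A tag contributes its count to at most one family: ambiguous tags go to the
fewest-mismatch family, ties broken lexicographically (deterministic).
"""

from __future__ import annotations

import re
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from ._seq import hamming_capped, normalize_rna
from .io import FastaRecord
from .preprocess import UniqueTag

_FAMILY_RE = re.compile(r"(?:^|-)(mir|miR|MIR)-?(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class FamilyAssignment:
    """Best reference match of one tag."""

    tag: str
    family: str
    reference_id: str
    mismatches: int
    via: str  # 'mature' or 'precursor'


@dataclass
class FamilyExpression:
    """A conserved miRNA family with raw counts and TPM per library."""

    family: str
    representative: str  # representative mature sequence
    representative_id: str
    member_tags: tuple[str, ...]
    counts: dict[str, int] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)


def parse_family(reference_id: str) -> str:
    """Family name from a miRBase-style id (ath-miR166a-5p -> miR166)."""
    m = _FAMILY_RE.search(reference_id)
    if not m:
        raise ValueError(f"cannot parse miRNA family from reference id {reference_id!r}")
    return f"miR{m.group(2)}"


def align_ungapped(tag: str, reference: str, max_mismatch: int) -> int | None:
    """Fewest mismatches over ungapped full-length-of-the-shorter placements.

    The shorter sequence slides along the longer; the best placement's
    mismatch count is returned if within ``max_mismatch``, else None.
    """
    short, long_ = (tag, reference) if len(tag) <= len(reference) else (reference, tag)
    best: int | None = None
    for off in range(len(long_) - len(short) + 1):
        d = hamming_capped(short, long_[off : off + len(short)], max_mismatch)
        if d <= max_mismatch and (best is None or d < best):
            best = d
            if d == 0:
                break
    return best


def assign_to_families(
    tags: Sequence[UniqueTag],
    matures: Sequence[FastaRecord],
    precursors: Sequence[FastaRecord] = (),
    max_mismatch: int = 2,
) -> dict[str, FamilyAssignment]:
    """Assign each tag to its best-matching miRNA family, if any.

    Fewest mismatches wins; ties broken by (family, reference id)
    lexicographically.  Tags matching nothing are simply absent from the
    result and remain in the unannotated pool.
    """
    refs: list[tuple[str, str, str, str]] = []  # (family, ref_id, seq, via)
    for rec in matures:
        refs.append((parse_family(rec.id), rec.id, normalize_rna(rec.seq), "mature"))
    for rec in precursors:
        refs.append((parse_family(rec.id), rec.id, normalize_rna(rec.seq), "precursor"))

    out: dict[str, FamilyAssignment] = {}
    for tag in tags:
        best: FamilyAssignment | None = None
        for family, rid, seq, via in refs:
            if via == "mature":
                d = align_ungapped(tag.seq, seq, max_mismatch)
            else:
                # tag must lie within the precursor
                d = align_ungapped(tag.seq, seq, max_mismatch) if len(tag.seq) <= len(seq) else None
            if d is None:
                continue
            cand = FamilyAssignment(tag.seq, family, rid, d, via)
            # fewest mismatches, then matures over precursors, then lexicographic
            key = (cand.mismatches, cand.via != "mature", cand.family, cand.reference_id)
            best_key = (
                (best.mismatches, best.via != "mature", best.family, best.reference_id)
                if best is not None
                else None
            )
            if best_key is None or key < best_key:
                best = cand
        if best is not None:
            out[tag.seq] = best
    return out


def build_family_reference(
    assignments: Mapping[str, FamilyAssignment],
    tags: Sequence[UniqueTag],
    matures: Sequence[FastaRecord],
) -> dict[str, tuple[str, str]]:
    """Temporary family reference: one representative mature per family.

    The representative is the reference mature whose assigned tags carry the
    highest summed read count across both libraries; exact ties go to the
    lexicographically smallest mature sequence.
    """
    if not assignments:
        return {}
    counts = {t.seq: t.total for t in tags}
    mature_seq = {rec.id: normalize_rna(rec.seq) for rec in matures}
    abundance: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    assigned_families = set()
    for a in assignments.values():
        assigned_families.add(a.family)
        if a.reference_id in mature_seq:
            abundance[a.family][a.reference_id] += counts.get(a.tag, 0)
    matures_by_family: dict[str, list[str]] = defaultdict(list)
    for rid in mature_seq:
        matures_by_family[parse_family(rid)].append(rid)
    reference: dict[str, tuple[str, str]] = {}
    for family in assigned_families:
        per_mature = abundance.get(family)
        if per_mature:
            pool = per_mature
            best_id = min(pool, key=lambda rid: (-pool[rid], mature_seq[rid], rid))
        elif matures_by_family.get(family):
            # family seen only through precursor matches: fall back to its
            # reference matures (zero observed abundance, deterministic pick)
            best_id = min(matures_by_family[family], key=lambda rid: (mature_seq[rid], rid))
        else:
            continue
        reference[family] = (best_id, mature_seq[best_id])
    return reference


def quantify_families(
    tags: Sequence[UniqueTag],
    family_reference: Mapping[str, tuple[str, str]],
    libraries: Sequence[str],
    max_mismatch: int = 2,
    library_totals: Mapping[str, int] | None = None,
) -> list[FamilyExpression]:
    """Per-family expression: sum counts of all tags within two mismatches
    of the family representative.

    A tag aligning to several representatives is counted once, for the
    fewest-mismatch family (ties: lexicographically first family).  Families
    with no aligned tags are absent.  TPM is filled in when
    ``library_totals`` (clean-read totals per library) is given.
    """
    members: dict[str, list[str]] = defaultdict(list)
    for tag in tags:
        best_family: str | None = None
        best_d: int | None = None
        for family in sorted(family_reference):
            d = align_ungapped(tag.seq, family_reference[family][1], max_mismatch)
            if d is not None and (best_d is None or d < best_d):
                best_family, best_d = family, d
        if best_family is not None:
            members[best_family].append(tag.seq)

    tag_by_seq = {t.seq: t for t in tags}
    out: list[FamilyExpression] = []
    for family in sorted(members):
        rid, rseq = family_reference[family]
        fam_counts = {
            lib: sum(tag_by_seq[s].count(lib) for s in members[family]) for lib in libraries
        }
        tpm = {}
        if library_totals:
            from .diffexpr import tpm as _tpm

            tpm = {lib: _tpm(fam_counts[lib], library_totals[lib]) for lib in libraries}
        out.append(
            FamilyExpression(
                family=family,
                representative=rseq,
                representative_id=rid,
                member_tags=tuple(members[family]),
                counts=fam_counts,
                tpm=tpm,
            )
        )
    return out


def venn_counts(expressions: Iterable[FamilyExpression], lib_a: str, lib_b: str) -> dict[str, int]:
    """Family presence accounting for a two-set Venn diagram."""
    a_only = b_only = both = 0
    for e in expressions:
        in_a = e.counts.get(lib_a, 0) > 0
        in_b = e.counts.get(lib_b, 0) > 0
        if in_a and in_b:
            both += 1
        elif in_a:
            a_only += 1
        elif in_b:
            b_only += 1
    return {"a_only": a_only, "b_only": b_only, "both": both}
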