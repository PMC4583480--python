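"""Plant miRNA target prediction over transcript sequences.

Every transcript window of miRNA length is scored as an ungapped antiparallel
duplex against the miRNA.  Positions are numbered 1..len from the miRNA 5'
end; each position is Watson–Crick (WC), G:U wobble (GU) or mismatch (MM),
and the mismatch score is #MM + 0.5·#GU.  A window is a candidate when its
score is below 4; candidates are then checked against six rules:

1. mismatch score < 4 (G:U counts half);
2. no more than two adjacent mismatches anywhere in the duplex;
3. no adjacent mismatches in positions 2–12;
4. no mismatch at position 10 or 11;
5. mismatch score restricted to positions 1–12 at most 2.5;
6. duplex hybridization energy at least 75% of the energy of the miRNA
   with its perfect complement.

G:U wobbles count toward the scores of rules 1 and 5 but are *pairs* for the
adjacency/position rules 2–4.  Acceptance is the conjunction of all six
rules; each outcome is recorded individually.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from ._seq import is_rna, normalize_rna
from .rna_structure import duplex_energy, perfect_complement_energy

MIN_MIRNA_LEN = 15
SCORE_CUTOFF = 4.0
SEED_SCORE_CUTOFF = 2.5
MFE_RATIO_CUTOFF = 0.75

_CODE = {b: i for i, b in enumerate("ACGU")}
# pairing state lookup tables indexed by (miRNA base, site base)
_WC_TABLE = np.zeros((4, 4), dtype=bool)
for a, b in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _WC_TABLE[_CODE[a], _CODE[b]] = True
_GU_TABLE = np.zeros((4, 4), dtype=bool)
for a, b in (("G", "U"), ("U", "G")):
    _GU_TABLE[_CODE[a], _CODE[b]] = True


@dataclass(frozen=True)
class DuplexAlignment:
    """An ungapped miRNA:target pairing at one transcript window."""

    mirna_id: str
    mirna: str
    transcript_id: str
    start: int  # 0-based half-open interval on the transcript
    end: int
    states: tuple[str, ...]  # per position from the miRNA 5' end
    score: float  # #MM + 0.5 * #GU
    seed_score: float  # same, restricted to positions 1-12


@dataclass(frozen=True)
class TargetHit:
    """A rule-checked duplex alignment."""

    alignment: DuplexAlignment
    duplex_dg: float
    perfect_dg: float
    mfe_ratio: float
    rules: tuple[bool, bool, bool, bool, bool, bool]
    accepted: bool


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


_ASCII_CODE = np.full(128, -1, dtype=np.int8)
for b, i in _CODE.items():
    _ASCII_CODE[ord(b)] = i


def duplex_score(states: Sequence[str]) -> float:
    return sum(1.0 if s == "MM" else 0.5 if s == "GU" else 0.0 for s in states)


def align_duplex(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    score_cutoff: float = SCORE_CUTOFF,
) -> list[DuplexAlignment]:
    """All transcript windows whose duplex mismatch score is below the cutoff.

    Exhaustive over every window of miRNA length; deterministic order by
    window start.  miRNA position ``i`` (1-based from the 5' end) faces
    transcript base ``start + len - i``.
    """
    mirna = normalize_rna(mirna)
    transcript = normalize_rna(transcript)
    if len(mirna) < MIN_MIRNA_LEN:
        raise ValueError(f"miRNA {mirna_id!r} shorter than {MIN_MIRNA_LEN} nt")
    if not is_rna(mirna) or not is_rna(transcript):
        raise ValueError("sequences must be ACGU")
    m, n = len(mirna), len(transcript)
    if n < m:
        return []
    mir_codes = _ASCII_CODE[_encode(mirna)].astype(np.intp)
    t_codes = _ASCII_CODE[_encode(transcript)].astype(np.intp)
    n_win = n - m + 1
    # facing[i, s] = transcript base opposite miRNA position i+1 for window s
    idx = (m - 1 - np.arange(m))[:, None] + np.arange(n_win)[None, :]
    facing = t_codes[idx]
    wc = _WC_TABLE[mir_codes[:, None], facing]
    gu = _GU_TABLE[mir_codes[:, None], facing]
    mm = ~(wc | gu)
    scores = mm.sum(axis=0) + 0.5 * gu.sum(axis=0)
    seed_scores = mm[:12].sum(axis=0) + 0.5 * gu[:12].sum(axis=0)
    out = []
    for s in np.nonzero(scores < score_cutoff)[0]:
        states = tuple(
            "WC" if wc[i, s] else "GU" if gu[i, s] else "MM" for i in range(m)
        )
        out.append(
            DuplexAlignment(
                mirna_id=mirna_id,
                mirna=mirna,
                transcript_id=transcript_id,
                start=int(s),
                end=int(s) + m,
                states=states,
                score=float(scores[s]),
                seed_score=float(seed_scores[s]),
            )
        )
    return out


def check_rules(alignment: DuplexAlignment) -> tuple[bool, ...]:
    """Evaluate the six target rules on one alignment."""
    states = alignment.states
    mm = [s == "MM" for s in states]
    # longest run of adjacent mismatches
    run = longest = 0
    for is_mm in mm:
        run = run + 1 if is_mm else 0
        longest = max(longest, run)
    r1 = alignment.score < SCORE_CUTOFF
    r2 = longest <= 2
    # positions 2..12 (1-based): indices 1..11
    r3 = not any(mm[i] and mm[i + 1] for i in range(1, min(11, len(mm) - 1)))
    r4 = not (mm[9] or mm[10])
    r5 = alignment.seed_score <= SEED_SCORE_CUTOFF
    return r1, r2, r3, r4, r5


def score_duplex(alignment: DuplexAlignment, site: str) -> TargetHit:
    """Rule outcomes plus the energy-ratio rule for one alignment.

    ``site`` is the transcript window sequence (5'->3').
    """
    dup = duplex_energy(alignment.mirna, site)
    perfect = perfect_complement_energy(alignment.mirna)
    ratio = dup.energy / perfect if perfect < 0 else 0.0
    r1, r2, r3, r4, r5 = check_rules(alignment)
    r6 = ratio >= MFE_RATIO_CUTOFF
    rules = (r1, r2, r3, r4, r5, r6)
    return TargetHit(
        alignment=alignment,
        duplex_dg=dup.energy,
        perfect_dg=perfect,
        mfe_ratio=ratio,
        rules=rules,
        accepted=all(rules),
    )


def predict_targets(
    mirnas: Mapping[str, str],
    transcriptome: Mapping[str, str],
    score_cutoff: float = SCORE_CUTOFF,
) -> tuple[list[TargetHit], dict[str, int]]:
    """Six-rule target search of every miRNA against every transcript.

    Returns all candidate hits (accepted and rejected, each with its rule
    outcomes) and the per-miRNA count of *accepted* targets.
    """
    hits: list[TargetHit] = []
    counts: dict[str, int] = {}
    for mid in sorted(mirnas):
        mseq = normalize_rna(mirnas[mid])
        n_acc = 0
        for tid in sorted(transcriptome):
            tseq = normalize_rna(transcriptome[tid])
            for aln in align_duplex(mid, mseq, tid, tseq, score_cutoff):
                site = tseq[aln.start : aln.end]
                hit = score_duplex(aln, site)
                hits.append(hit)
                n_acc += hit.accepted
        if n_acc:
            counts[mid] = n_acc
    return hits, counts


def render_alignment(hit: TargetHit, site: str) -> str:
    """Text pairing diagram of a duplex (miRNA 5'->3' on top)."""
    aln = hit.alignment
    site_rev = site[::-1]  # 3'->5' under the miRNA
    bonds = "".join(
        "|" if s == "WC" else "o" if s == "GU" else " " for s in aln.states
    )
    return (
        f"{aln.mirna_id} vs {aln.transcript_id}:{aln.start + 1}-{aln.end} "
        f"score={aln.score:.1f} ratio={hit.mfe_ratio:.2f}\n"
        f"miRNA  5' {aln.mirna} 3'\n"
        f"          {bonds}\n"
        f"target 3' {site_rev} 5'"
    )
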