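"""RNA secondary-structure folding and ungapped duplex hybridization energies.

Two distinct energy calculations are used by the pipeline:

* :func:`fold` — the minimum-free-energy secondary structure of a single
  sequence (hairpin-precursor evaluation).  This delegates to the ViennaRNA
  thermodynamic engine (nearest-neighbor Turner parameters), which is the
  field-standard MFE folder; the backend identity is surfaced in
  :data:`FOLD_BACKEND` so run manifests can record it.

* :func:`duplex_energy` — the hybridization energy of an *ungapped*
  miRNA:target pairing.  Plant target rules score fixed-length antisense
  windows, so the duplex here is positionally constrained: Watson–Crick and
  G:U wobble pairs stack, mismatches interrupt stacks and contribute nothing.
  Stacking free energies for WC/WC steps are the Xia/Turner nearest-neighbor
  values (kcal/mol, 37 °C); steps involving a wobble pair use the WC-analog
  value (G:U read as G:C) scaled by 0.5 per wobble pair and clamped at zero,
  which keeps the model monotone: converting any pair to a mismatch can never
  make the energy more negative.  Target acceptance uses only the *ratio* of
  duplex to perfect-complement energy, so a consistent relative scale is what
  matters, not absolute calorimetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import RNA

from ._seq import complement_base, is_rna, normalize_rna, revcomp

FOLD_BACKEND = f"ViennaRNA {RNA.__version__}"

MIN_FOLD_LEN = 10
MAX_FOLD_LEN = 1000

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

# Xia et al. / Turner WC stack free energies, keyed by
# (top strand 5'->3' dinucleotide, bottom strand 3'->5' dinucleotide).
_WC_STACK = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}
# rotational symmetry: 5'XY3'/3'WZ5' == 5'ZW3'/3'YX5'
for (top, bot), e in list(_WC_STACK.items()):
    _WC_STACK.setdefault((bot[::-1], top[::-1]), e)

# replace a wobble pair by its purine-preserving WC analog
_WC_ANALOG = {("G", "U"): ("G", "C"), ("U", "G"): ("U", "A")}


@dataclass(frozen=True)
class FoldResult:
    """MFE structure of a single RNA sequence."""

    structure: str  # dot-bracket
    energy: float  # kcal/mol
    pairs: tuple[tuple[int, int], ...]  # 0-based (i, j), i < j

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DuplexEnergy:
    """Hybridization energy of an ungapped miRNA:site duplex."""

    energy: float  # kcal/mol
    states: tuple[str, ...]  # per position from the miRNA 5' end: WC | GU | MM


def pairs_from_dotbracket(structure: str) -> tuple[tuple[int, int], ...]:
    """Base-pair list from a dot-bracket string (no pseudoknots)."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"unsupported dot-bracket symbol {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


def fold(seq: str) -> FoldResult:
    """Minimum-free-energy secondary structure of ``seq``.

    ``seq`` may be DNA- or RNA-alphabet; T is normalized to U.  Deterministic
    for a given backend version.
    """
    rna = normalize_rna(seq)
    if not (MIN_FOLD_LEN <= len(rna) <= MAX_FOLD_LEN):
        raise ValueError(f"sequence length {len(rna)} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    if not is_rna(rna):
        raise ValueError("sequence contains non-ACGU symbols")
    structure, energy = RNA.fold(rna)
    pairs = pairs_from_dotbracket(structure)
    if not pairs:
        energy = 0.0
    return FoldResult(structure=structure, energy=float(energy), pairs=pairs)


def pair_state(mirna_base: str, site_base: str) -> str:
    """Pairing state of one duplex position: WC, GU (wobble) or MM."""
    key = (mirna_base, site_base)
    if key in _WC:
        return "WC"
    if key in _WOBBLE:
        return "GU"
    return "MM"


def _step_energy(p1: tuple[str, str], p2: tuple[str, str]) -> float:
    """Stacking energy of two adjacent pairs (each WC or wobble)."""
    scale = 1.0
    adj = []
    for p in (p1, p2):
        if p in _WC_ANALOG:
            p = _WC_ANALOG[p]
            scale *= 0.5
        adj.append(p)
    top = adj[0][0] + adj[1][0]
    bot = adj[0][1] + adj[1][1]
    return min(0.0, _WC_STACK[(top, bot)] * scale)


def duplex_states(mirna: str, site: str) -> tuple[str, ...]:
    """Per-position pairing states for an ungapped antiparallel duplex.

    ``mirna`` is 5'->3'; ``site`` is the transcript window 5'->3'.  Position
    ``i`` (0-based from the miRNA 5' end) faces ``site[len-1-i]``.
    """
    if len(mirna) != len(site):
        raise ValueError("miRNA and site must have equal length for an ungapped duplex")
    n = len(mirna)
    return tuple(pair_state(mirna[i], site[n - 1 - i]) for i in range(n))


def duplex_energy(mirna: str, site: str) -> DuplexEnergy:
    """Hybridization energy of an ungapped miRNA:site duplex.

    Adjacent non-mismatch positions contribute a stacking term; mismatches
    interrupt stacking.  Energy is <= 0 by construction.
    """
    mirna = normalize_rna(mirna)
    site = normalize_rna(site)
    if not (is_rna(mirna) and is_rna(site)):
        raise ValueError("duplex sequences must be non-empty ACGU")
    states = duplex_states(mirna, site)
    n = len(mirna)
    energy = 0.0
    for i in range(n - 1):
        if states[i] != "MM" and states[i + 1] != "MM":
            p1 = (mirna[i], site[n - 1 - i])
            p2 = (mirna[i + 1], site[n - 2 - i])
            energy += _step_energy(p1, p2)
    return DuplexEnergy(energy=energy, states=states)


def perfect_complement_energy(mirna: str) -> float:
    """Duplex energy of ``mirna`` against its exact reverse complement."""
    mirna = normalize_rna(mirna)
    if not is_rna(mirna):
        raise ValueError("miRNA must be non-empty ACGU")
    return duplex_energy(mirna, revcomp(mirna)).energy
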