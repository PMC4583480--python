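# Methods

`trichomir` reimplements, as a tested library, the classic two-library plant
small-RNA workflow used to compare miRNA populations between a secretory
tissue (glandular trichomes) and whole young leaves: read cleaning and tag
collapsing, mismatch-bounded transcriptome mapping, conserved miRNA family
quantification against a miRBase-like reference, hairpin-based novel miRNA
prediction, six-rule target prediction, exact two-library differential
expression, flat-term enrichment, and stem-loop qPCR quantification. The
headline numbers of any real study of this kind depend on its sequencing
libraries and transcriptome assembly; this package instead ships a synthetic
data generator that plants known ground truth, so every stage is validated
by property tests, brute-force oracles and parameter recovery at desk scale.

## Read cleaning

Raw reads are fixed-length 49-nt single-end sequences. The cleaning cascade
removes, in order: (1) low-quality reads — more than four bases with quality
below 10, or more than six bases with quality below 13; (2) reads carrying
the 5' adapter at the read start (exact 5-nt seed); (3) reads without a
locatable 3' adapter; (4) adapter dimers (empty insert); (5) poly(A) inserts
(≥ 90% A — the threshold is a package choice, configurable); (6) inserts
shorter than 18 nt. Inserts longer than the 30-nt size-selection bound are
kept as a distinguishable extra category so the accounting identity
`high_quality = clean + Σ removals` holds exactly. The two low-quality
triggers are read as independent discard conditions (OR). "Quality" is the
Phred-scaled FASTQ base quality with a configurable offset (33 default, 64
for older Illumina dialects); older Solexa-style scores are approximated by
Phred.

The 3' adapter is located by the best ungapped placement of the adapter (or
its prefix at the read end) with at least 7 nt of overlap and at most one
mismatch; fewest mismatches wins, leftmost on ties. Survivors are trimmed,
normalized to the RNA alphabet and collapsed into unique tags with
per-library counts.

## Mapping and annotation

Tags are mapped to the transcriptome by pigeonhole seeding: a tag matching
with ≤ m mismatches must contain one of m+1 disjoint exact k-mers (k = 6 by
default), so exact seed lookups plus full Hamming verification enumerate
*all* hits — the oracle tests compare against an exhaustive scan over every
window of a toy transcriptome, both strands. The mismatch bound follows the
usual "fewer than two mismatches" convention, i.e. ≤ 1 by default,
configurable to 2.

Annotation partitions tags with a fixed elimination priority — rRNA > tRNA >
snRNA > snoRNA > conserved miRNA > unannotated — so each tag lands in
exactly one category and per-category totals sum to the library totals. An
ncRNA match is an exact substring or a ≤ 1-mismatch full-length placement
within a category reference; covariance-model search (Rfam-style) is out of
scope and approximated by sequence matching.

## Conserved miRNA quantification

Three steps: (1) tags are assigned to families by ungapped alignment to
reference matures (full length of the shorter sequence, ≤ 2 mismatches) or
containment in a reference precursor (≤ 2 mismatches); family names are
parsed from miRBase-style ids (`ath-miR166a-5p → miR166`). (2) One
representative per family — the mature whose assigned tags carry the highest
summed count over both libraries — forms a temporary reference; exact ties
go to the lexicographically smallest sequence. (3) Family expression is the
sum of counts of all tags within 2 mismatches of the representative. A tag
aligning to several representatives is counted once, for the
fewest-mismatch family (ties: lexicographically first) — the resolution of
multi-family tags is an explicit package decision, since pipelines of this
generation left it unstated. Assignment ties between a mature and a
precursor of the same family prefer the mature.

## RNA structure

Single-sequence folding delegates to ViennaRNA's MFE engine
(nearest-neighbor Turner parameters); the backend identity is recorded in
run manifests. Oracle tests check that the reported MFE is at or below the
energy of every enumerated single-stem structure on short sequences.

The miRNA:target duplex model is deliberately simpler: target rules score
fixed-length ungapped antisense windows, so the duplex energy is a sum of
stacking terms over adjacent non-mismatch positions. WC/WC steps use the
Xia/Turner stacking free energies (kcal/mol, 37 °C); steps involving a G:U
wobble use the WC-analog value (G:U read as G:C, U:G as U:A) scaled by 0.5
per wobble pair and clamped at zero. The clamp guarantees monotonicity —
converting any pair to a mismatch can never make the energy more negative —
which the acceptance rules rely on. Only the *ratio* of duplex to
perfect-complement energy enters the target rules, so a consistent relative
scale matters more than absolute calorimetry; with this parameterization a
single wobble in a GC-rich 21-mer keeps 75–100% of the perfect-complement
energy.

## Novel miRNA prediction

Unannotated tags of 18–25 nt with sense transcriptome hits seed candidate
precursors: two windows per hit (long 150-nt flank upstream or downstream,
20 nt on the short side), capped at 350 nt — real plant precursors of this
kind span roughly 66–323 nt, so the cap accommodates them. Each window is
folded and checked in a fixed order, the first failure recorded as the
rejection reason:

1. the fold contains a hairpin (`no-hairpin`);
2. the mature lies entirely on one arm, never straddling the terminal loop
   (`in-loop`);
3. within the mature:star duplex no bulge/internal loop exceeds 4 nt and at
   most 6 mature bases are unpaired (`large-bulge`) — the magnitude limits
   are Mireap-like defaults, as the criterion "lacks large internal loops or
   bulges" carries no numbers;
4. folding free energy ≤ −18 kcal/mol (`energy`);
5. summed read support over both libraries ≥ 5 (`support`) — the "at least
   five in the alignment results" criterion is read as read-count support.

The star interval is derived from the mature's pairing partners with the
conventional 2-nt 3' overhang; star-read presence is reported but not
required. Candidates sharing a mature sequence collapse into one reported
novel miRNA. Position-wise nucleotide bias of accepted matures is profiled
(U at position 1, A at position 10 are the canonical plant signatures).

## Target prediction

Every transcript window of miRNA length is scored as an ungapped
antiparallel duplex; positions count 1..L from the miRNA 5' end, and the
mismatch score is #MM + 0.5·#GU. Windows with score < 4 are candidates;
acceptance requires all six rules: score < 4; no run of more than two
adjacent mismatches; no adjacent mismatches within positions 2–12; no
mismatch at positions 10–11; score restricted to positions 1–12 ≤ 2.5; and
duplex energy ≥ 75% of the perfect-complement energy. G:U wobbles count
toward the scores but are *pairs* for the adjacency/position rules — the
scoring convention distinguishes wobbles from mismatches. Duplexes are
strictly ungapped (the rule set never mentions bulges), a documented
limitation relative to gap-tolerant plant target finders. Search is
sense-strand only by default, since assembled transcripts are oriented.

## Differential expression and enrichment

Expression is TPM over the clean-read total of each library. Significance
of a count difference between the two unreplicated libraries is an exact
Audic–Claverie test: conditional on count x in library 1, the count in
library 2 follows a negative-binomial predictive distribution with odds
N1/(N1+N2). The raw conditional is asymmetric in the two libraries by one
count; the implementation averages each directional tail over both
conditioning orientations and doubles the smaller direction (capped at 1),
restoring exact exchange symmetry. Fisher's exact test is available as a
config alternative. Multiple testing uses Benjamini–Hochberg (the
deterministic choice where "corrected p-value (q-value)" names no method).
A miRNA is called when p < 0.05, q < 0.05 and |log2 ratio| > 1
(trichomes over leaves); zero TPM is floored at 0.01 for fold changes.
Term enrichment is a one-sided hypergeometric upper tail per flat term with
BH correction; enriched means corrected p ≤ 0.05. Ontology-DAG propagation
is out of scope.

## qPCR

The comparative 2^−ΔΔCt method with a reference gene (actin by default):
replicates are averaged on the Ct scale, ΔCt = Ct(target) − Ct(reference)
per condition, ΔΔCt subtracts the calibrator condition, fold = 2^−ΔΔCt.
Replicate ΔCt spread propagates to an asymmetric fold range. No
amplification-efficiency correction.

## Synthetic data: what it emulates, and what it does not

The generator builds a transcriptome (60 transcripts of 400–1500 nt), a
miRBase-like mature/precursor reference (50 planted + 10 decoy families),
categorized ncRNA references, and plants: hairpin precursors embedded in
transcripts (perfect-stem construction with a mutated far arm, verified to
pass the hairpin criteria in isolation, half 5p / half 3p, 80% U-start and
A-at-10 bias); target sites designed to pass all six rules or to violate
one designated rule each (verified against the scorer at generation time);
and 8 conserved families with 8-fold tissue differences, up/down pairs
sharing a base abundance so the multiplied mass balances between libraries.
Per-tag expression is log-normal; per-library counts are one multinomial
draw, so counts sum exactly to the configured 100k reads per library. Reads
are insert + 3' adapter padded to 49 nt with Gaussian per-position Phred
qualities (mean 36, sd 3) and quality-driven substitution errors;
artifact classes (low-quality, 5'-adapter contamination, missing 3'
adapter, adapter dimers, poly(A), short inserts) are sampled at Table-like
fractions of a few per mille to one percent. Insert lengths peak at 24 nt,
then 21, then 23.

What passing tests therefore demonstrate: the stages implement their stated
criteria exactly, agree with brute-force oracles, and recover planted truth
under realistic sampling noise. What they do not demonstrate: behavior on
real libraries with structured error profiles, adapter variants, RNA
modifications, isomiR spectra, or an incomplete/fragmented transcriptome —
the generator's reads are clean-roomed by construction.

## Problem sizes and numerical choices

Default simulations use 2 × 100k reads, chosen so that recovery statistics
are stable while a full end-to-end run stays around a minute; the test
suite's end-to-end fixtures reuse one full-scale run per session and use
3k–6k reads where only plumbing is exercised. Tie-breaks are lexicographic
and deterministic everywhere; all randomness flows from a single integer
seed through named substreams, making FASTQ output byte-identical across
reruns. Degenerate inputs (empty libraries, empty selections, zero totals,
non-RNA symbols) raise explicit errors rather than propagating NaNs.

## Known limitations

- Ungapped duplexes only, in both conserved-family alignment and target
  scoring; no isomiR-aware soft-clipping.
- ncRNA classification by sequence match, not covariance models.
- The duplex wobble parameterization is a simplification; only energy
  ratios are consumed downstream.
- No replicate-aware DE model (the design is one library per tissue).
- No genome-based precursor search — this workflow is transcriptome-only,
  as for any species without an assembled genome.
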