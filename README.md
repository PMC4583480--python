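# trichomir

Small-RNA sequencing analysis for plant miRNA discovery, built around the
classic two-library design: one sequencing library from a secretory tissue
(glandular trichomes) and one from whole young leaves, compared to find the
conserved and novel miRNAs — and their mRNA targets — that may regulate
tissue-specific metabolism. It is aimed at plant small-RNA bioinformaticians
who want the standard pipeline of this study design as a reusable,
property-tested library rather than a chain of one-off vendor tools.

The pipeline stages, each an importable module:

| stage | module | what it does |
|---|---|---|
| read cleaning | `trichomir.preprocess` | quality/adapter/poly(A)/length cascade; collapse to unique tags |
| mapping | `trichomir.tag_mapping` | exhaustive ≤ *m*-mismatch transcriptome mapping (pigeonhole k-mer seeds); ncRNA/miRNA/unannotated partition |
| conserved miRNAs | `trichomir.conserved` | miRBase-style family assignment (≤ 2 mismatches), per-family representative and counts |
| structure | `trichomir.rna_structure` | MFE folding (ViennaRNA backend) and an ungapped nearest-neighbor duplex energy model |
| novel miRNAs | `trichomir.novel` | hairpin-precursor criteria: stem-loop fold, mature on one arm, bounded bulges, ΔG ≤ −18 kcal/mol, ≥ 5 reads |
| targets | `trichomir.targets` | six-rule plant target scoring (G:U = half mismatch; MFE ratio ≥ 75%) |
| differential expression | `trichomir.diffexpr` | TPM, exact Audic–Claverie test, BH q-values, \|log₂ ratio\| > 1 calls; hypergeometric term enrichment |
| qPCR | `trichomir.qpcr` | comparative 2^−ΔΔCt quantification |
| synthetic data | `trichomir.synthetic_data` | two FASTQ libraries + reference bundle with planted ground truth |
| orchestration | `trichomir.pipeline` | end-to-end run, publication-style TSV tables, checksummed manifest |

## The statistics at the core

**Target rules.** A duplex between miRNA *m* (positions 1..L from the 5'
end) and an ungapped antisense transcript window is scored
`S = #MM + 0.5·#GU`. A site is accepted iff: S < 4; no run of > 2 adjacent
mismatches; no adjacent mismatches in positions 2–12; no mismatch at
positions 10–11; S restricted to positions 1–12 ≤ 2.5; and
ΔG(duplex)/ΔG(perfect complement) ≥ 0.75. Wobbles count toward S but are
pairs for the positional rules.

**Two-library test.** With counts x, y in libraries of N₁, N₂ clean reads,
the Audic–Claverie conditional is negative-binomial,
P(y | x) = C(x+y, y) p^(x+1) (1−p)^y with p = N₁/(N₁+N₂); the two-sided
p-value symmetrizes the directional tails over both conditioning
orientations, so p(x, N₁, y, N₂) = p(y, N₂, x, N₁) exactly. A miRNA is
differentially expressed when p < 0.05, BH q < 0.05 and
|log₂(TPM_trichome/TPM_leaf)| > 1.

**Novel miRNA criteria.** An unannotated 18–25-nt tag mapped to the
transcriptome seeds candidate precursor windows that must fold into a
stem-loop with the mature entirely on one arm, no bulge > 4 nt in the
mature:star duplex (≤ 6 unpaired mature bases), ΔG ≤ −18 kcal/mol, and ≥ 5
supporting reads.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Score a perfect target site and one carrying a mismatch at position 10
(`examples/05_target_prediction.py`):

```
t_bad:81-101 score=1.0 ratio=0.88 rules=111011 accepted=False
t_good:81-101 score=0.0 ratio=1.00 rules=111111 accepted=True
accepted targets per miRNA: {'miR-demo': 1}
miR-demo vs t_good:81-101 score=0.0 ratio=1.00
miRNA  5' UGGAGCUCCCUUCAUUCCAAU 3'
          |||||||||||||||||||||
target 3' ACCUCGAGGGAAGUAAGGUUA 5'
```

The perfect site passes all six rules; the position-10 mismatch flips rule
4 (`rules=111011`) and the site is rejected even though its score (1.0) and
energy ratio are otherwise acceptable.

Relative quantification by stem-loop qPCR (`examples/07_qpcr.py`), actin
reference, leaf calibrator:

```
  assay condition  n_replicates  delta_ct  sd_delta_ct  ddct  fold   fold_lo   fold_hi
miR6435      leaf             3       9.2          0.1   0.0   1.0  0.933033  1.071773
miR6435  trichome             3       5.2          0.1  -4.0  16.0 14.928528 17.148375
```

ΔΔCt = −4 cycles means a 2⁴ = 16-fold higher transcript level in trichomes.

The other scripts in `examples/` walk through simulation, cleaning and
annotation, conserved-family quantification, novel-miRNA prediction and
differential expression, each printing the quantities it computes. The full
pipeline runs with

```bash
trichomir run --out runs/demo --seed 1 --n-reads 100000
```

writing filter statistics, the category table, family counts/TPMs, the
novel-miRNA funnel, target hits, DE calls, enrichment and a checksummed
`manifest.json` under `runs/demo/results/`.

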