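"""Call differentially expressed miRNAs between two libraries.

TPM normalization, the exact Audic-Claverie two-library test, BH q-values,
and the three-threshold call (p < 0.05, q < 0.05, |log2 ratio| > 1).
"""

from trichomir.diffexpr import audic_claverie_test, call_de, enrich_terms

totals = (1_200_000, 900_000)  # clean reads: leaves, trichomes
counts = {
    "miR166": (1200, 905),     # similar expression
    "miR6435": (4, 310),       # trichome-enriched
    "miR159": (800, 45),       # leaf-enriched
    "novel-mir-3": (0, 60),    # trichome-specific
}

table = call_de(counts, totals)
print(table[["id", "tpm_leaves", "tpm_trichomes", "log2_ratio", "p_value", "q_value", "call"]]
      .to_string(index=False))
print("\nsingle test:", audic_claverie_test(4, totals[0], 310, totals[1]))

annotation = {"g1": {"terpenoid"}, "g2": {"terpenoid"}, "g3": {"housekeeping"}, "g4": set()}
enr = enrich_terms(["g1", "g2"], annotation, annotation.keys())
print("\nenrichment of the DE-target set:")
print(enr.to_string(index=False))
# 'up' means higher in trichomes; the trichome-specific tag gets its fold
# from the 0.01-TPM floor. The enrichment table is a hypergeometric upper
# tail per term with BH correction.
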