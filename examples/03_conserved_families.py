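"""Quantify conserved miRNA families against a miRBase-like reference.

Three steps: assign tags to families (<= 2 mismatches), choose the most
abundant mature per family as representative, then sum the counts of all
tags within 2 mismatches of each representative.
"""

from trichomir.conserved import (
    assign_to_families,
    build_family_reference,
    quantify_families,
    venn_counts,
)
from trichomir.io import FastaRecord
from trichomir.preprocess import UniqueTag

matures = [
    FastaRecord("ath-miR166a", "UCGGACCAGGCUUCAUUCCCC"),
    FastaRecord("ath-miR166b", "UCGGACCAGGCUUCAUACCCC"),  # same family, 1 mismatch
    FastaRecord("osa-miR159a", "UUUGGAUUGAAGGGAGCUCUA"),
]
tags = [
    UniqueTag("UCGGACCAGGCUUCAUUCCCC", {"leaves": 100, "trichomes": 40}),
    UniqueTag("UCGGACCAGGCUUCAUACCCC", {"leaves": 30, "trichomes": 0}),
    UniqueTag("UUUGGAUUGAAGGGAGCUCUA", {"leaves": 0, "trichomes": 12}),
]

assignments = assign_to_families(tags, matures)
reference = build_family_reference(assignments, tags, matures)
expressions = quantify_families(tags, reference, ["leaves", "trichomes"],
                                library_totals={"leaves": 1_000_000, "trichomes": 1_000_000})
for fe in expressions:
    print(f"{fe.family}: representative={fe.representative_id} "
          f"counts={fe.counts} tpm={ {k: round(v, 1) for k, v in fe.tpm.items()} }")
print("venn:", venn_counts(expressions, "leaves", "trichomes"))
# miR166's representative is the 130-read mature; both member tags pool into
# one family count per library. The venn triple counts family presence.
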