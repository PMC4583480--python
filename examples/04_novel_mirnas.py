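"""Predict a novel miRNA from a hairpin-forming transcript locus.

Embeds a stem-loop precursor in a transcript, maps the mature tag, excises
candidate windows and pushes them through the hairpin criteria.
"""

from trichomir._seq import revcomp
from trichomir.novel import bias_summary, predict_novel
from trichomir.tag_mapping import build_index, map_tags

mature = "UGAGGUAGUAGGUUGUAUAGU"
stem5 = mature + "GCAUCGGAUCCAUGCAGG"
precursor = stem5 + "GAAACAAC" + revcomp(stem5)
transcript = ("ACGU" * 40 + precursor + "UGCA" * 40).replace("U", "T")

index = build_index({"t1": transcript})
hits = [h for h in map_tags([mature], index, max_mismatch=0) if h.strand == "+"]
novel, candidates, _ = predict_novel(hits, index.transcripts, {mature: 12})

print(f"candidate windows evaluated: {len(candidates)}")
for c in candidates:
    print(f"  window {c.window.start}-{c.window.end}: "
          f"dG={c.fold.energy:.1f} kcal/mol, accepted={c.accepted}, reason={c.reason}")
for nm in novel:
    print(f"novel miRNA: {nm.mature} arm={nm.arm} support={nm.support} reads")
print("nucleotide bias of accepted matures:", bias_summary([n.mature for n in novel]))
# Acceptance requires: a hairpin fold, the mature on one arm, bounded
# bulges, dG <= -18 kcal/mol, and at least 5 supporting reads.
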