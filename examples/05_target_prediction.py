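"""Score miRNA target sites with the six plant-target rules.

Builds a transcript carrying a perfect site and a site with a mismatch at
position 10, and shows the per-rule outcomes and the pairing diagram.
"""

from trichomir._seq import revcomp
from trichomir.targets import predict_targets, render_alignment

mirna = "UGGAGCUCCCUUCAUUCCAAU"
perfect_site = revcomp(mirna)
bad = list(perfect_site)
bad[len(mirna) - 10] = mirna[9]  # mismatch facing miRNA position 10
transcriptome = {
    "t_good": "ACGU" * 20 + perfect_site + "GGCA" * 20,
    "t_bad": "ACGU" * 20 + "".join(bad) + "GGCA" * 20,
}

hits, counts = predict_targets({"miR-demo": mirna}, transcriptome)
for h in hits:
    a = h.alignment
    print(f"{a.transcript_id}:{a.start + 1}-{a.end} score={a.score} "
          f"ratio={h.mfe_ratio:.2f} rules={''.join('1' if r else '0' for r in h.rules)} "
          f"accepted={h.accepted}")
print("accepted targets per miRNA:", counts)

good = next(h for h in hits if h.accepted)
site = transcriptome[good.alignment.transcript_id][good.alignment.start:good.alignment.end]
print(render_alignment(good, site))
# The perfect site passes all six rules (ratio 1.0); the position-10
# mismatch violates the no-mismatch-at-10/11 rule and is rejected.
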