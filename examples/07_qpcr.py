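"""Validate expression by stem-loop RT-qPCR (comparative 2^-ddCt).

Three technical replicates per condition, actin as reference gene, leaf as
the calibrator condition.
"""

import pandas as pd

from trichomir.qpcr import relative_expression

rows = []
for cond, target_ct in (("leaf", 24.1), ("trichome", 20.1)):
    for rep in range(3):
        rows.append({"condition": cond, "assay": "miR6435", "replicate": rep,
                     "ct": target_ct + 0.1 * rep})
        rows.append({"condition": cond, "assay": "actin", "replicate": rep, "ct": 15.0})

table = relative_expression(pd.DataFrame(rows), reference_assay="actin",
                            calibrator_condition="leaf")
print(table.to_string(index=False))
# ddCt = dCt(trichome) - dCt(leaf) = -4, so the trichome fold is 2^4 = 16
# relative to leaf (leaf itself is 1 by construction); the fold range
# propagates the replicate spread of dCt.
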