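"""Stem-loop RT-qPCR relative quantification by the comparative 2^-ddCt method.

Replicate Ct values are averaged on the Ct scale; per condition,
dCt = mean Ct(target) - mean Ct(reference gene); ddCt subtracts the
calibrator condition's dCt, and fold change is 2^-ddCt (so the calibrator
condition is 1 by construction).  The replicate spread of dCt is propagated
to an asymmetric fold range [2^-(ddCt+sd), 2^-(ddCt-sd)].  No
amplification-efficiency correction is applied.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("condition", "assay", "replicate", "ct")


def _validate(ct: pd.DataFrame, reference_assay: str, calibrator_condition: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    conditions = ct["condition"].unique()
    if calibrator_condition not in conditions:
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent from Ct table")
    for cond in conditions:
        has_ref = ((ct["condition"] == cond) & (ct["assay"] == reference_assay)).any()
        if not has_ref:
            raise ValueError(f"reference assay {reference_assay!r} missing in condition {cond!r}")
    return ct


def relative_expression(
    ct: pd.DataFrame,
    reference_assay: str = "actin",
    calibrator_condition: str = "leaf",
) -> pd.DataFrame:
    """Per-assay, per-condition fold change relative to the calibrator.

    Expects a long-format table with columns condition, assay, replicate, ct.
    Returns one row per (assay, condition) with n replicates, delta_ct, its
    replicate sd, ddct, fold and the sd-propagated fold range.
    """
    ct = _validate(ct, reference_assay, calibrator_condition)
    ref_mean = (
        ct[ct["assay"] == reference_assay].groupby("condition")["ct"].mean().to_dict()
    )
    rows = []
    targets = ct[ct["assay"] != reference_assay]
    dct_mean: dict[tuple[str, str], float] = {}
    for (assay, cond), group in targets.groupby(["assay", "condition"], sort=True):
        dct = group["ct"] - ref_mean[cond]
        dct_mean[(assay, cond)] = float(dct.mean())
        rows.append(
            {
                "assay": assay,
                "condition": cond,
                "n_replicates": len(group),
                "delta_ct": float(dct.mean()),
                "sd_delta_ct": float(dct.std(ddof=1)) if len(group) > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    folds = []
    for row in out.itertuples():
        cal = dct_mean.get((row.assay, calibrator_condition))
        if cal is None:
            raise ValueError(
                f"assay {row.assay!r} not measured in calibrator condition {calibrator_condition!r}"
            )
        ddct = row.delta_ct - cal
        folds.append(
            {
                "ddct": ddct,
                "fold": 2.0 ** (-ddct),
                "fold_lo": 2.0 ** (-(ddct + row.sd_delta_ct)),
                "fold_hi": 2.0 ** (-(ddct - row.sd_delta_ct)),
            }
        )
    return pd.concat([out, pd.DataFrame(folds)], axis=1)
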