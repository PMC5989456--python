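"""Relative gene expression (ddCt) from qPCR cycle thresholds.

Fold change of a target gene under a test condition relative to a
reference condition, normalized to an endogenous-control gene measured in
the same sample:

    dCt   = Ct_target − Ct_control              (per sample)
    ddCt  = dCt_condition − mean(dCt_reference)
    fold  = E^(−ddCt)

with amplification efficiency E = 2 (perfect doubling) by default.
Technical replicates are averaged per sample before any biological
statistics; the biological SD is computed on log2 fold changes and
reported back on the linear scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["validate_ct_records", "ddct_fold_change"]

REQUIRED_COLUMNS = ("sample", "condition", "gene", "role", "ct")
ROLES = ("target", "endogenous_control")


def validate_ct_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad_roles = set(records["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
    ct = records["ct"].astype(float)
    if ((ct <= 0) | (ct >= 45)).any():
        raise ValueError("Ct values must lie in the open interval (0, 45)")
    return records


def ddct_fold_change(
    records: pd.DataFrame,
    reference_condition: str,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-gene, per-condition fold change relative to the reference.

    Samples lacking an endogenous-control measurement are excluded with a
    warning; a missing reference condition is an error.  Returns one row
    per (gene, condition) with columns fold_change, fold_sd (linear-scale
    SD from log2 replicate spread; NaN for single replicates) and n.
    """
    records = validate_ct_records(records)
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if reference_condition not in set(records["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} absent")

    # technical replicates -> one Ct per sample x gene x role
    ct = (
        records.groupby(["sample", "condition", "gene", "role"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    controls = (
        ct[ct["role"] == "endogenous_control"]
        .groupby("sample")["ct"]
        .mean()
        .rename("ct_control")
    )
    targets = ct[ct["role"] == "target"].copy()
    targets = targets.join(controls, on="sample")
    orphans = targets["ct_control"].isna()
    if orphans.any():
        lost = sorted(targets.loc[orphans, "sample"].unique())
        warnings.warn(f"samples without endogenous control excluded: {lost}")
        targets = targets[~orphans]
    targets["dct"] = targets["ct"] - targets["ct_control"]

    ref_dct = (
        targets[targets["condition"] == reference_condition]
        .groupby("gene")["dct"]
        .mean()
        .rename("ref_dct")
    )
    targets = targets.join(ref_dct, on="gene")
    no_ref = targets["ref_dct"].isna()
    if no_ref.any():
        lost = sorted(targets.loc[no_ref, "gene"].unique())
        raise ValueError(f"genes lack reference-condition measurements: {lost}")
    targets["ddct"] = targets["dct"] - targets["ref_dct"]
    targets["log2_fold"] = -targets["ddct"] * np.log2(efficiency)

    rows = []
    for (gene, condition), grp in targets.groupby(["gene", "condition"], sort=True):
        log2_folds = grp["log2_fold"].to_numpy()
        mean_log2 = float(log2_folds.mean())
        fold = float(2.0**mean_log2)
        if log2_folds.size > 1:
            sd_log2 = float(log2_folds.std(ddof=1))
            # symmetric linear-scale spread around the geometric-mean fold
            fold_sd = fold * float(2.0**sd_log2 - 2.0**-sd_log2) / 2.0
        else:
            fold_sd = float("nan")
        rows.append(
            {
                "gene": gene,
                "condition": condition,
                "fold_change": fold,
                "fold_sd": fold_sd,
                "n": int(log2_folds.size),
            }
        )
    return pd.DataFrame(rows)
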