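"""Relative expression by the 2^-ddCt (Livak) method.

Each target Ct is normalized to the housekeeping gene within its
(tissue, condition, replicate), then to the mean delta-Ct of the
calibrator condition for that gene and tissue; relative expression is
2 raised to minus the resulting ddCt.  Replicates are independent
biological units, so ddCt is taken against the calibrator's *mean*
delta-Ct rather than replicate-paired.  Amplification efficiency is
fixed at 2 (the standard-method assumption).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionTable", "delta_delta_ct"]


@dataclass
class ExpressionTable:
    """Replicate-level and aggregated relative expression.

    ``replicates`` has one row per (gene, tissue, condition, replicate)
    with ``delta_ct``, ``delta_delta_ct`` and ``rel_expr`` columns;
    ``aggregated`` reports mean +/- sample SD (n-1) and replicate count;
    ``flagged_genes`` lists genes left with fewer than two surviving
    replicates in some condition — these are excluded from downstream
    scoring.
    """

    replicates: pd.DataFrame
    aggregated: pd.DataFrame
    calibrator: str
    housekeeping: str
    flagged_genes: frozenset[str] = field(default_factory=frozenset)


def delta_delta_ct(
    ct: pd.DataFrame, housekeeping: str, calibrator: str
) -> ExpressionTable:
    """Compute 2^-ddCt relative expression from a replicate Ct table.

    Parameters
    ----------
    ct:
        Frame with columns ``gene_id``, ``tissue``, ``condition_id``,
        ``replicate``, ``ct``.  Ct values must be finite and positive
        and keys unique.
    housekeeping:
        Gene id of the reference gene; its rows are consumed for
        normalization and do not appear in the output.
    calibrator:
        Condition id whose mean delta-Ct anchors ddCt (fold change 1).

    Replicates missing a housekeeping Ct are dropped with a warning.
    A missing calibrator condition for any gene/tissue is an error.
    """
    required = {"gene_id", "tissue", "condition_id", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    vals = ct["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("Ct values must be finite and > 0")
    keys = ["gene_id", "tissue", "condition_id", "replicate"]
    if ct.duplicated(subset=keys).any():
        raise ValueError("duplicate (gene, tissue, condition, replicate) keys in Ct table")
    if housekeeping not in set(ct["gene_id"]):
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from Ct table")
    if calibrator not in set(ct["condition_id"]):
        raise ValueError(f"calibrator condition {calibrator!r} absent from Ct table")

    hk = (
        ct.loc[ct["gene_id"] == housekeeping, ["tissue", "condition_id", "replicate", "ct"]]
        .rename(columns={"ct": "ct_hk"})
    )
    targets = ct.loc[ct["gene_id"] != housekeeping].copy()
    merged = targets.merge(hk, on=["tissue", "condition_id", "replicate"], how="left")
    lost = merged["ct_hk"].isna()
    if lost.any():
        dropped = merged.loc[lost, ["tissue", "condition_id", "replicate"]].drop_duplicates()
        for _, row in dropped.iterrows():
            logger.warning(
                "dropping replicate without housekeeping Ct: tissue=%s condition=%s replicate=%s",
                row["tissue"], row["condition_id"], row["replicate"],
            )
        merged = merged.loc[~lost].copy()

    merged["delta_ct"] = merged["ct"] - merged["ct_hk"]

    cal = merged.loc[merged["condition_id"] == calibrator]
    cal_mean = (
        cal.groupby(["gene_id", "tissue"], sort=False)["delta_ct"]
        .mean()
        .rename("cal_delta_ct")
    )
    have_cal = set(cal_mean.index)
    need = set(map(tuple, merged[["gene_id", "tissue"]].drop_duplicates().to_numpy()))
    lacking = sorted(need - have_cal)
    if lacking:
        raise ValueError(f"calibrator condition missing for gene/tissue pairs: {lacking}")

    merged = merged.join(cal_mean, on=["gene_id", "tissue"])
    merged["delta_delta_ct"] = merged["delta_ct"] - merged["cal_delta_ct"]
    merged["rel_expr"] = np.exp2(-merged["delta_delta_ct"])

    replicates = merged[
        ["gene_id", "tissue", "condition_id", "replicate", "delta_ct", "delta_delta_ct", "rel_expr"]
    ].reset_index(drop=True)

    agg = (
        replicates.groupby(["gene_id", "tissue", "condition_id"], sort=False)["rel_expr"]
        .agg(mean_rel_expr="mean", sd_rel_expr=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    flagged = frozenset(agg.loc[agg["n"] < 2, "gene_id"])
    for g in sorted(flagged):
        logger.warning("gene %s has < 2 surviving replicates in some condition; flagged", g)

    return ExpressionTable(
        replicates=replicates,
        aggregated=agg,
        calibrator=calibrator,
        housekeeping=housekeeping,
        flagged_genes=flagged,
    )
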