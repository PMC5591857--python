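"""Relative gene expression by the delta-delta-CT method.

qPCR threshold cycles (CT) are converted to relative expression assuming
100% amplification efficiency (a clean doubling per cycle):

    dCT   = CT_target - CT_housekeeping          (per sample)
    ddCT  = dCT - mean(dCT of the reference group within the same
                       gene x region x hemisphere cell)
    rel%  = 100 * 2 ** (-ddCT)

so the reference (vehicle) group averages 100% in every cell by
construction, and the result is invariant to any CT shift common to target
and housekeeping gene. Group contrasts default to a pooled two-sample t
test of treated versus reference percent values (df = n1 + n2 - 2); a
one-sample form against 100% is also available. Hemisphere pairs are
Bonferroni corrected with m = 2.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, EmptyCellError, MissingHousekeepingError
from .stats import GroupComparison, bonferroni, one_sample_t, two_sample_t

__all__ = ["delta_delta_ct", "expression_contrast"]

SAMPLE_COLS = ["bird", "group", "hemisphere", "region"]
CELL_COLS = ["gene", "region", "hemisphere"]


def _validate_ct(ct: pd.DataFrame) -> None:
    missing = [c for c in (*SAMPLE_COLS, "gene", "ct") if c not in ct.columns]
    if missing:
        raise DegenerateInputError(f"CT table missing columns {missing}")
    vals = ct["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise DegenerateInputError("CT values must be positive and finite")


def delta_delta_ct(ct: pd.DataFrame, housekeeping_gene: str = "18s",
                   reference_group: str = "vehicle") -> pd.DataFrame:
    """Per-sample relative expression as percent of the reference group.

    Parameters
    ----------
    ct : DataFrame
        Columns ``bird, group, hemisphere, region, gene, ct``; every sample
        (bird x hemisphere x region) must include one ``housekeeping_gene``
        row alongside its target-gene rows.
    housekeeping_gene, reference_group : str
        Normalization gene and the group whose mean dCT defines 100%.

    Returns
    -------
    DataFrame with one row per target-gene measurement and added columns
    ``delta_ct``, ``delta_delta_ct``, ``rel_expr_pct``.

    Raises
    ------
    MissingHousekeepingError
        Naming the first samples lacking a housekeeping CT.
    EmptyCellError
        If a gene x region x hemisphere cell has no reference-group samples.
    """
    _validate_ct(ct)
    hk = ct[ct["gene"] == housekeeping_gene]
    if hk.empty:
        raise MissingHousekeepingError(f"no rows for housekeeping gene {housekeeping_gene!r}")
    dup = hk.duplicated(SAMPLE_COLS)
    if dup.any():
        raise MissingHousekeepingError(
            f"duplicate housekeeping CT for samples: {hk.loc[dup, SAMPLE_COLS].to_dict('records')[:5]}")
    targets = ct[ct["gene"] != housekeeping_gene].copy()
    if targets.empty:
        raise DegenerateInputError("CT table contains no target-gene rows")

    merged = targets.merge(hk[SAMPLE_COLS + ["ct"]], on=SAMPLE_COLS,
                           how="left", suffixes=("", "_hk"))
    orphan = merged["ct_hk"].isna()
    if orphan.any():
        bad = merged.loc[orphan, SAMPLE_COLS].drop_duplicates().head().to_dict("records")
        raise MissingHousekeepingError(f"samples without housekeeping CT: {bad}")
    merged["delta_ct"] = merged["ct"] - merged["ct_hk"]

    ref = merged[merged["group"] == reference_group]
    ref_mean = ref.groupby(CELL_COLS)["delta_ct"].mean().rename("ref_delta_ct")
    merged = merged.merge(ref_mean, how="left", left_on=CELL_COLS, right_index=True)
    empty = merged["ref_delta_ct"].isna()
    if empty.any():
        bad = merged.loc[empty, CELL_COLS].drop_duplicates().head().to_dict("records")
        raise EmptyCellError(
            f"no {reference_group!r} samples in cells: {bad}")
    merged["delta_delta_ct"] = merged["delta_ct"] - merged["ref_delta_ct"]
    merged["rel_expr_pct"] = 100.0 * np.exp2(-merged["delta_delta_ct"])
    return merged.drop(columns=["ct_hk", "ref_delta_ct"])


def expression_contrast(rel: pd.DataFrame, reference_group: str = "vehicle",
                        treatment_group: str | None = None,
                        method: str = "two_sample", bonferroni_m: int = 2,
                        alpha: float = 0.05) -> list[GroupComparison]:
    """Group contrast of relative expression per gene x region x hemisphere.

    ``method="two_sample"`` (default) runs a pooled t test of the treated
    group's percent values against the reference group's; ``"one_sample"``
    tests the treated values against the 100% reference identity instead.
    Raw p values are Bonferroni corrected with ``bonferroni_m`` (default 2,
    the left/right hemisphere pair within each gene x region).
    """
    if method not in ("two_sample", "one_sample"):
        raise DegenerateInputError(f"unknown method {method!r}")
    groups = [g for g in rel["group"].unique() if g != reference_group]
    if treatment_group is None:
        if len(groups) != 1:
            raise DegenerateInputError(
                f"treatment_group is ambiguous; candidates: {sorted(groups)}")
        treatment_group = groups[0]

    out: list[GroupComparison] = []
    for (gene, region, hemi), cell in rel.groupby(CELL_COLS, sort=True):
        treat = cell.loc[cell["group"] == treatment_group, "rel_expr_pct"]
        if treat.empty:
            continue
        keys: Mapping = {"gene": gene, "region": region, "hemisphere": hemi,
                         "group": treatment_group, "reference": reference_group}
        if method == "two_sample":
            refv = cell.loc[cell["group"] == reference_group, "rel_expr_pct"]
            cmp_ = two_sample_t(treat, refv, alpha=alpha, keys=keys)
        else:
            cmp_ = one_sample_t(treat, 100.0, alpha=alpha, keys=keys)
        cmp_.p_corrected = bonferroni(cmp_.p, m=bonferroni_m)
        out.append(cmp_)
    return out
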