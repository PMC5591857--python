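"""Familiarity Index (FI) computation and pooling.

The FI of a familiar song at one recording site is the ratio of the site's
adaptation rate to novel songs over its rate to that familiar song
(FI = N/F). Because a remembered song adapts more slowly than a novel one,
FI > 1 indicates neuronal memory; FI = 1 means the previously heard song is
processed as if novel. One FI record is produced per site x test set x
familiar song, with the novel denominator averaged over the same test set's
novel songs (same-session novels control for slow drift in responsiveness).

Both component rates must be negative (adaptation) for the ratio to be
interpretable; records failing the sign checks, or built on rates that were
themselves undefined, are emitted with an ``excluded_reason`` rather than
silently dropped. Pooling reports the median FI and interquartile range per
(group, hemisphere, region) cell, the distributions on which the group
statistics run.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyCellError, MissingNovelRatesError
from .ssa import SsaRate

__all__ = ["FamiliarityRecord", "compute_fi", "fi_table", "pool_fi"]

log = logging.getLogger(__name__)

SITE_SET_COLS = ["bird", "group", "hemisphere", "region", "site", "set"]

#: Exclusion reason codes.
REASON_NONNEG_FAMILIAR = "nonnegative_rate"
REASON_NONNEG_NOVEL = "nonnegative_novel_mean"
REASON_UNDEFINED_FAMILIAR = "undefined_familiar_rate"
REASON_UNDEFINED_NOVEL = "undefined_novel_rate"


@dataclass(frozen=True)
class FamiliarityRecord:
    """One FI value (or an excluded placeholder) for one familiar song."""

    bird: str
    group: str
    hemisphere: str
    region: str
    site: int
    set: int
    familiar_stimulus: str
    fi: float                    # NaN when excluded
    novel_rate_mean: float       # percent per trial
    familiar_rate: float         # percent per trial
    excluded_reason: str | None = None

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not None


def _classify(familiar_rate: float, novel_mean: float) -> str | None:
    if np.isnan(familiar_rate):
        return REASON_UNDEFINED_FAMILIAR
    if np.isnan(novel_mean):
        return REASON_UNDEFINED_NOVEL
    if familiar_rate >= 0:
        return REASON_NONNEG_FAMILIAR
    if novel_mean >= 0:
        return REASON_NONNEG_NOVEL
    return None


def compute_fi(rates: Sequence[SsaRate]) -> list[FamiliarityRecord]:
    """FI records for the rates of one site x one test set.

    ``rates`` must contain this site/set's familiar ('F') and novel ('N')
    stimulus rates. For each familiar stimulus with a negative rate, and a
    negative novel-rate mean, FI = mean(novel rates) / familiar rate;
    otherwise the record is excluded with a reason code.

    Raises
    ------
    MissingNovelRatesError
        If no novel rates are present.
    """
    keys = {(r.bird, r.hemisphere, r.region, r.site, r.set) for r in rates}
    if len(keys) != 1:
        raise MissingNovelRatesError(f"rates span {len(keys)} site x set groups; expected exactly one")
    novel = [r.rate for r in rates if r.stim_class == "N"]
    if not novel:
        raise MissingNovelRatesError(f"no novel rates for site x set {keys.pop()}")
    novel_mean = float(np.nanmean(novel)) if not np.all(np.isnan(novel)) else float("nan")

    out = []
    for r in rates:
        if r.stim_class != "F":
            continue
        reason = _classify(r.rate, novel_mean)
        fi = novel_mean / r.rate if reason is None else float("nan")
        out.append(FamiliarityRecord(
            bird=r.bird, group=r.group, hemisphere=r.hemisphere, region=r.region,
            site=r.site, set=r.set, familiar_stimulus=r.stimulus,
            fi=fi, novel_rate_mean=novel_mean, familiar_rate=r.rate,
            excluded_reason=reason))
    return out


def fi_table(rates: pd.DataFrame) -> pd.DataFrame:
    """FI records for every site x test set of a rates table (vectorized).

    ``rates`` is the output of :func:`songmem.ssa.fit_rates_table`. The
    novel denominator is the mean of the set's defined novel rates (an
    undefined novel rate is skipped; the record is excluded only when all
    the set's novel rates are undefined). Returns one row per familiar
    stimulus with columns ``familiar_stimulus``, ``fi``, ``novel_rate_mean``,
    ``familiar_rate`` and ``excluded_reason`` (None when valid).
    """
    nov = rates[rates["stim_class"] == "N"]
    if nov.empty:
        raise MissingNovelRatesError("rates table contains no novel-stimulus rows")
    novel_mean = nov.groupby(SITE_SET_COLS, sort=False)["rate"].mean()  # skips NaN
    fam = rates[rates["stim_class"] == "F"]
    merged = fam.merge(novel_mean.rename("novel_rate_mean"), how="left",
                       left_on=SITE_SET_COLS, right_index=True)
    fam_idx = pd.MultiIndex.from_frame(fam[SITE_SET_COLS])
    orphan = ~fam_idx.isin(novel_mean.index)
    if orphan.any():
        missing = fam.loc[orphan, SITE_SET_COLS].drop_duplicates().head().to_dict("records")
        raise MissingNovelRatesError(f"site x set groups without novel rates: {missing}")

    f_rate = merged["rate"].to_numpy()
    n_mean = merged["novel_rate_mean"].to_numpy()
    reason = np.select(
        [np.isnan(f_rate), np.isnan(n_mean), f_rate >= 0, n_mean >= 0],
        [REASON_UNDEFINED_FAMILIAR, REASON_UNDEFINED_NOVEL,
         REASON_NONNEG_FAMILIAR, REASON_NONNEG_NOVEL],
        default=None)
    with np.errstate(divide="ignore", invalid="ignore"):
        fi = np.where(pd.isna(reason), n_mean / f_rate, np.nan)

    out = merged[SITE_SET_COLS].copy()
    out["familiar_stimulus"] = merged["stimulus"].to_numpy()
    out["fi"] = fi
    out["novel_rate_mean"] = n_mean
    out["familiar_rate"] = f_rate
    out["excluded_reason"] = reason
    n_exc = int(pd.notna(reason).sum())
    if n_exc:
        log.info("fi_table: %d of %d records excluded: %s", n_exc, len(out),
                 pd.Series(reason[pd.notna(reason)]).value_counts().to_dict())
    return out


def pool_fi(records: pd.DataFrame,
            by: Sequence[str] = ("group", "hemisphere", "region"),
            cells: Sequence[tuple] | None = None,
            filters: dict | None = None) -> pd.DataFrame:
    """Median FI and IQR per pooling cell.

    Pools the non-excluded records of ``records`` (output of
    :func:`fi_table`) over the grouping key ``by`` (any subset of the label
    columns; coarser keys pool more sites). ``filters`` restricts rows by
    column value first. When ``cells`` lists the expected key tuples,
    requested cells with no usable records appear explicitly with ``n = 0``
    and NaN summaries instead of being omitted; an entirely empty result
    raises :class:`EmptyCellError`.

    Median convention: numpy's, i.e. the mean of the two central values for
    even n. IQR is quartile 75 minus quartile 25 (linear interpolation).
    """
    by = list(by)
    df = records
    if filters:
        for col, val in filters.items():
            df = df[df[col] == val]
    valid = df[pd.isna(df["excluded_reason"]) & np.isfinite(df["fi"])]
    if valid.empty and cells is None:
        raise EmptyCellError(f"no non-excluded FI records to pool (filters={filters})")
    g = valid.groupby(by, sort=True)["fi"]
    pooled = pd.DataFrame({
        "n": g.size(),
        "median_fi": g.median(),
        "q25": g.quantile(0.25),
        "q75": g.quantile(0.75),
    })
    pooled["iqr"] = pooled["q75"] - pooled["q25"]
    if cells is not None:
        idx = pd.MultiIndex.from_tuples([tuple(c) for c in cells], names=by) \
            if len(by) > 1 else pd.Index([c[0] if isinstance(c, tuple) else c for c in cells], name=by[0])
        pooled = pooled.reindex(idx)
        pooled["n"] = pooled["n"].fillna(0).astype(int)
    return pooled.reset_index()
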