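"""Stimulus-specific adaptation (SSA) rates.

Repeated presentation of the same song evokes progressively smaller
responses in NCM; the decline is approximately linear in trial number after
the first few trials. The SSA rate is the OLS slope of response magnitude
versus trial number over that linear region (trials 6-25 by default),
normalized by the mean magnitude over the same window and expressed as
percent change per trial:

    rate = 100 * slope / mean(magnitude over fit window)

Negative rates indicate adaptation; familiar (remembered) songs adapt more
slowly (shallower rate) than novel songs. Normalizing by the observed mean
makes the rate dimensionless and invariant to the overall gain of a
recording site, so rates are comparable across sites and birds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SeriesValidationError, UndefinedRateError
from .signalproc import SERIES_LABELS, ResponseSeries

__all__ = ["SsaRate", "fit_ssa_rate", "fit_rates_table", "DEFAULT_FIT_WINDOW", "DEFAULT_EPSILON"]

log = logging.getLogger(__name__)

DEFAULT_FIT_WINDOW = (6, 25)   # inclusive 1-based trial interval, 20 points
DEFAULT_EPSILON = 1e-9         # magnitudes below this mean are treated as no signal

#: Alternative normalization denominators (the field's convention is the
#: window mean; the others are provided for sensitivity analyses).
DENOMINATORS = ("window_mean", "intercept", "first_trial")


@dataclass(frozen=True)
class SsaRate:
    """Normalized adaptation slope of one response series."""

    bird: str
    group: str
    hemisphere: str
    region: str
    site: int
    set: int
    stimulus: str
    stim_class: str
    rate: float            # percent change per trial, signed
    mean_magnitude: float  # magnitude units, over the fit window
    r_squared: float
    fit_window: tuple[int, int]

    @property
    def labels(self) -> dict:
        return {k: getattr(self, k) for k in SERIES_LABELS}


def _window_ols(m: np.ndarray, lo: int, hi: int) -> tuple[float, float, float]:
    """Slope, window mean, and r^2 of magnitude vs 1-based trial over [lo, hi]."""
    t = np.arange(lo, hi + 1, dtype=float)
    y = m[lo - 1:hi]
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ y) / sxx
    ybar = float(y.mean())
    sst = float(np.square(y - ybar).sum())
    r2 = (slope * slope * sxx / sst) if sst > 0 else 0.0
    return slope, ybar, r2


def fit_ssa_rate(series: ResponseSeries,
                 fit_window: tuple[int, int] = DEFAULT_FIT_WINDOW,
                 epsilon: float = DEFAULT_EPSILON,
                 denominator: str = "window_mean") -> SsaRate:
    """Fit the normalized adaptation rate of one series.

    Parameters
    ----------
    series : ResponseSeries
        Must contain every trial of ``fit_window``.
    fit_window : (int, int)
        Inclusive 1-based trial interval of the linear region.
    epsilon : float
        Series whose denominator is at or below this (in magnitude units)
        have no defined rate and raise :class:`UndefinedRateError`; batch
        callers flag them excluded instead of dropping them silently.
    denominator : str
        ``"window_mean"`` (default, the field's convention), ``"intercept"``
        (fitted value at the first window trial) or ``"first_trial"``.

    Raises
    ------
    SeriesValidationError
        If the series does not cover the fit window.
    UndefinedRateError
        If the denominator is at or below ``epsilon``.
    """
    lo, hi = int(fit_window[0]), int(fit_window[1])
    if lo < 1 or hi <= lo:
        raise SeriesValidationError(f"invalid fit_window {fit_window}")
    if series.n_trials < hi:
        raise SeriesValidationError(
            f"series {series.labels} has {series.n_trials} trials; fit window needs {hi}")
    if denominator not in DENOMINATORS:
        raise SeriesValidationError(f"unknown denominator {denominator!r}; options: {DENOMINATORS}")

    slope, mean, r2 = _window_ols(series.magnitudes, lo, hi)
    if denominator == "window_mean":
        denom = mean
    elif denominator == "intercept":
        denom = mean + slope * (lo - (lo + hi) / 2.0)  # fitted value at the first window trial
    else:
        denom = float(series.magnitudes[lo - 1])
    if denom <= epsilon:
        raise UndefinedRateError(
            f"series {series.labels}: denominator {denom:.3g} <= epsilon {epsilon:.3g}")
    return SsaRate(**series.labels, rate=100.0 * slope / denom,
                   mean_magnitude=mean, r_squared=r2, fit_window=(lo, hi))


def fit_rates_table(table: pd.DataFrame,
                    fit_window: tuple[int, int] = DEFAULT_FIT_WINDOW,
                    epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Fit every series of a tidy trial table (vectorized).

    ``table`` needs the label columns, ``trial`` and ``magnitude``. Returns
    one row per series with columns ``rate``, ``mean_magnitude``,
    ``r_squared``, ``excluded_reason`` (NaN when the fit is valid,
    ``"near_zero_mean"`` when the denominator is below ``epsilon``; such
    rows carry a NaN rate and are logged, not dropped).

    Raises
    ------
    SeriesValidationError
        If any series has missing or duplicated trials inside the window.
    """
    lo, hi = int(fit_window[0]), int(fit_window[1])
    if lo < 1 or hi <= lo:
        raise SeriesValidationError(f"invalid fit_window {fit_window}")
    label_cols = [c for c in SERIES_LABELS if c in table.columns]
    if not label_cols:
        raise SeriesValidationError("table has no series label columns")
    sub = table[(table["trial"] >= lo) & (table["trial"] <= hi)]
    try:
        wide = sub.pivot(index=label_cols, columns="trial", values="magnitude")
    except ValueError as exc:  # duplicate (series, trial) entries
        raise SeriesValidationError(f"duplicate trials in table: {exc}") from exc
    expected = list(range(lo, hi + 1))
    missing_cols = sorted(set(expected) - set(wide.columns))
    if missing_cols or wide.isna().any().any():
        bad = wide.index[wide.reindex(columns=expected).isna().any(axis=1)].tolist()[:5]
        raise SeriesValidationError(
            f"missing trials in fit window {fit_window}; first offending series: {bad}")
    m = wide[expected].to_numpy(dtype=float)

    t = np.arange(lo, hi + 1, dtype=float)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = m @ tc / sxx
    mean = m.mean(axis=1)
    sst = np.square(m - mean[:, None]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, slope * slope * sxx / sst, 0.0)
        rate = 100.0 * slope / mean

    out = wide.index.to_frame(index=False)
    excluded = mean <= epsilon
    out["rate"] = np.where(excluded, np.nan, rate)
    out["mean_magnitude"] = mean
    out["r_squared"] = r2
    out["excluded_reason"] = np.where(excluded, "near_zero_mean", None)
    n_exc = int(excluded.sum())
    log.info("fit %d series over trials %d-%d; %d excluded (near_zero_mean)",
             len(out), lo, hi, n_exc)
    return out
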