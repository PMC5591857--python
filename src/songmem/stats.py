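"""Inferential battery for pooled FI and expression data.

Four tests cover the analyses this pipeline reports:

* sign test of the median against a fixed null (FI against 1.0) — exact
  binomial for n <= 100, continuity-corrected normal approximation with a
  reported Z statistic for larger samples, ties with the null dropped;
* two-sample Kolmogorov-Smirnov test (d statistic, asymptotic p) for
  comparing FI distributions between groups, hemispheres or regions;
* one- and two-sample t tests (pooled variance) for relative-expression
  contrasts;
* Bonferroni correction, defaulting to m = 2 for the per-hemisphere
  comparison pairs.

Every test returns a :class:`GroupComparison`, a self-describing record of
the statistic, its p value, the sample sizes and the correction applied.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateInputError

__all__ = [
    "GroupComparison", "sign_test", "ks_two_sample",
    "one_sample_t", "two_sample_t", "bonferroni", "two_sided_normal_p",
]

#: Sample size above which the sign test switches from the exact binomial
#: p value to the continuity-corrected normal approximation with a Z
#: statistic (the convention of the statistical software this mirrors).
SIGN_TEST_NORMAL_N = 100


@dataclass
class GroupComparison:
    """One statistical contrast: test, statistic, p, correction, sizes."""

    test: str
    keys: Mapping[str, object]
    statistic_name: str
    statistic: float
    p: float
    n: int | Mapping[str, int]
    alpha: float = 0.05
    null_value: float | None = None
    p_corrected: float | None = None
    ties_dropped: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise DegenerateInputError(f"p out of [0, 1]: {self.p}")
        if self.p_corrected is not None and self.p_corrected < self.p:
            raise DegenerateInputError("corrected p cannot be below the raw p")

    @property
    def effective_p(self) -> float:
        return self.p if self.p_corrected is None else self.p_corrected

    def significant(self) -> bool:
        return self.effective_p < self.alpha

    def to_dict(self) -> dict:
        d = {
            "test": self.test, "keys": dict(self.keys),
            "statistic_name": self.statistic_name,
            "statistic": float(self.statistic), "p": float(self.p),
            "n": self.n if isinstance(self.n, int) else dict(self.n),
            "alpha": self.alpha, "null_value": self.null_value,
            "p_corrected": None if self.p_corrected is None else float(self.p_corrected),
            "ties_dropped": self.ties_dropped,
        }
        d.update(self.extra)
        return d


def two_sided_normal_p(z: float) -> float:
    """Two-sided tail probability of a standard normal statistic."""
    return min(1.0, 2.0 * float(sps.norm.sf(abs(z))))


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    if not np.all(np.isfinite(v)):
        raise DegenerateInputError("sample contains non-finite values")
    return v


def sign_test(values, null: float = 1.0, alpha: float = 0.05,
              keys: Mapping | None = None) -> GroupComparison:
    """Two-sided sign test of ``median(values) = null``.

    Ties with the null are dropped (classical convention) and counted in
    ``ties_dropped``. For n <= 100 the exact binomial p value is returned
    with the count above the null as the statistic; for n > 100 the
    continuity-corrected normal approximation

        Z = (k - n/2 - sign(k - n/2) / 2) / sqrt(n / 4)

    is reported (``statistic_name`` = "Z").

    Raises
    ------
    DegenerateInputError
        If no values remain after dropping ties.
    """
    v = _clean(values)
    ties = int(np.sum(v == null))
    v = v[v != null]
    n = v.size
    if n == 0:
        raise DegenerateInputError("all values tied with the null; sign test undefined")
    k = int(np.sum(v > null))
    if n <= SIGN_TEST_NORMAL_N:
        p = float(sps.binomtest(k, n, 0.5).pvalue)
        stat, name = float(k), "k_above"
    else:
        d = k - n / 2.0
        z = 0.0 if d == 0 else (d - math.copysign(0.5, d)) / math.sqrt(n / 4.0)
        p = two_sided_normal_p(z)
        stat, name = z, "Z"
    return GroupComparison(test="sign_test", keys=dict(keys or {}), statistic_name=name,
                           statistic=stat, p=p, n=n, alpha=alpha, null_value=null,
                           ties_dropped=ties, extra={"k_above_null": k})


def ks_two_sample(a, b, alpha: float = 0.05,
                  keys: Mapping | None = None) -> GroupComparison:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p).

    The statistic d is the supremum distance between the two empirical
    CDFs, so the test is invariant under any common strictly monotone
    transform of both samples.
    """
    a, b = _clean(a), _clean(b)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("ks_two_sample requires two non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return GroupComparison(test="ks_two_sample", keys=dict(keys or {}),
                           statistic_name="d", statistic=float(res.statistic),
                           p=float(min(1.0, res.pvalue)), n={"a": int(a.size), "b": int(b.size)},
                           alpha=alpha)


def one_sample_t(values, mu: float, alpha: float = 0.05,
                 keys: Mapping | None = None) -> GroupComparison:
    """Two-sided one-sample t test against ``mu`` (df = n - 1)."""
    v = _clean(values)
    if v.size < 2:
        raise DegenerateInputError("one_sample_t requires n >= 2")
    if np.ptp(v) == 0:
        raise DegenerateInputError("one_sample_t requires nonzero variance")
    res = sps.ttest_1samp(v, mu)
    return GroupComparison(test="one_sample_t", keys=dict(keys or {}),
                           statistic_name="t", statistic=float(res.statistic),
                           p=float(res.pvalue), n=int(v.size), alpha=alpha, null_value=mu,
                           extra={"df": int(v.size - 1)})


def two_sample_t(a, b, alpha: float = 0.05,
                 keys: Mapping | None = None) -> GroupComparison:
    """Two-sided pooled-variance two-sample t test (df = n_a + n_b - 2)."""
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("two_sample_t requires n >= 2 per sample")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise DegenerateInputError("two_sample_t requires nonzero variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(test="two_sample_t", keys=dict(keys or {}),
                           statistic_name="t", statistic=float(res.statistic),
                           p=float(res.pvalue), n={"a": int(a.size), "b": int(b.size)},
                           alpha=alpha, extra={"df": int(a.size + b.size - 2)})


def bonferroni(p_values: Sequence[float] | float, m: int | None = None):
    """Bonferroni-corrected p values: ``min(1, m * p)``.

    ``m`` defaults to the number of p values supplied; it may be given
    explicitly (the hemisphere comparisons this pipeline reports use m = 2).
    Accepts a scalar or a sequence and returns the matching shape.
    """
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise DegenerateInputError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if int(m) < 1:
        raise DegenerateInputError(f"number of comparisons m must be >= 1, got {m}")
    out = np.minimum(1.0, int(m) * p)
    return float(out[0]) if scalar else out
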