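"""Percentile estimation with exact order-statistic confidence intervals.

The point estimate uses the linear-interpolation sample quantile, while the
confidence interval is the distribution-free exact construction whose
endpoints are order statistics of the sample ("without interpolation").
Because the two conventions differ, the point estimate is not guaranteed to
fall inside the interval for extreme percentiles at small n; this is logged,
not raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

DETECTION_FLOOR_NG_L = 3.0


@dataclass(frozen=True)
class QuantileEstimate:
    """A percentile point estimate plus an exact order-statistic CI.

    ``ci_low``/``ci_high`` are ``None`` when no index pair attains the
    requested confidence (e.g. tiny samples). ``j``/``k`` are the 1-based
    order-statistic indices of the interval endpoints.
    """

    p: float
    n: int
    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    j: Optional[int] = None
    k: Optional[int] = None
    achieved_coverage: Optional[float] = None

    @property
    def ci_available(self) -> bool:
        return self.ci_low is not None


def apply_detection_floor(
    values: Sequence[float], floor: float = DETECTION_FLOOR_NG_L
) -> np.ndarray:
    """Replace every value below ``floor`` by ``floor`` (left-censoring rule).

    Order and length are preserved. Raises :class:`ValidationError` on
    non-finite input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        bad = np.flatnonzero(~np.isfinite(arr))
        raise ValidationError(f"non-finite values at positions {bad.tolist()}")
    return np.maximum(arr, floor)


def percentile_point(values: Sequence[float], p: float) -> float:
    """Linear-interpolation sample percentile (1-based order statistics).

    h = (n-1)*p/100; result interpolates between x_(floor(h)+1) and the next
    order statistic.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("percentile of an empty sample is undefined")
    if not 0 <= p <= 100:
        raise DomainError(f"percentile level {p} outside [0, 100]")
    return float(np.percentile(arr, p, method="linear"))


def _search_exact_pair(n: int, p: float, conf: float):
    """Minimal-width (j, k) with P(j <= B <= k-1) >= conf, B ~ Bin(n, p/100).

    Ties on width are broken by maximal coverage, then by smallest j.
    Returns (j, k, coverage) or None.
    """
    prob = p / 100.0
    # cdf[m] = P(B <= m) for m = 0..n
    cdf = stats.binom.cdf(np.arange(n + 1), n, prob)
    # For each j in 1..n-1, the smallest k with cdf[k-1] - cdf[j-1] >= conf.
    lower = cdf[: n - 1]  # P(B <= j-1) for j = 1..n-1
    targets = conf + lower
    km1 = np.searchsorted(cdf, targets, side="left")  # smallest m: cdf[m] >= target
    js = np.arange(1, n)
    ks = km1 + 1
    valid = (ks <= n) & (ks > js) & (km1 <= n - 1)
    # guard against searchsorted landing past the end
    valid &= km1 < len(cdf)
    if not np.any(valid):
        return None
    js, ks = js[valid], ks[valid]
    cov = cdf[ks - 1] - lower[valid]
    # float-safe re-check
    ok = cov >= conf - 1e-12
    if not np.any(ok):
        return None
    js, ks, cov = js[ok], ks[ok], cov[ok]
    width = ks - js
    wmin = width.min()
    cand = width == wmin
    js, ks, cov = js[cand], ks[cand], cov[cand]
    best = np.lexsort((js, -cov))[0]
    return int(js[best]), int(ks[best]), float(cov[best])


def exact_quantile_ci(
    values: Sequence[float], p: float, conf: float = 0.95
) -> QuantileEstimate:
    """Exact two-sided CI for the p-th percentile from binomial tail sums.

    Among all 1 <= j < k <= n with coverage P(j <= B <= k-1) >= ``conf``
    (B ~ Binomial(n, p/100)), the minimal-width pair is chosen; ties go to
    maximal coverage, then smallest j. The interval is [x_(j), x_(k)] on the
    sorted sample, without interpolation. When no pair attains ``conf`` the
    CI is reported unavailable.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise DomainError("confidence interval of an empty sample is undefined")
    if not 0 < p < 100:
        raise DomainError(f"percentile level {p} outside (0, 100)")
    if not 0 < conf < 1:
        raise DomainError(f"confidence level {conf} outside (0, 1)")

    point = percentile_point(arr, p)
    pair = _search_exact_pair(n, p, conf) if n >= 2 else None
    if pair is None:
        return QuantileEstimate(p=p, n=n, point=point)
    j, k, cov = pair
    lo, hi = float(arr[j - 1]), float(arr[k - 1])
    if not lo <= point <= hi:
        logger.info(
            "point estimate %.4g outside exact CI [%.4g, %.4g] (p=%s, n=%d); "
            "expected for extreme percentiles at small n",
            point, lo, hi, p, n,
        )
    return QuantileEstimate(
        p=p, n=n, point=point, ci_low=lo, ci_high=hi, j=j, k=k,
        achieved_coverage=cov,
    )
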