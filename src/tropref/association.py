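"""Rank-based association measures: Spearman correlation and the
two-sample rank test used for per-stratum sex comparisons."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError

#: Exact permutation enumeration is limited to this many observations.
EXACT_LIMIT = 10


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float


def spearman(
    x: Sequence[float], y: Sequence[float], *, method: str = "t"
) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of mid-ranks; the two-sided p-value uses
    the t-approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df (reported as
    0 when |rho| = 1). ``method="exact"`` enumerates all permutations
    (only for n <= 10) and is intended for small-sample verification.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DomainError("x and y must be 1-D of equal length")
    n = xa.size
    if n < 3:
        raise DomainError("spearman requires n >= 3")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DomainError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))

    if method == "exact":
        if n > EXACT_LIMIT:
            raise DomainError(f"exact permutation limited to n <= {EXACT_LIMIT}")
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(np.dot(rx_c, rx_c) * np.dot(ry_c, ry_c)))
        obs = abs(float(np.dot(rx_c, ry_c)) / denom)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(float(np.dot(rx_c, ry_c[list(perm)])) / denom)
            count += r >= obs - 1e-12
            total += 1
        return CorrelationResult(rho=rho, n=n, p_value=count / total)
    if method != "t":
        raise DomainError(f"unknown method {method!r}")

    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, n=n, p_value=min(p, 1.0))


def _mann_whitney_u(values_f: np.ndarray, values_m: np.ndarray) -> float:
    pooled = np.concatenate([values_f, values_m])
    ranks = stats.rankdata(pooled)
    n_f = values_f.size
    return float(ranks[:n_f].sum() - n_f * (n_f + 1) / 2.0)


def sex_difference_test(
    values_f: Sequence[float], values_m: Sequence[float], *, method: str = "auto"
) -> float:
    """Two-sided Mann–Whitney U p-value.

    Large samples use the normal approximation with tie correction and no
    continuity correction, so identical groups give p = 1 exactly (U at its
    mean). ``method="exact"`` enumerates group assignments (pooled n <= 12),
    handling ties through mid-ranks; ``"auto"`` picks exact whenever the
    pooled sample is small enough, where the normal approximation is poor.
    """
    f = np.asarray(values_f, dtype=float)
    m = np.asarray(values_m, dtype=float)
    if f.size == 0 or m.size == 0:
        raise DomainError("both groups must be nonempty")
    n_f, n_m = f.size, m.size
    n = n_f + n_m
    if method == "auto":
        method = "exact" if n <= 12 else "normal"
    u_obs = _mann_whitney_u(f, m)
    mean_u = n_f * n_m / 2.0

    if method == "exact":
        if n > 12:
            raise DomainError("exact enumeration limited to n_f + n_m <= 12")
        pooled = np.concatenate([f, m])
        ranks = stats.rankdata(pooled)
        offset = n_f * (n_f + 1) / 2.0
        dev_obs = abs(u_obs - mean_u)
        count = total = 0
        for idx in itertools.combinations(range(n), n_f):
            u = float(ranks[list(idx)].sum() - offset)
            count += abs(u - mean_u) >= dev_obs - 1e-12
            total += 1
        return count / total
    if method != "normal":
        raise DomainError(f"unknown method {method!r}")

    pooled = np.concatenate([f, m])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var_u = n_f * n_m / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 1.0  # all observations identical
    z = (u_obs - mean_u) / math.sqrt(var_u)
    return min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
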