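"""Floating (sliding rectangular window) percentile curves and surfaces.

At every grid point the statistic is recomputed from the subjects whose
axis value lies within a closed window around the point; underpopulated
windows yield missing values rather than wild extreme-percentile estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .errors import DomainError, ValidationError
from .quantiles import percentile_point

logger = logging.getLogger(__name__)

Stat = Union[str, float]  # "median" or a percentile level


@dataclass(frozen=True)
class AxisConfig:
    """Grid step, window half-width and minimum window occupancy for an axis."""

    step: float
    half_width: float
    min_window_n: int = 20

    def __post_init__(self):
        if self.step <= 0 or self.half_width <= 0:
            raise DomainError("step and half_width must be > 0")
        if self.min_window_n < 1:
            raise DomainError("min_window_n must be >= 1")


#: Default windowing per axis: age ±5 yr in 1-yr steps, creatinine ±15 in
#: steps of 10 µmol/L, eGFR ±10 in steps of 3 mL/min/1.73 m².
DEFAULT_AXES = {
    "age": AxisConfig(step=1.0, half_width=5.0),
    "creatinine": AxisConfig(step=10.0, half_width=15.0),
    "egfr": AxisConfig(step=3.0, half_width=10.0),
}


@dataclass(frozen=True)
class FloatingCurve:
    axis: str
    stat: Stat
    grid: np.ndarray
    values: np.ndarray  # NaN where window underpopulated
    window_n: np.ndarray
    half_width: float
    step: float


@dataclass(frozen=True)
class SurfaceGrid:
    age_grid: np.ndarray
    creatinine_grid: np.ndarray
    values: np.ndarray  # shape (len(age_grid), len(creatinine_grid))
    window_n: np.ndarray


def _stat_level(stat: Stat) -> float:
    if isinstance(stat, str):
        if stat == "median":
            return 50.0
        if stat.startswith("p"):
            try:
                return float(stat[1:])
            except ValueError:
                pass
        raise DomainError(f"unknown statistic {stat!r}")
    level = float(stat)
    if not 0 <= level <= 100:
        raise DomainError(f"percentile level {level} outside [0, 100]")
    return level


def _make_grid(xs: np.ndarray, step: float) -> np.ndarray:
    k0 = math.floor(xs.min() / step)
    k1 = math.ceil(xs.max() / step)
    return np.arange(k0, k1 + 1) * step


def floating_stat_curve(
    xs: Sequence[float],
    ys: Sequence[float],
    axis_config: AxisConfig,
    stat: Stat = "median",
    *,
    axis: str = "x",
) -> FloatingCurve:
    """Windowed percentile of ``ys`` along ``xs`` on a regular grid.

    The grid spans [min(xs), max(xs)] rounded outward to step multiples;
    each window is the closed interval |x − g| ≤ half_width.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("xs and ys must be 1-D of equal length")
    if x.size == 0:
        raise DomainError("cannot build a curve from an empty sample")
    level = _stat_level(stat)
    grid = _make_grid(x, axis_config.step)
    values = np.full(grid.shape, np.nan)
    counts = np.zeros(grid.shape, dtype=int)
    order = np.argsort(x)
    xs_sorted, ys_sorted = x[order], y[order]
    for i, g in enumerate(grid):
        lo = np.searchsorted(xs_sorted, g - axis_config.half_width, side="left")
        hi = np.searchsorted(xs_sorted, g + axis_config.half_width, side="right")
        counts[i] = hi - lo
        if counts[i] >= axis_config.min_window_n:
            values[i] = percentile_point(ys_sorted[lo:hi], level)
    n_under = int((counts < axis_config.min_window_n).sum())
    if n_under:
        logger.warning(
            "%d/%d grid points under min_window_n=%d on axis %s",
            n_under, grid.size, axis_config.min_window_n, axis,
        )
    return FloatingCurve(
        axis=axis, stat=stat, grid=grid, values=values, window_n=counts,
        half_width=axis_config.half_width, step=axis_config.step,
    )


def percentile_band(
    xs: Sequence[float],
    ys: Sequence[float],
    axis_config: AxisConfig,
    p_low: float = 97.0,
    p_high: float = 99.4,
    band_half_width: float = 10.0,
    *,
    axis: str = "x",
) -> Tuple[FloatingCurve, FloatingCurve]:
    """Lower/upper floating percentile curves using the band's own window."""
    if p_low > p_high:
        raise ValidationError(f"p_low={p_low} exceeds p_high={p_high}")
    cfg = replace(axis_config, half_width=band_half_width)
    low = floating_stat_curve(xs, ys, cfg, p_low, axis=axis)
    high = floating_stat_curve(xs, ys, cfg, p_high, axis=axis)
    return low, high


def floating_surface(
    ages: Sequence[float],
    creatinines: Sequence[float],
    ys: Sequence[float],
    age_config: Optional[AxisConfig] = None,
    cr_config: Optional[AxisConfig] = None,
    stat: Stat = 99.0,
) -> SurfaceGrid:
    """Windowed percentile on the (age, creatinine) grid.

    At each node the statistic pools subjects inside the rectangular window
    |age − a| ≤ hw_age and |creatinine − c| ≤ hw_cr; nodes with fewer than
    min_window_n subjects are missing.
    """
    age_config = age_config or DEFAULT_AXES["age"]
    cr_config = cr_config or DEFAULT_AXES["creatinine"]
    a = np.asarray(ages, dtype=float)
    c = np.asarray(creatinines, dtype=float)
    y = np.asarray(ys, dtype=float)
    if not (a.shape == c.shape == y.shape) or a.ndim != 1:
        raise ValidationError("ages, creatinines and ys must be 1-D of equal length")
    if a.size == 0:
        raise DomainError("cannot build a surface from an empty sample")
    level = _stat_level(stat)
    age_grid = _make_grid(a, age_config.step)
    cr_grid = _make_grid(c, cr_config.step)
    min_n = max(age_config.min_window_n, cr_config.min_window_n)
    values = np.full((age_grid.size, cr_grid.size), np.nan)
    counts = np.zeros((age_grid.size, cr_grid.size), dtype=int)
    for i, ga in enumerate(age_grid):
        in_age = np.abs(a - ga) <= age_config.half_width
        if not in_age.any():
            continue
        c_sub, y_sub = c[in_age], y[in_age]
        for j, gc in enumerate(cr_grid):
            sel = np.abs(c_sub - gc) <= cr_config.half_width
            counts[i, j] = int(sel.sum())
            if counts[i, j] >= min_n:
                values[i, j] = percentile_point(y_sub[sel], level)
    return SurfaceGrid(
        age_grid=age_grid, creatinine_grid=cr_grid, values=values,
        window_n=counts,
    )


def curve_to_frame(curve: FloatingCurve):
    import pandas as pd

    return pd.DataFrame(
        {
            "grid": curve.grid,
            "value": curve.values,
            "window_n": curve.window_n,
        }
    )


def surface_to_frame(surface: SurfaceGrid):
    """Long-format (age, creatinine, value, n) frame."""
    import pandas as pd

    aa, cc = np.meshgrid(surface.age_grid, surface.creatinine_grid, indexing="ij")
    return pd.DataFrame(
        {
            "age": aa.ravel(),
            "creatinine": cc.ravel(),
            "value": surface.values.ravel(),
            "window_n": surface.window_n.ravel(),
        }
    )
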