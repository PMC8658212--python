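"""Per-sex stratified reference tables (median / 99th percentile).

Printed integer bin labels are backed by contiguous half-open real
intervals (lo, hi], the lowest bin closed at its lower edge, so real-valued
ages and creatinines bin without gaps. Out-of-range values go to an
"unbinned" row — counted, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DomainError
from .quantiles import QuantileEstimate, exact_quantile_ci, percentile_point
from .renal import add_renal_columns

UNBINNED = "unbinned"

#: Bin scheme: (edges, labels). Interval i is (edges[i], edges[i+1]],
#: except the first which is [edges[0], edges[1]].
BinScheme = Tuple[Tuple[float, ...], Tuple[str, ...]]

SCHEMES: Dict[str, BinScheme] = {
    "age": (
        (20.0, 40.0, 50.0, 60.0, 70.0, 80.0),
        ("20–40", "41–50", "51–60", "61–70", "71–80"),
    ),
    "creatinine": (
        (0.0, 50.0, 100.0, 150.0, 200.0, 250.0),
        ("0–50", "51–100", "101–150", "151–200", "201–250"),
    ),
    # variant with the sparse upper creatinine bins merged
    "creatinine_merged": (
        (0.0, 50.0, 100.0, 150.0, 250.0),
        ("0–50", "51–100", "101–150", "151–250"),
    ),
    "egfr": (
        (0.0, 30.0, 60.0, 90.0, 120.0, 150.0),
        ("0–30", "31–60", "61–90", "91–120", "121–150"),
    ),
}

#: Which cohort column each scheme bins on.
SCHEME_COLUMN = {
    "age": "age",
    "creatinine": "creatinine_umolL",
    "creatinine_merged": "creatinine_umolL",
    "egfr": "egfr",
}

#: Schemes whose P99 is suppressed below the minimum group size.
MIN_N_SCHEMES = {"creatinine", "creatinine_merged", "egfr"}


def assign_bin(
    value: Union[float, np.ndarray], scheme: str
) -> Union[str, np.ndarray]:
    """Label for ``value`` under the named bin scheme; out of range → "unbinned"."""
    if scheme not in SCHEMES:
        raise DomainError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    edges_t, labels_t = SCHEMES[scheme]
    edges = np.asarray(edges_t)
    scalar = np.isscalar(value)
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    idx = np.searchsorted(edges, arr, side="left") - 1
    idx = np.where(arr == edges[0], 0, idx)  # lowest bin closed at its lower edge
    out_of_range = (arr < edges[0]) | (arr > edges[-1])
    labels = np.array(labels_t + (UNBINNED,), dtype=object)
    idx = np.where(out_of_range, len(labels_t), idx)
    out = labels[idx]
    return str(out[0]) if scalar else out


@dataclass(frozen=True)
class StratumSummary:
    """Summary statistics for one sex × bin stratum."""

    sex: str
    bin_label: str
    n: int
    median: Optional[float]
    p99: Optional[QuantileEstimate]
    median_age: Optional[float] = None
    age_iqr: Optional[Tuple[float, float]] = None


def reference_table(
    cohort: pd.DataFrame,
    scheme: str,
    *,
    percentile: float = 99.0,
    conf: float = 0.95,
    min_n: int = 300,
    floor: float = 3.0,
) -> List[StratumSummary]:
    """One :class:`StratumSummary` per sex × bin (plus "unbinned").

    Medians are always reported for populated strata. The upper percentile
    is reported unconditionally for the age scheme but only for strata with
    n ≥ ``min_n`` under the creatinine/eGFR schemes. The creatinine schemes
    additionally report median age with IQR. Troponin values are floored
    before any statistic.
    """
    if scheme not in SCHEMES:
        raise DomainError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    df = cohort
    if SCHEME_COLUMN[scheme] == "egfr" and "egfr" not in df.columns:
        df = add_renal_columns(df)
    values = df[SCHEME_COLUMN[scheme]].to_numpy(dtype=float)
    bins = assign_bin(values, scheme) if len(df) else np.array([], dtype=object)
    tnt = np.maximum(df["troponin_ngL"].to_numpy(dtype=float), floor)
    ages = df["age"].to_numpy(dtype=float)
    sexes = df["sex"].to_numpy() if len(df) else np.array([], dtype=object)

    with_age = scheme.startswith("creatinine")
    apply_min_n = scheme in MIN_N_SCHEMES
    labels = SCHEMES[scheme][1] + (UNBINNED,)

    out: List[StratumSummary] = []
    for sex in ("F", "M"):
        for label in labels:
            mask = (sexes == sex) & (bins == label)
            n = int(mask.sum())
            if n == 0:
                out.append(StratumSummary(sex, label, 0, None, None))
                continue
            v = tnt[mask]
            median = percentile_point(v, 50.0)
            p99: Optional[QuantileEstimate] = None
            if label != UNBINNED and (not apply_min_n or n >= min_n):
                p99 = exact_quantile_ci(v, percentile, conf)
            med_age = iqr = None
            if with_age:
                med_age = percentile_point(ages[mask], 50.0)
                iqr = (
                    percentile_point(ages[mask], 25.0),
                    percentile_point(ages[mask], 75.0),
                )
            out.append(
                StratumSummary(sex, label, n, median, p99, med_age, iqr)
            )
    return out


def table_to_frame(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    """Flatten summaries for CSV export (unavailable values as empty fields)."""
    rows = []
    for s in summaries:
        q = s.p99
        rows.append(
            {
                "sex": s.sex,
                "bin": s.bin_label,
                "n": s.n,
                "median_age": s.median_age,
                "age_q1": s.age_iqr[0] if s.age_iqr else None,
                "age_q3": s.age_iqr[1] if s.age_iqr else None,
                "median": s.median,
                "p99": q.point if q else None,
                "p99_ci_low": q.ci_low if q else None,
                "p99_ci_high": q.ci_high if q else None,
                "p99_coverage": q.achieved_coverage if q else None,
            }
        )
    return pd.DataFrame(rows)
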