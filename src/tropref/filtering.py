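"""Exclusion cascade producing the cardiac-healthy study cohorts.

Stage order is fixed: (1) cardiac disease / angina history, (2) abnormal
NT-proBNP (age-dependent limit) or HbA1c, survivors form cohort 2,
(3) eGFR below the renal cutoff, survivors form cohort 1. All thresholds
are strict inequalities; input frames are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .renal import ckd_epi_egfr
from .synthetic import COHORT_COLUMNS

#: Columns apply_exclusions needs on every record.
REQUIRED_COLUMNS = tuple(c for c in COHORT_COLUMNS)


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds of the exclusion cascade.

    NT-proBNP limit is age-dependent: ``ntprobnp_limit_young`` below
    ``ntprobnp_age_cut`` years, ``ntprobnp_limit_old`` at or above it.
    """

    ntprobnp_limit_young: float = 125.0
    ntprobnp_age_cut: float = 75.0
    ntprobnp_limit_old: float = 450.0
    hba1c_limit: float = 42.0
    egfr_cutoff: float = 60.0

    def __post_init__(self):
        for name in (
            "ntprobnp_limit_young", "ntprobnp_limit_old",
            "hba1c_limit", "egfr_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(name, "must be > 0")
        if self.ntprobnp_limit_old < self.ntprobnp_limit_young:
            raise ConfigurationError(
                "ntprobnp_limit_old", "must be >= ntprobnp_limit_young"
            )


@dataclass(frozen=True)
class FilterReport:
    """Per-stage audit counts of the cascade."""

    n_input: int
    n_excluded_cardiac: int
    n_excluded_biomarker: int
    n_cohort2: int
    n_excluded_renal: int
    n_cohort1: int

    def to_dict(self) -> dict:
        return asdict(self)


def _validate(frame: pd.DataFrame) -> None:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")
    numeric = [
        "age", "troponin_ngL", "creatinine_umolL", "ntprobnp_ngL",
        "hba1c_mmolmol",
    ]
    values = frame[numeric].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(values), axis=1)
    if frame["cardiac_disease"].isna().any():
        bad |= frame["cardiac_disease"].isna().to_numpy()
    if bad.any():
        ids = frame.loc[bad, "id"].tolist()
        raise ValidationError(f"records with missing/non-finite fields: {ids}")


def apply_exclusions(
    cohort: pd.DataFrame, config: ExclusionConfig | None = None
) -> Tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Run the cascade; returns (cohort1, cohort2, report).

    cohort1 ⊆ cohort2 ⊆ input, rows in original order, input unchanged.
    An empty input yields empty outputs and an all-zero report.
    """
    config = config or ExclusionConfig()
    n_input = len(cohort)
    if n_input == 0:
        empty = cohort.copy()
        return empty, empty.copy(), FilterReport(0, 0, 0, 0, 0, 0)
    _validate(cohort)

    healthy = cohort.loc[cohort["cardiac_disease"].astype(int) == 0]
    n_cardiac = n_input - len(healthy)

    age = healthy["age"].to_numpy(dtype=float)
    bnp_limit = np.where(
        age >= config.ntprobnp_age_cut,
        config.ntprobnp_limit_old,
        config.ntprobnp_limit_young,
    )
    abnormal = (healthy["ntprobnp_ngL"].to_numpy(dtype=float) > bnp_limit) | (
        healthy["hba1c_mmolmol"].to_numpy(dtype=float) > config.hba1c_limit
    )
    cohort2 = healthy.loc[~abnormal].copy()
    n_biomarker = int(abnormal.sum())

    egfr = ckd_epi_egfr(
        cohort2["creatinine_umolL"].to_numpy(dtype=float),
        cohort2["age"].to_numpy(dtype=float),
        cohort2["sex"].to_numpy(),
    )
    renal_ok = egfr >= config.egfr_cutoff
    cohort1 = cohort2.loc[renal_ok].copy()
    n_renal = int((~renal_ok).sum())

    report = FilterReport(
        n_input=n_input,
        n_excluded_cardiac=n_cardiac,
        n_excluded_biomarker=n_biomarker,
        n_cohort2=len(cohort2),
        n_excluded_renal=n_renal,
        n_cohort1=len(cohort1),
    )
    return cohort1, cohort2, report
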