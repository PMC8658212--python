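"""eGFR from serum creatinine via the 2009 CKD-EPI equation.

Creatinine arrives in µmol/L (the cohort's reporting unit) and is converted
to mg/dL internally. The race coefficient is not applied by default; a flag
exists for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .errors import DomainError

ArrayLike = Union[float, np.ndarray]

UMOL_PER_MGDL = 88.4

_KAPPA = {"F": 0.7, "M": 0.9}
_ALPHA = {"F": -0.329, "M": -0.411}
_SEX_COEF = {"F": 1.018, "M": 1.0}
_RACE_COEF = 1.159

EGFR_BIN_EDGES = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
EGFR_BIN_LABELS = ("0–30", "31–60", "61–90", "91–120", "121–150")
OUT_OF_RANGE_LABEL = "unbinned"


@dataclass(frozen=True)
class RenalResult:
    creatinine_mgdl: float
    egfr: float


def creatinine_umol_to_mgdl(scr: ArrayLike) -> ArrayLike:
    """Convert serum creatinine from µmol/L to mg/dL (divide by 88.4)."""
    arr = np.asarray(scr, dtype=float)
    if np.any(arr < 0):
        raise DomainError("creatinine must be non-negative")
    out = arr / UMOL_PER_MGDL
    return float(out) if np.isscalar(scr) else out


def _normalize_sex(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.ndim == 0:
        s = s.reshape(1)
    s = np.char.upper(s.astype(str))
    bad = ~np.isin(s, ("F", "M"))
    if np.any(bad):
        raise DomainError(f"sex must be 'F' or 'M', got {np.unique(s[bad])}")
    return s


def ckd_epi_egfr(
    scr_umol: ArrayLike, age: ArrayLike, sex, *, race_black: bool = False
) -> ArrayLike:
    """2009 CKD-EPI eGFR in mL/min/1.73 m².

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age
           · (1.018 if female) [· 1.159 if race_black]

    with Scr in mg/dL, κ = 0.7 (F) / 0.9 (M), α = −0.329 (F) / −0.411 (M).
    """
    scalar = np.isscalar(scr_umol) and np.isscalar(age)
    scr = np.atleast_1d(np.asarray(scr_umol, dtype=float))
    age_a = np.atleast_1d(np.asarray(age, dtype=float))
    sex_a = _normalize_sex(sex)
    scr, age_a, sex_a = np.broadcast_arrays(scr, age_a, sex_a)
    if np.any(scr <= 0):
        raise DomainError("creatinine must be positive")
    if np.any(age_a < 18):
        raise DomainError("CKD-EPI is defined for adults (age >= 18)")

    female = sex_a == "F"
    kappa = np.where(female, _KAPPA["F"], _KAPPA["M"])
    alpha = np.where(female, _ALPHA["F"], _ALPHA["M"])
    ratio = (scr / UMOL_PER_MGDL) / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age_a
        * np.where(female, _SEX_COEF["F"], 1.0)
    )
    if race_black:
        egfr = egfr * _RACE_COEF
    return float(egfr[0]) if scalar else egfr


def renal_result(scr_umol: float, age: float, sex: str) -> RenalResult:
    return RenalResult(
        creatinine_mgdl=creatinine_umol_to_mgdl(scr_umol),
        egfr=ckd_epi_egfr(scr_umol, age, sex),
    )


def egfr_bin(egfr: ArrayLike) -> Union[str, np.ndarray]:
    """Assign eGFR to the contiguous bins (0,30], (30,60], ..., (120,150].

    Values above 150 get the out-of-range label.
    """
    scalar = np.isscalar(egfr)
    arr = np.atleast_1d(np.asarray(egfr, dtype=float))
    if np.any(arr <= 0):
        raise DomainError("eGFR must be positive")
    edges = np.asarray(EGFR_BIN_EDGES)
    idx = np.searchsorted(edges, arr, side="left") - 1
    labels = np.array(EGFR_BIN_LABELS + (OUT_OF_RANGE_LABEL,), dtype=object)
    idx = np.where(arr > edges[-1], len(EGFR_BIN_LABELS), idx)
    out = labels[idx]
    return str(out[0]) if scalar else out


def add_renal_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the cohort frame with creatinine_mgdl and egfr columns."""
    out = frame.copy()
    out["creatinine_mgdl"] = creatinine_umol_to_mgdl(
        frame["creatinine_umolL"].to_numpy()
    )
    out["egfr"] = ckd_epi_egfr(
        frame["creatinine_umolL"].to_numpy(),
        frame["age"].to_numpy(),
        frame["sex"].to_numpy(),
    )
    return out
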