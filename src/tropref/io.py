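"""Cohort CSV dialect: UTF-8, comma-separated, '.' decimals, mandatory header.

Lines starting with '#' are treated as comments (used for config-hash
stamps), so a stamped file round-trips through these readers unchanged.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import ValidationError
from .synthetic import COHORT_COLUMNS

PathLike = Union[str, Path]


def write_cohort_csv(
    frame: pd.DataFrame, path: PathLike, *, stamp: Optional[str] = None
) -> None:
    """Write a cohort frame in the canonical column order."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort frame missing columns: {missing}")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if stamp:
            fh.write(f"# config={stamp}\n")
        frame.loc[:, list(COHORT_COLUMNS)].to_csv(fh, index=False)


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#", encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns: {missing}")
    frame["sex"] = frame["sex"].astype(str).str.upper()
    bad_sex = ~frame["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise ValidationError(
            f"{path}: invalid sex values {sorted(frame.loc[bad_sex, 'sex'].unique())}"
        )
    frame["cardiac_disease"] = frame["cardiac_disease"].astype(int)
    return frame


def write_frame_csv(
    frame: pd.DataFrame, path: PathLike, *, stamp: Optional[str] = None
) -> None:
    """Write an analysis output frame (tables, curves, surfaces)."""
    with open(Path(path), "w", encoding="utf-8", newline="") as fh:
        if stamp:
            fh.write(f"# config={stamp}\n")
        frame.to_csv(fh, index=False)
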