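"""End-to-end orchestration: simulate/ingest → filter → tables → curves →
surface → correlations, with a YAML config and a consolidated report.

Every output file is stamped with a hash of the resolved configuration so a
report bundle can be traced back to the exact parameters that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .association import sex_difference_test, spearman
from .curves import (
    AxisConfig,
    DEFAULT_AXES,
    floating_stat_curve,
    floating_surface,
    surface_to_frame,
)
from .errors import ConfigurationError, TroprefError
from .filtering import ExclusionConfig, apply_exclusions
from .quantiles import apply_detection_floor
from .reference import reference_table, table_to_frame
from .renal import add_renal_columns
from .synthetic import GeneratorParams, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``input_csv`` takes precedence over the generator; with neither
    customized, defaults reproduce the reference procedure on synthetic data.
    """

    input_csv: Optional[str] = None
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    min_n: int = 300
    conf: float = 0.95
    detection_floor: float = 3.0
    merge_sparse_creatinine_bins: bool = False
    axes: Dict[str, AxisConfig] = field(default_factory=lambda: dict(DEFAULT_AXES))
    seed: Optional[int] = None
    outdir: str = "tropref_out"

    def resolved_generator(self) -> GeneratorParams:
        if self.seed is not None:
            return dataclasses.replace(self.generator, seed=self.seed)
        return self.generator

    def to_dict(self) -> Dict[str, Any]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(dataclasses.asdict(self))

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where its outputs land
        payload = self.to_dict()
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a (possibly partial) YAML document."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config", "top level must be a mapping")
    kwargs: Dict[str, Any] = {}
    if "generator" in raw:
        kwargs["generator"] = GeneratorParams(**raw.pop("generator"))
    if "exclusion" in raw:
        kwargs["exclusion"] = ExclusionConfig(**raw.pop("exclusion"))
    if "axes" in raw:
        kwargs["axes"] = {
            name: AxisConfig(**cfg) for name, cfg in raw.pop("axes").items()
        }
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key not in known:
            raise ConfigurationError(key, "unknown configuration key")
        kwargs[key] = value
    return RunConfig(**kwargs)


def _safe_spearman(x, y):
    from .errors import DomainError

    try:
        return dataclasses.asdict(spearman(x, y))
    except DomainError as err:  # tiny or degenerate stratum: report, don't abort
        return {"rho": None, "n": int(len(x)), "p_value": None, "error": str(err)}


def _correlations(cohort1: pd.DataFrame, cohort2: pd.DataFrame, floor: float):
    """The correlation set of the analysis: age and eGFR pooled, creatinine
    per sex."""
    t1 = apply_detection_floor(cohort1["troponin_ngL"], floor)
    t2 = apply_detection_floor(cohort2["troponin_ngL"], floor)
    out = {
        "age_troponin_cohort1": _safe_spearman(cohort1["age"], t1),
        "egfr_troponin_cohort2": _safe_spearman(cohort2["egfr"], t2),
    }
    for sex in ("F", "M"):
        m = (cohort2["sex"] == sex).to_numpy()
        out[f"creatinine_troponin_cohort2_{sex}"] = _safe_spearman(
            cohort2["creatinine_umolL"].to_numpy()[m], t2[m]
        )
    return out


def _age_table_with_p(cohort1: pd.DataFrame, conf: float, floor: float):
    """Age-scheme reference table plus the per-bin sex-difference p-value."""
    from .reference import SCHEMES, assign_bin

    summaries = reference_table(
        cohort1, "age", conf=conf, floor=floor
    )
    frame = table_to_frame(summaries)
    tnt = apply_detection_floor(cohort1["troponin_ngL"], floor)
    bins = assign_bin(cohort1["age"].to_numpy(dtype=float), "age")
    sexes = cohort1["sex"].to_numpy()
    pvals = {}
    for label in SCHEMES["age"][1]:
        f = tnt[(sexes == "F") & (bins == label)]
        m = tnt[(sexes == "M") & (bins == label)]
        pvals[label] = (
            sex_difference_test(f, m) if len(f) and len(m) else None
        )
    frame["sex_diff_p"] = [pvals.get(b) for b in frame["bin"]]
    return frame


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Execute the full analysis; returns a manifest of outputs and counts.

    Deterministic given the config (the seed is part of it). On any stage
    failure the partially written outputs are removed and the error is
    re-raised with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = config.config_hash()
    written: List[Path] = []
    stage = "setup"

    def emit_csv(frame: pd.DataFrame, name: str, cohort: bool = False):
        path = outdir / name
        if cohort:
            tio.write_cohort_csv(frame, path, stamp=stamp)
        else:
            tio.write_frame_csv(frame, path, stamp=stamp)
        written.append(path)
        return path

    def emit_json(obj, name: str):
        path = outdir / name
        path.write_text(
            json.dumps({"config": stamp, **obj}, indent=2, default=str) + "\n",
            encoding="utf-8",
        )
        written.append(path)
        return path

    t_start = time.time()
    try:
        stage = "ingest"
        if config.input_csv is not None:
            cohort = tio.read_cohort_csv(config.input_csv)
            logger.info("read %d subjects from %s", len(cohort), config.input_csv)
        else:
            cohort = generate_cohort(config.resolved_generator())
            logger.info("generated %d synthetic subjects", len(cohort))

        stage = "filter"
        cohort1, cohort2, report = apply_exclusions(cohort, config.exclusion)
        logger.info(
            "cascade: %d -> cohort2 %d -> cohort1 %d",
            report.n_input, report.n_cohort2, report.n_cohort1,
        )
        stage = "egfr"
        cohort1 = add_renal_columns(cohort1)
        cohort2 = add_renal_columns(cohort2)
        emit_csv(cohort1, "cohort1.csv", cohort=True)
        emit_csv(cohort2, "cohort2.csv", cohort=True)
        emit_json(report.to_dict(), "filter_report.json")

        stage = "reference-tables"
        floor = config.detection_floor
        emit_csv(_age_table_with_p(cohort1, config.conf, floor), "table_age.csv")
        creat_scheme = (
            "creatinine_merged"
            if config.merge_sparse_creatinine_bins
            else "creatinine"
        )
        for scheme, name in ((creat_scheme, "table_creatinine.csv"),
                             ("egfr", "table_egfr.csv")):
            summaries = reference_table(
                cohort2, scheme, conf=config.conf, min_n=config.min_n,
                floor=floor,
            )
            emit_csv(table_to_frame(summaries), name)

        stage = "curves"
        from .curves import curve_to_frame

        for sex in ("F", "M"):
            sub1 = cohort1[cohort1["sex"] == sex]
            sub2 = cohort2[cohort2["sex"] == sex]
            t_sub1 = apply_detection_floor(sub1["troponin_ngL"], floor)
            t_sub2 = apply_detection_floor(sub2["troponin_ngL"], floor)
            for stat, tag in (("median", "median"), (99.0, "p99")):
                curve = floating_stat_curve(
                    sub1["age"], t_sub1, config.axes["age"], stat, axis="age"
                )
                emit_csv(curve_to_frame(curve), f"curve_age_{tag}_{sex}.csv")
            for axis, col in (("creatinine", "creatinine_umolL"), ("egfr", "egfr")):
                curve = floating_stat_curve(
                    sub2[col], t_sub2, config.axes[axis], "median", axis=axis
                )
                emit_csv(curve_to_frame(curve), f"curve_{axis}_median_{sex}.csv")

        stage = "surface"
        for sex in ("F", "M"):
            sub2 = cohort2[cohort2["sex"] == sex]
            surf = floating_surface(
                sub2["age"],
                sub2["creatinine_umolL"],
                apply_detection_floor(sub2["troponin_ngL"], floor),
                config.axes["age"],
                config.axes["creatinine"],
            )
            emit_csv(surface_to_frame(surf), f"surface_{sex}.csv")

        stage = "correlations"
        emit_json(_correlations(cohort1, cohort2, floor), "correlations.json")

        stage = "summary"
        summary = outdir / "summary.txt"
        summary.write_text(
            "\n".join(
                [
                    f"config: {stamp}",
                    f"input subjects:          {report.n_input}",
                    f"excluded (cardiac):      {report.n_excluded_cardiac}",
                    f"excluded (biomarker):    {report.n_excluded_biomarker}",
                    f"study cohort 2:          {report.n_cohort2}",
                    f"excluded (renal):        {report.n_excluded_renal}",
                    f"study cohort 1:          {report.n_cohort1}",
                ]
            )
            + "\n",
            encoding="utf-8",
        )
        written.append(summary)
        logger.info("pipeline finished in %.1f s", time.time() - t_start)
    except TroprefError as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise TroprefError(f"pipeline stage '{stage}' failed: {err}") from err

    return {
        "config": stamp,
        "outdir": str(outdir),
        "files": [p.name for p in written],
        "report": report.to_dict(),
    }
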