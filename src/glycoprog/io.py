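"""Readers/writers and pipeline configuration.

All tables are tab-delimited UTF-8 text with "." decimal separator and
missing values as empty cells; floats are written with 17 significant
digits so that write-then-read round-trips are exact and reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .glycomics import META_COLUMNS, PEAKS

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"

CLINICAL_COLUMNS = (
    "sample_id", "age", "sex", "stage", "site", "bmi", "crp", "crp_gt10",
    "op_type", "op_to_sample", "time", "event_all", "event_crc",
)


class IOError_(ValueError):
    pass


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT,
                  lineterminator="\n")


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak table (sample_id, plate_id, is_standard, GP1..GP24)."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                     dtype={"sample_id": str, "plate_id": str})
    missing = [c for c in (*META_COLUMNS, *PEAKS) if c not in df.columns]
    if missing:
        raise IOError_(f"peak table missing columns: {missing}")
    for c in PEAKS:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise IOError_(f"malformed numeric cell at row {row}, column {c}")
        df[c] = pd.to_numeric(df[c])
    samples = df.loc[df["is_standard"] == 0, "sample_id"]
    dup = samples[samples.duplicated()]
    if len(dup):
        raise IOError_(f"duplicated non-standard sample_id: {sorted(set(dup))}")
    return df


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical/outcome table; validates outcome invariants."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                     dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"clinical table missing columns: {missing}")
    if not df["stage"].isin([1, 2, 3, 4]).all():
        raise IOError_("stage must be coded 1-4")
    if (df["time"] < 0).any():
        raise IOError_("negative follow-up time")
    viol = df["event_crc"].astype(bool) & ~df["event_all"].astype(bool)
    if viol.any():
        raise IOError_(
            f"event_crc without event_all for sample(s) "
            f"{list(df.loc[viol, 'sample_id'])}"
        )
    if df["bmi"].isna().any():
        logger.info("BMI missing for %d patients (flagged)", df["bmi"].isna().sum())
    return df


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds steering :func:`glycoprog.pipeline.run_pipeline`."""

    peak_table: str = ""
    clinical_table: str = ""
    annotation: str | None = None  # packaged default when None
    output_dir: str = "results/pipeline"
    robustness_threshold: float = 20.0
    transform: str = "rank"
    models: tuple = ("I", "II", "III")
    outcomes: tuple = ("all", "crc")
    strata: tuple = ("whole", "exclude_stage4")
    horizon_years: float = 5.0
    cv_runs: int = 3
    cv_folds: int = 10
    inner_folds: int = 3
    n_boot: int = 50
    selection_alpha: float = 0.05
    seed: int = 1
    # synthetic-data generation (used by the simulate stage)
    n_patients: int = 400

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise IOError_(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        for p in (cfg.peak_table, cfg.clinical_table):
            if p and not Path(p).exists():
                raise IOError_(f"input path does not exist: {p}")
        return cfg
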