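"""Cohort file I/O and validation."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("survstrat")

__all__ = ["read_cohort", "write_cohort", "validate_cohort"]

REQUIRED_COLUMNS = ("patient_id", "time", "event")


def validate_cohort(cohort: pd.DataFrame, config=None) -> list:
    """Validate a cohort table; returns a list of warning strings.

    Hard errors (raised): missing required columns, non-positive times,
    malformed event codes, duplicate patient ids.  Soft issues (returned):
    per-column missingness.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if config is not None:
        needed = list(config.biomarkers) + list(config.confounders)
        missing += [c for c in needed if c not in cohort.columns and c not in missing]
    if missing:
        raise ValueError(f"cohort is missing required column(s): {missing}")

    if cohort["patient_id"].duplicated().any():
        dup = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dup[:10]}")

    times = pd.to_numeric(cohort["time"], errors="coerce")
    bad_time = cohort.loc[times.isna() | (times <= 0), "patient_id"].tolist()
    if bad_time:
        raise ValueError(
            f"non-positive or non-numeric survival times for patients: {bad_time[:10]}"
        )

    events = pd.to_numeric(cohort["event"], errors="coerce")
    if not set(events.dropna().unique()) <= {0, 1} or events.isna().any():
        raise ValueError("event column must contain only 0/1 codes")

    warnings_out = []
    na_counts = cohort.isna().sum()
    for col, count in na_counts[na_counts > 0].items():
        warnings_out.append(f"column '{col}' has {int(count)} missing value(s)")
    return warnings_out


def read_cohort(path, config=None) -> pd.DataFrame:
    """Read a cohort CSV/TSV, validate it and return a typed table.

    The delimiter is taken from the extension (.tsv → tab) or sniffed.
    Validation warnings are logged; structural problems raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tsv", ".tab"):
        cohort = pd.read_csv(path, sep="\t")
    else:
        cohort = pd.read_csv(path, sep=None, engine="python")
    for col in ("time", "event"):
        if col in cohort.columns:
            cohort[col] = pd.to_numeric(cohort[col], errors="coerce")
    warnings_out = validate_cohort(cohort, config)
    for w in warnings_out:
        logger.warning(w)
    cohort.attrs["validation_warnings"] = warnings_out
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (or TSV by extension), full precision."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, sep=sep, index=False, float_format="%.12g")
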