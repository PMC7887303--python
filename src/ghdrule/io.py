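"""Cohort CSV reading and writing.

One row per patient; tri-state predictor flags encoded 0/1/NA; GH peaks
as a semicolon-joined list; a header comment line carries the schema
version (and optionally the generator seed and config hash for
reproducibility).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .cohort import PREDICTORS

__all__ = ["SCHEMA_VERSION", "SchemaError", "read_cohort", "write_cohort"]

SCHEMA_VERSION = "ghdrule-cohort/1"

REQUIRED_COLUMNS = (
    "patient_id",
    "sex",
    "age_years",
    "era",
    "pubertal_stage",
    "height_sds",
    "weight_kg",
    "gh_peaks",
    "mri_available",
    *PREDICTORS,
    "ghd_status",
)


class SchemaError(ValueError):
    """The cohort file violates the expected schema; the message names
    the offending column or value."""


def write_cohort(
    cohort: pd.DataFrame,
    path: Union[str, Path],
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> None:
    df = cohort.copy()
    for pred in PREDICTORS:
        df[pred] = df[pred].map({True: "1", False: "0"}).fillna("NA")
    df["mri_available"] = df["mri_available"].map({True: "1", False: "0"})
    if "eligible" in df.columns:
        df["eligible"] = df["eligible"].map({True: "1", False: "0"})
    header = f"# schema={SCHEMA_VERSION}"
    if seed is not None:
        header += f" seed={seed}"
    if config_hash is not None:
        header += f" config={config_hash}"
    with open(path, "w", newline="") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, na_rep="NA")


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise SchemaError(
                f"{path.name}: missing schema header comment line"
            )
        if SCHEMA_VERSION not in first:
            raise SchemaError(
                f"{path.name}: unsupported schema (expected {SCHEMA_VERSION})"
            )
        body = fh.read()
    df = pd.read_csv(
        _io.StringIO(body), na_values=["NA"], keep_default_na=False, dtype={"sex": str}
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for pred in PREDICTORS:
        bad = set(df[pred].dropna().unique()) - {0, 1, 0.0, 1.0, "0", "1"}
        if bad:
            raise SchemaError(f"{path.name}: column {pred} has invalid values {bad}")
        df[pred] = df[pred].map(
            lambda v: pd.NA if pd.isna(v) else bool(int(v))
        ).astype("boolean")
    df["mri_available"] = df["mri_available"].astype(int).astype(bool)
    if "eligible" in df.columns:
        df["eligible"] = df["eligible"].fillna(0).astype(int).astype(bool)
    bad_status = set(df["ghd_status"].dropna().unique()) - {
        "case",
        "control",
        "unknown",
    }
    if bad_status:
        raise SchemaError(f"{path.name}: invalid ghd_status values {bad_status}")
    return df


def parse_gh_peaks(value: str) -> tuple[float, ...]:
    """Parse the semicolon-joined GH peak column of one row."""
    if pd.isna(value) or value == "":
        return ()
    return tuple(float(x) for x in str(value).split(";"))
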