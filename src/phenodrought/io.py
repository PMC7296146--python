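"""Readers, writers, and validation for the pipeline's tabular formats.

All tables are plain CSV/TSV with a header row (delimiter chosen from the
file extension, UTF-8).  Missing observations are absent rows, never
sentinel values; every downstream mean or correlation operates on
pairwise-complete data.

Three long formats are used:

* plant observations — ``genotype, treatment, carrier, plant, day, trait,
  value``: one row per surviving per-plant measurement;
* carrier means — ``genotype, treatment, carrier, day, trait, value``:
  plant observations averaged within carriers;
* post-harvest — ``genotype, treatment, plant, trait, value``: the
  architecture/yield traits scored once per plant after ripening.
"""

from __future__ import annotations

import os

import pandas as pd

from .design import ExperimentDesign

PLANT_OBS_COLUMNS = ["genotype", "treatment", "carrier", "plant", "day", "trait", "value"]
CARRIER_MEAN_COLUMNS = ["genotype", "treatment", "carrier", "day", "trait", "value"]
POSTHARVEST_COLUMNS = ["genotype", "treatment", "plant", "trait", "value"]

#: the twelve post-harvest architecture and yield traits
POSTHARVEST_TRAITS = (
    "PH", "NTP", "NTT", "TGW",
    "LSm", "NSm", "NGm", "GWm",
    "LSl", "NSl", "NGl", "GWl",
)

#: the four main-spike traits forming the correlated spike complex
MAIN_SPIKE_TRAITS = ("LSm", "NSm", "NGm", "GWm")


class TableValidationError(ValueError):
    """Raised when a table violates the experimental design; carries the
    offending row indices so callers can report rather than silently drop."""

    def __init__(self, message: str, bad_rows: list[int] | None = None):
        super().__init__(message)
        self.bad_rows = bad_rows or []


def _delimiter(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read(path: str | os.PathLike, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=_delimiter(path), dtype={"value": float})
    except ValueError as exc:  # malformed rows carry pandas' line diagnostics
        raise TableValidationError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing required columns {missing}")
    df = df[columns].copy()
    for col in columns:
        if col == "value":
            df[col] = pd.to_numeric(df[col], errors="raise")
        elif col == "day":
            df[col] = df[col].astype(int)
        else:
            df[col] = df[col].astype(str)
    return df


def validate_plant_observations(df: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Validate a plant-observation table against the design.

    Checks treatment labels, day bounds, and key uniqueness.  Offending
    rows are reported in the raised error (0-based positions), never
    dropped silently.
    """
    bad_treat = df.index[~df["treatment"].isin(design.treatments)].tolist()
    if bad_treat:
        raise TableValidationError(
            f"unknown treatment labels in rows {bad_treat[:20]} "
            f"(allowed: {list(design.treatments)})",
            bad_treat,
        )
    bad_day = df.index[(df["day"] < 1) | (df["day"] > design.n_days)].tolist()
    if bad_day:
        raise TableValidationError(
            f"day outside [1, {design.n_days}] in rows {bad_day[:20]}", bad_day
        )
    key = ["genotype", "treatment", "carrier", "plant", "day", "trait"]
    dup = df.index[df.duplicated(key)].tolist()
    if dup:
        raise TableValidationError(f"duplicate observation keys in rows {dup[:20]}", dup)
    return df


def read_plant_observations(path: str | os.PathLike,
                            design: ExperimentDesign) -> pd.DataFrame:
    df = _read(path, PLANT_OBS_COLUMNS)
    return validate_plant_observations(df, design)


def read_carrier_means(path: str | os.PathLike) -> pd.DataFrame:
    return _read(path, CARRIER_MEAN_COLUMNS)


def read_postharvest(path: str | os.PathLike) -> pd.DataFrame:
    df = _read(path, POSTHARVEST_COLUMNS)
    unknown = sorted(set(df["trait"]) - set(POSTHARVEST_TRAITS))
    if unknown:
        raise TableValidationError(f"unknown post-harvest trait symbols: {unknown}")
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any pipeline table as delimited text (delimiter by extension)."""
    df.to_csv(path, sep=_delimiter(path), index=False)
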