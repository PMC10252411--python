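"""CSV readers/writers and packaged reference tables.

Three reference tables ship with the package as plain CSV resources:

* ``table4`` — 76 commercial ciders with IRF/NYCA scale scores, scale ratings
  and the trained panel's sensory dryness scores and ratings;
* ``table7`` — the 38-sample validation set with NYCA, sensory and the three
  PLS-model ratings;
* ``table3_calibration`` / ``table3_validation`` — distribution summaries
  (max, min, median, quartiles, average) of the chemistry of each sample set.

These are authoritative transcriptions: printed values are stored exactly as
published, including internal inconsistencies, and only rating *labels* are
normalized (e.g. "semidry" -> "semi-dry").
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .categories import DrynessCategory
from .records import CHEMISTRY_FIELDS, CiderSample, RatedSample, ValidationRecord


class SchemaError(ValueError):
    """A CSV is missing mandatory columns or violates basic value constraints."""


_FIXTURE_FILES = {
    "table4": "table4.csv",
    "table7": "table7.csv",
    "table3_calibration": "table3.csv",
    "table3_validation": "table3.csv",
}

_RATING_COLUMNS = (
    "irf_rating_no_ph",
    "irf_rating_ph",
    "nyca_rating",
    "sensory_rating",
    "model1_rating",
    "model2_rating",
    "model3_rating",
)

#: summary statistics, in the order that must be monotone (average excluded)
SUMMARY_ORDER = ("min", "q1", "median", "q3", "max")


def _fixture_path(filename: str):
    return resources.files("ciderdry.fixtures").joinpath(filename)


def fixture_text(name: str) -> str:
    """Raw text of a packaged fixture file (used for integrity checks)."""
    if name not in _FIXTURE_FILES:
        raise ValueError(f"unknown fixture name: {name!r}")
    return _fixture_path(_FIXTURE_FILES[name]).read_text(encoding="utf-8")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables as a DataFrame.

    ``name`` must be one of ``table4``, ``table7``, ``table3_calibration``,
    ``table3_validation``. Rating labels are normalized to the canonical
    spellings; everything else is returned as printed.
    """
    if name not in _FIXTURE_FILES:
        raise ValueError(
            f"unknown fixture name: {name!r}; expected one of {sorted(_FIXTURE_FILES)}"
        )
    with _fixture_path(_FIXTURE_FILES[name]).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    if name.startswith("table3"):
        which = name.split("_", 1)[1]
        df = df[df["set"] == which].drop(columns="set").set_index("statistic")
        check_distribution_summary(df)
        return df
    for col in _RATING_COLUMNS:
        if col in df.columns:
            df[col] = [DrynessCategory.from_label(v).label for v in df[col]]
    return df


def table4_records() -> list[RatedSample]:
    df = load_fixture("table4")
    return [RatedSample(**row) for row in df.to_dict("records")]


def table7_records() -> list[ValidationRecord]:
    df = load_fixture("table7")
    return [ValidationRecord(**row) for row in df.to_dict("records")]


def check_distribution_summary(summary: pd.DataFrame) -> None:
    """Assert min <= Q1 <= median <= Q3 <= max per variable, average in range."""
    for col in summary.columns:
        values = [summary.loc[s, col] for s in SUMMARY_ORDER]
        if not all(a <= b for a, b in zip(values, values[1:])):
            raise ValueError(f"summary for {col!r} is not monotone: {values}")
        if "average" in summary.index:
            avg = summary.loc["average", col]
            if not summary.loc["min", col] <= avg <= summary.loc["max", col]:
                raise ValueError(f"average of {col!r} outside [min, max]")


def summarize_chemistry(chemistry: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary of a chemistry table in the packaged-table layout."""
    numeric = chemistry[[c for c in CHEMISTRY_FIELDS if c in chemistry.columns]]
    summary = pd.DataFrame(
        {
            "max": numeric.max(),
            "min": numeric.min(),
            "median": numeric.median(),
            "q1": numeric.quantile(0.25),
            "q3": numeric.quantile(0.75),
            "average": numeric.mean(),
        }
    ).T
    summary.index.name = "statistic"
    return summary


def read_chemistry_csv(
    path: Union[str, Path],
    dialect: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read a per-sample chemistry table.

    ``dialect`` maps file column names to canonical field names, e.g.
    ``{"Abs. 280 nm": "abs280"}``. Columns are renamed, never rescaled —
    values are assumed to already be in the canonical units (residual sugar
    mg/100 mL, acids g/L). ``tannins`` and ``facility_code`` are optional.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in ("sample_id", *CHEMISTRY_FIELDS) if c not in df.columns]
    if missing:
        raise SchemaError(f"chemistry CSV is missing mandatory columns: {missing}")
    validate_chemistry(df)
    return df


def validate_chemistry(df: pd.DataFrame) -> None:
    """Value-level checks shared by the reader and the synthetic generator."""
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise SchemaError(f"duplicate sample ids: {dupes}")
    check_cols = list(CHEMISTRY_FIELDS) + (["tannins"] if "tannins" in df.columns else [])
    for col in check_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            bad = df.loc[values.isna(), "sample_id"].iloc[0]
            raise SchemaError(f"sample {bad!r}: field {col!r} is not numeric")
        if col == "ph":
            out = (values <= 0) | (values >= 14)
            if out.any():
                bad = df.loc[out, "sample_id"].iloc[0]
                raise SchemaError(f"sample {bad!r}: ph outside (0, 14)")
        elif (values < 0).any():
            bad = df.loc[values < 0, "sample_id"].iloc[0]
            raise SchemaError(f"sample {bad!r}: field {col!r} is negative")


def write_chemistry_csv(chemistry: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a chemistry table; floats keep 12 significant digits for round-trips."""
    chemistry.to_csv(path, index=False, float_format="%.12g")


def chemistry_records(df: pd.DataFrame) -> list[CiderSample]:
    """Typed view of a chemistry DataFrame."""
    out = []
    for row in df.to_dict("records"):
        kwargs = {k: row[k] for k in ("sample_id", *CHEMISTRY_FIELDS)}
        for opt in ("tannins", "facility_code"):
            if opt in row and not pd.isna(row[opt]):
                kwargs[opt] = row[opt]
        out.append(CiderSample(**kwargs))
    return out
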