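"""Strain-phenotype tables: loading, validation, transformation, subsetting.

The core container is a pandas DataFrame in one of two layouts:

* **phenotype table** — one row per strain with the raw measurements
  (acute-IR D10 in kGy, binary chronic-irradiation growth, binary low-pH
  growth, maximum growth temperature in degrees C, and the highest tolerated
  concentrations in uM of HgCl2, merbromin, CrCl3 and K2Cr2O7);
* **transformed table** — analysis-ready predictors: the heavy-metal
  tolerances and D10 are log10-transformed, a binary Ascomycota indicator
  and a genus column are derived, and the binary outcome is carried through.

A packaged 95-strain dataset of wild yeast and dimorphic fungal isolates
(two phyla, 34 Saccharomyces cerevisiae strains) ships with the package and
is the reference input for the whole analysis pipeline.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RAW_COLUMNS",
    "PREDICTORS",
    "SchemaError",
    "ValidationError",
    "load_table",
    "load_builtin",
    "write_table",
    "transform",
    "subset",
]

#: Required columns of the on-disk CSV schema, in canonical order.
RAW_COLUMNS = [
    "strain_id",
    "species_name",
    "phylum",
    "D10_kGy",
    "CIRgrowth",
    "lowpHgrowth",
    "Tmax_C",
    "HgCl2_uM",
    "MER_uM",
    "CrCl3_uM",
    "K2Cr2O7_uM",
]

_NUMERIC = RAW_COLUMNS[3:]
_BINARY = ["CIRgrowth", "lowpHgrowth"]
_LOG_SOURCES = {
    "logD10": "D10_kGy",
    "logHgCl2": "HgCl2_uM",
    "logMER": "MER_uM",
    "logCrCl3": "CrCl3_uM",
    "logK2Cr2O7": "K2Cr2O7_uM",
}

#: The eight analysis predictors of the chronic-irradiation growth outcome.
PREDICTORS = [
    "logD10",
    "lowpHgrowth",
    "Tmax",
    "logHgCl2",
    "logMER",
    "logCrCl3",
    "logK2Cr2O7",
    "Ascomycota",
]

#: Predictors available within a single phylum (the indicator is constant there).
WITHIN_PHYLUM_PREDICTORS = PREDICTORS[:-1]


class SchemaError(ValueError):
    """The file does not match the expected CSV schema."""


class ValidationError(ValueError):
    """A row violates a strain-record invariant."""


def _validate(df: pd.DataFrame) -> None:
    if df.empty:
        raise SchemaError("table contains no strain records")
    dup = df["strain_id"][df["strain_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate strain_id: {sorted(dup.unique())}")
    bad_phylum = ~df["phylum"].isin(["A", "B"])
    if bad_phylum.any():
        ids = df.loc[bad_phylum, "strain_id"].tolist()
        raise ValidationError(f"phylum must be 'A' or 'B'; offending strains: {ids}")
    for col in _NUMERIC:
        vals = df[col]
        if vals.isna().any():
            ids = df.loc[vals.isna(), "strain_id"].tolist()
            raise ValidationError(f"missing value in {col} for strains {ids}")
    for col in _BINARY:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            ids = df.loc[bad, "strain_id"].tolist()
            raise ValidationError(f"{col} must be 0 or 1; offending strains: {ids}")
    for col in ["D10_kGy", "HgCl2_uM", "MER_uM", "CrCl3_uM", "K2Cr2O7_uM"]:
        bad = df[col] <= 0
        if bad.any():
            ids = df.loc[bad, "strain_id"].tolist()
            raise ValidationError(f"{col} must be positive; offending strains: {ids}")
    bad_t = (df["Tmax_C"] <= 0) | (df["Tmax_C"] > 60)
    if bad_t.any():
        ids = df.loc[bad_t, "strain_id"].tolist()
        raise ValidationError(f"Tmax_C must lie in (0, 60]; offending strains: {ids}")


def load_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a strain-phenotype CSV.

    Header names are matched case-insensitively against :data:`RAW_COLUMNS`.
    Raises :class:`SchemaError` for missing columns or an empty file and
    :class:`ValidationError` for rows breaking a record invariant; messages
    name the offending strain ids.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    lower_map = {c.lower(): c for c in df.columns}
    missing = [c for c in RAW_COLUMNS if c.lower() not in lower_map]
    if missing:
        raise SchemaError(f"{path} is missing required columns {missing}")
    df = df.rename(columns={lower_map[c.lower()]: c for c in RAW_COLUMNS})
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            ids = df.loc[bad, "strain_id"].tolist()
            raise ValidationError(f"non-numeric value in {col} for strains {ids}")
        df[col] = coerced
    _validate(df)
    keep = RAW_COLUMNS + [c for c in df.columns if c not in RAW_COLUMNS]
    return df[keep].reset_index(drop=True)


def load_builtin(name: str = "strains95") -> pd.DataFrame:
    """Load a packaged dataset by name (currently only ``strains95``)."""
    resource = importlib.resources.files("stresscorr.datasets") / f"{name}.csv"
    if not resource.is_file():
        raise FileNotFoundError(f"no builtin dataset named {name!r}")
    with importlib.resources.as_file(resource) as p:
        return load_table(p)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype table as CSV (round-trips losslessly via load_table)."""
    df.to_csv(path, index=False)


def transform(table: pd.DataFrame) -> pd.DataFrame:
    """Build the analysis-ready predictor table.

    Log10-transforms D10 and the four metal tolerances, renames Tmax_C to
    Tmax, derives the binary ``Ascomycota`` indicator from the phylum code
    and ``genus`` as the first whitespace-delimited token of the species name
    (so the hybrid "Saccharomyces bayanus x cerivisiae" is grouped with
    Saccharomyces). The binary outcome ``CIRgrowth`` is carried through.
    """
    for new, src in _LOG_SOURCES.items():
        if (table[src] <= 0).any():
            ids = table.loc[table[src] <= 0, "strain_id"].tolist()
            raise ValidationError(
                f"cannot log10-transform non-positive {src} for strains {ids}"
            )
    out = pd.DataFrame(index=table.index)
    out["strain_id"] = table["strain_id"]
    out["species_name"] = table["species_name"]
    out["genus"] = table["species_name"].str.split().str[0]
    out["phylum"] = table["phylum"]
    out["Ascomycota"] = (table["phylum"] == "A").astype(int)
    for new, src in _LOG_SOURCES.items():
        out[new] = np.log10(table[src].astype(float))
    out["Tmax"] = table["Tmax_C"].astype(float)
    out["lowpHgrowth"] = table["lowpHgrowth"].astype(int)
    out["CIRgrowth"] = table["CIRgrowth"].astype(int)
    return out.reset_index(drop=True)


def subset(
    table: pd.DataFrame,
    phylum: str | None = None,
    species_include: list[str] | None = None,
    species_exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Filter a (transformed) table by phylum and/or species, order preserved.

    ``phylum`` accepts the code ('A'/'B') or the full name. An empty result
    triggers a warning rather than an error.
    """
    mask = pd.Series(True, index=table.index)
    if phylum is not None:
        code = {"ascomycota": "A", "basidiomycota": "B"}.get(phylum.lower(), phylum)
        if code not in ("A", "B"):
            raise ValueError(f"unknown phylum {phylum!r}")
        mask &= table["phylum"] == code
    known = set(table["species_name"])
    for lst, sense in ((species_include, True), (species_exclude, False)):
        if lst is not None:
            unknown = [s for s in lst if s not in known]
            if unknown:
                raise ValueError(f"species not present in table: {unknown}")
            hit = table["species_name"].isin(lst)
            mask &= hit if sense else ~hit
    out = table[mask].reset_index(drop=True)
    if out.empty:
        warnings.warn("subset produced an empty table", stacklevel=2)
    return out
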