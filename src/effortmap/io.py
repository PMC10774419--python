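"""CSV readers/writers, output layout, schema validation, conversions.

The mapped-effort deposit layout is two folders:

* ``effort_mapped/`` — one file per (year, sector); the Year column is
  omitted inside per-year files to reduce size (it is in the filename);
* ``effort_mapped_country/`` — one file per country, with all fields.

Files are UTF-8, comma-separated CSV with a header row and '.' decimal;
floats are written in shortest round-trippable form, so a write→read
round trip is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import EFFORT_FIELDS, LENGTH_CLASSES, SECTORS


def write_effort_outputs(
    records: pd.DataFrame,
    out_dir: str | Path,
    registry: list | None = None,
) -> dict:
    """Write a mapped-effort table in the two-folder deposit layout.

    Parameters
    ----------
    records:
        The 13-field mapped-effort table (one row per record).
    out_dir:
        Destination directory; ``effort_mapped/`` and
        ``effort_mapped_country/`` are created inside it.
    registry:
        Optional list of SAUP country codes.  When given, one per-country
        file is written for *every* registry entry (header-only when the
        country has no records); otherwise one per country present.

    Returns a manifest with file counts and paths.
    """
    missing = [c for c in EFFORT_FIELDS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing fields: {missing}")
    records = records[list(EFFORT_FIELDS)]
    key_cols = ["Year", "SAUP", "Length_Category", "Gear", "Lat", "Lon", "FGroup", "Sector"]
    if records.duplicated(subset=key_cols).any():
        raise ValueError("duplicate record keys in effort table")

    out_dir = Path(out_dir)
    mapped_dir = out_dir / "effort_mapped"
    country_dir = out_dir / "effort_mapped_country"
    mapped_dir.mkdir(parents=True, exist_ok=True)
    country_dir.mkdir(parents=True, exist_ok=True)

    mapped_files = []
    no_year = [c for c in EFFORT_FIELDS if c != "Year"]
    for (year, sector), chunk in records.groupby(["Year", "Sector"], sort=True):
        path = mapped_dir / f"mapped_effort_{int(year)}_{sector}.csv"
        chunk[no_year].to_csv(path, index=False)
        mapped_files.append(str(path))

    country_files = []
    codes = registry if registry is not None else sorted(records["SAUP"].unique())
    by_country = dict(list(records.groupby("SAUP")))
    for code in codes:
        path = country_dir / f"mapped_effort_country_{code}.csv"
        chunk = by_country.get(code, records.iloc[0:0])
        chunk.to_csv(path, index=False)
        country_files.append(str(path))

    return {
        "n_effort_mapped": len(mapped_files),
        "n_effort_mapped_country": len(country_files),
        "effort_mapped": mapped_files,
        "effort_mapped_country": country_files,
    }


def read_effort_file(path: str | Path, year: int | None = None) -> pd.DataFrame:
    """Read a mapped-effort CSV; supply ``year`` for per-year files."""
    df = pd.read_csv(path)
    if year is not None and "Year" not in df.columns:
        df.insert(0, "Year", year)
    return df


def _on_centre_lattice(values: np.ndarray) -> np.ndarray:
    """True where coordinates are odd multiples of 0.25 (cell centres)."""
    q = np.asarray(values, float) * 4.0
    return (np.abs(q - np.round(q)) < 1e-6) & (np.abs(np.round(q)) % 2 == 1)


def validate_schema(path: str | Path, has_year: bool = True) -> dict:
    """Validate a mapped-effort file against the 13-field schema.

    Checks field names and order, sector codes, the five length-class
    labels, value signs, and that lat/lon are 0.5° cell centres.  Returns
    ``{"passed": bool, "n_fields": int, "failures": [...]}``.
    """
    df = pd.read_csv(path)
    failures: list[str] = []
    expected = list(EFFORT_FIELDS) if has_year else [c for c in EFFORT_FIELDS if c != "Year"]
    if list(df.columns) != expected:
        failures.append(f"fields are {list(df.columns)}, expected {expected}")
    if len(df):
        bad_sector = set(df["Sector"].unique()) - set(SECTORS)
        if bad_sector:
            failures.append(f"Sector: invalid codes {sorted(bad_sector)}")
        bad_len = set(df["Length_Category"].unique()) - set(LENGTH_CLASSES)
        if bad_len:
            failures.append(f"Length_Category: invalid labels {sorted(bad_len)}")
        for col in ("NV", "P", "GT", "NomActive", "EffActive"):
            if col in df.columns and (pd.to_numeric(df[col], errors="coerce") < 0).any():
                failures.append(f"{col}: negative values")
        for col in ("Lat", "Lon"):
            if col in df.columns and not _on_centre_lattice(df[col].to_numpy()).all():
                failures.append(f"{col}: values off the 0.25-offset cell-centre lattice")
    return {"passed": not failures, "n_fields": len(df.columns), "failures": failures}


@dataclass
class ConversionTable:
    """Hours of fishing per day at sea, by gear and length class."""

    table: pd.DataFrame  # gear, length_class, hours_per_das
    default: float | None = None

    def __post_init__(self) -> None:
        f = self.table["hours_per_das"]
        if ((f <= 0) | (f > 24)).any():
            raise ValueError("hours-per-day-at-sea factors must be in (0, 24]")
        if self.default is not None and not (0 < self.default <= 24):
            raise ValueError("default factor must be in (0, 24]")

    def factor(self, gear: str, length_class: str) -> tuple[float, str]:
        sel = self.table[(self.table["gear"] == gear) & (self.table["length_class"] == length_class)]
        if len(sel):
            return float(sel["hours_per_das"].iloc[0]), "table"
        if self.default is not None:
            return self.default, "default"
        raise KeyError(f"no conversion factor for ({gear!r}, {length_class!r}) and no default")


def convert_das_to_hours(records: pd.DataFrame, conversion: ConversionTable) -> pd.DataFrame:
    """Convert record effort from kW·days to kW·hours.

    Adds ``NomActive_hours`` (and ``EffActive_hours``) columns plus a
    ``conversion_provenance`` column.  Raises listing every uncovered
    (gear, length class) pair when no default factor is configured.
    """
    pairs = records[["Gear", "Length_Category"]].drop_duplicates()
    factors, gaps = {}, []
    for gear, lc in pairs.itertuples(index=False):
        try:
            factors[(gear, lc)] = conversion.factor(gear, lc)
        except KeyError:
            gaps.append((gear, lc))
    if gaps:
        raise KeyError(f"missing conversion factors for: {sorted(gaps)}")
    out = records.copy()
    fac = np.array([factors[(g, l)][0] for g, l in zip(out["Gear"], out["Length_Category"])])
    prov = [factors[(g, l)][1] for g, l in zip(out["Gear"], out["Length_Category"])]
    out["NomActive_hours"] = out["NomActive"] * fac
    if "EffActive" in out.columns:
        out["EffActive_hours"] = out["EffActive"] * fac
    out["conversion_provenance"] = prov
    return out


def load_country_codes(path: str | Path) -> pd.DataFrame:
    """Load a SAUP-code ↔ country-name map and check it is bijective."""
    df = pd.read_csv(path)
    for col in ("saup", "country"):
        if col not in df.columns:
            raise ValueError(f"country-code map must have a {col!r} column")
        if df[col].duplicated().any():
            raise ValueError(f"country-code map is not bijective: duplicate {col!r}")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
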