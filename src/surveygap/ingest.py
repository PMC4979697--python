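"""Reading, filtering and inventory-building for occurrence records.

An occurrence record is one database row representing an individual organism
at a known location (decimal latitude/longitude) and time (calendar year).
Records are screened (coordinate issues, year window, species rank, record
type), assigned to grid cells, and aggregated into per-(cell, period)
survey inventories that carry the incidence frequencies (n, S_obs, Q1, Q2)
used by the completeness estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, TimePeriodScheme, assign_cells  # noqa: F401 (re-export)

#: canonical column order of an occurrence table
OCCURRENCE_COLUMNS = [
    "species",
    "taxon_group",
    "latitude",
    "longitude",
    "year",
    "basis_of_record",
    "coordinate_issue",
]

#: default mapping from Darwin-Core-style headers to canonical names
DARWIN_CORE_MAP = {
    "species": "species",
    "scientificName": "species",
    "taxon_group": "taxon_group",
    "taxonGroup": "taxon_group",
    "decimalLatitude": "latitude",
    "latitude": "latitude",
    "decimalLongitude": "longitude",
    "longitude": "longitude",
    "year": "year",
    "basisOfRecord": "basis_of_record",
    "basis_of_record": "basis_of_record",
    "issue": "coordinate_issue",
    "coordinate_issue": "coordinate_issue",
    "hasGeospatialIssues": "coordinate_issue",
}

_MANDATORY = ["species", "latitude", "longitude", "year"]


def read_occurrences(
    path, column_map: dict[str, str] | None = None, sep: str | None = None
) -> pd.DataFrame:
    """Read delimited occurrence records into the canonical table.

    The delimiter is sniffed unless ``sep`` is given.  Rows with unparseable
    or out-of-bounds coordinates/years are *retained* but flagged in the
    boolean ``parse_issue`` column; only :func:`filter_records` removes them,
    so the filter report accounts for every row.

    Raises
    ------
    ValueError
        If a mandatory column (species, latitude, longitude, year) is
        missing after applying the column mapping.
    """
    cmap = dict(DARWIN_CORE_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    raw = raw.rename(columns={c: cmap[c] for c in raw.columns if c in cmap})
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    out = pd.DataFrame(index=raw.index)
    out["species"] = raw["species"].str.strip()
    out["taxon_group"] = raw.get("taxon_group", pd.Series("", index=raw.index)).str.strip()
    lat = pd.to_numeric(raw["latitude"], errors="coerce")
    lon = pd.to_numeric(raw["longitude"], errors="coerce")
    year = pd.to_numeric(raw["year"], errors="coerce")
    out["latitude"] = lat
    out["longitude"] = lon
    out["year"] = year
    out["basis_of_record"] = raw.get(
        "basis_of_record", pd.Series("", index=raw.index)
    ).str.strip()
    issue = raw.get("coordinate_issue", pd.Series("", index=raw.index)).str.strip()
    out["coordinate_issue"] = issue.str.lower().isin(
        {"true", "t", "1", "yes", "y"}
    )
    bad_coord = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    bad_year = year.isna() | (year != year.round())
    out["parse_issue"] = (bad_coord | bad_year).to_numpy()
    # integer years where parseable; NaN-safe nullable dtype
    out["year"] = year.round().astype("Int64")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class FilterCriteria:
    """Screening rules applied to an occurrence table, in fixed order.

    Order: coordinate issue -> year window -> species rank -> record type.
    Year bounds are inclusive on both ends.  The record-type comparison is
    case-insensitive against ``allowed_record_types``; ``None`` disables the
    rule (systematic datasets such as breeding-bird or fish surveys lack a
    basis-of-record field).
    """

    require_no_coordinate_issue: bool = True
    year_range: tuple[int, int] = (1800, 2013)
    require_species_rank: bool = True
    allowed_record_types: frozenset[str] | None = frozenset({"specimen"})

    def __post_init__(self) -> None:
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range min must be <= max")

    @classmethod
    def gbif(cls) -> "FilterCriteria":
        return cls()

    @classmethod
    def systematic(cls) -> "FilterCriteria":
        """Preset for standardized surveys: no coordinate-issue or
        record-type fields to filter on."""
        return cls(require_no_coordinate_issue=False, allowed_record_types=None)


def filter_records(
    records: pd.DataFrame, criteria: FilterCriteria = FilterCriteria()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply screening rules; return (retained table, removal report).

    The report counts removals per rule in the fixed application order, so a
    record violating several rules is charged to the first.  Retained plus
    removed always equals the input row count.
    """
    df = records
    report: dict[str, int] = {}
    n0 = len(df)

    if criteria.require_no_coordinate_issue:
        bad = df["coordinate_issue"].to_numpy(dtype=bool)
        if "parse_issue" in df.columns:
            bad = bad | df["parse_issue"].to_numpy(dtype=bool)
        report["coordinate_issue"] = int(bad.sum())
        df = df.loc[~bad]

    y0, y1 = criteria.year_range
    year = pd.to_numeric(df["year"], errors="coerce")
    bad = ~((year >= y0) & (year <= y1))
    report["year"] = int(bad.sum())
    df = df.loc[~bad.to_numpy(dtype=bool)]

    if criteria.require_species_rank:
        sp = df["species"].astype(str).str.strip()
        bad = (sp == "") | sp.str.lower().isin({"nan", "none"})
        report["rank"] = int(bad.sum())
        df = df.loc[~bad.to_numpy(dtype=bool)]

    if criteria.allowed_record_types is not None:
        allowed = {t.lower() for t in criteria.allowed_record_types}
        bad = ~df["basis_of_record"].astype(str).str.strip().str.lower().isin(allowed)
        report["record_type"] = int(bad.sum())
        df = df.loc[~bad.to_numpy(dtype=bool)]

    report["retained"] = len(df)
    assert len(df) + sum(v for k, v in report.items() if k != "retained") == n0
    return df.reset_index(drop=True), report


@dataclass
class SurveyInventory:
    """One survey: per-species record counts in one cell and time period.

    Derived incidence frequencies (each record = one sampling unit):
    ``n`` total records, ``S_obs`` species observed, ``Q1``/``Q2`` species
    with exactly one / exactly two records.
    """

    cell_id: int
    period: str
    dataset: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def q1(self) -> int:
        return sum(1 for v in self.counts.values() if v == 1)

    @property
    def q2(self) -> int:
        return sum(1 for v in self.counts.values() if v == 2)

    def count_vector(self) -> np.ndarray:
        return np.asarray(sorted(self.counts.values()), dtype=np.int64)


def build_inventories(
    records: pd.DataFrame,
    scheme: TimePeriodScheme,
    dataset: str = "dataset",
) -> pd.DataFrame:
    """Aggregate cell-assigned records into survey inventories.

    A record contributes to *every* period of ``scheme`` whose year interval
    contains it (the complete and contemporary periods overlap by design).
    Returns a long table with one row per (dataset, period, cell, species):
    columns dataset, period, cell_id, species, record_count.
    """
    if "cell_id" not in records.columns:
        raise ValueError("records must carry cell ids; run assign_cells first")
    pieces = []
    year = pd.to_numeric(records["year"], errors="coerce")
    for name, y0, y1 in scheme.periods:
        sel = records.loc[((year >= y0) & (year <= y1)).to_numpy(dtype=bool)]
        if sel.empty:
            continue
        g = (
            sel.groupby(["cell_id", "species"], sort=True)
            .size()
            .rename("record_count")
            .reset_index()
        )
        g.insert(0, "period", name)
        pieces.append(g)
    if not pieces:
        return pd.DataFrame(
            columns=["dataset", "period", "cell_id", "species", "record_count"]
        )
    long = pd.concat(pieces, ignore_index=True)
    long.insert(0, "dataset", dataset)
    return long


def inventory_stats(inventories: pd.DataFrame) -> pd.DataFrame:
    """Per-survey incidence frequencies from a long inventory table.

    Returns one row per (dataset, period, cell_id) with n, S_obs, Q1, Q2.
    """
    if inventories.empty:
        return pd.DataFrame(
            columns=["dataset", "period", "cell_id", "n", "s_obs", "q1", "q2"]
        )
    g = inventories.groupby(["dataset", "period", "cell_id"], sort=True)["record_count"]
    out = g.agg(
        n="sum",
        s_obs="size",
        q1=lambda c: int((c == 1).sum()),
        q2=lambda c: int((c == 2).sum()),
    ).reset_index()
    out[["n", "s_obs", "q1", "q2"]] = out[["n", "s_obs", "q1", "q2"]].astype(np.int64)
    return out


def write_inventories(inventories: pd.DataFrame, grid: GridSpec, path) -> None:
    """Write the long inventory table as delimited text with cell corners."""
    out = inventories.copy()
    if not out.empty:
        x0, y0, _, _ = grid.cell_bounds(out["cell_id"].to_numpy())
        out["cell_lon_min"] = x0
        out["cell_lat_min"] = y0
    else:
        out["cell_lon_min"] = []
        out["cell_lat_min"] = []
    cols = [
        "dataset",
        "period",
        "cell_id",
        "cell_lon_min",
        "cell_lat_min",
        "species",
        "record_count",
    ]
    out[cols].to_csv(path, sep="\t", index=False)
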