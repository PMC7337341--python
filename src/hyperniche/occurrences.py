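"""Occurrence record ingestion, cleaning, and cumulative temporal slicing.

Invasion timelines are analysed on *cumulative* record subsets: the first
subset holds everything up to the first breakpoint year (a long initial
window so the first niche model has a solid record base), and each later
subset adds one decade of records, so successive subsets are nested and the
last one equals the full cleaned dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rasters import WGS84, ClimateStack

__all__ = [
    "OccurrenceSet",
    "TemporalSlicing",
    "read_occurrences",
    "clean_records",
    "cumulative_subsets",
]

#: decimal places used when comparing coordinates for duplicate detection
COORD_DECIMALS = 4

REQUIRED_COLUMNS = ("lon", "lat", "year")


@dataclass
class OccurrenceSet:
    """Georeferenced, year-stamped presence records (WGS84 lon/lat).

    Backed by a DataFrame with columns ``id, lon, lat, year`` (+ optional
    ``source``).  The rejection log accumulated across read/clean steps is
    kept alongside so that accepted + rejected always accounts for every
    input row.
    """

    df: pd.DataFrame
    crs: str = WGS84
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")
        if "id" not in self.df.columns:
            self.df = self.df.copy()
            self.df.insert(0, "id", [str(i) for i in range(len(self.df))])
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lon(self) -> np.ndarray:
        return self.df["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.df["lat"].to_numpy(dtype=float)

    @property
    def year(self) -> np.ndarray:
        return self.df["year"].to_numpy(dtype=int)

    def subset(self, mask: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.df.loc[np.asarray(mask, bool)].copy(), self.crs)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def write_rejection_log(self, path: str | Path) -> None:
        self.rejected.to_csv(path, index=False)


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    year_range: tuple[int, int] | None = None,
    delimiter: str = ",",
) -> OccurrenceSet:
    """Read delimited-text occurrences, validating each row.

    ``column_map`` maps the logical names ``lon``/``lat``/``year`` (and
    optionally ``id``/``source``) to the file's column headers.  Rows with
    unparseable or out-of-bounds coordinates, or years outside *year_range*,
    are rejected with a reason rather than aborting the read; a missing
    mapped column is a configuration error and fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    for logical in REQUIRED_COLUMNS:
        src = column_map.get(logical, logical)
        if src not in raw.columns:
            raise KeyError(
                f"column {src!r} (mapped to {logical!r}) not found in {path.name}; "
                f"available: {list(raw.columns)}"
            )
    rename = {column_map.get(k, k): k for k in ("id", "lon", "lat", "year", "source")}
    table = raw.rename(columns={src: k for src, k in rename.items() if src in raw.columns})

    records, rejects = [], []
    for i, row in table.iterrows():
        rid = str(row["id"]) if "id" in table.columns and row.get("id", "") != "" else str(i)
        try:
            lon = float(row["lon"])
            lat = float(row["lat"])
        except (TypeError, ValueError):
            rejects.append({"id": rid, "reason": "unparseable coordinate"})
            continue
        try:
            year = int(float(row["year"]))
        except (TypeError, ValueError):
            rejects.append({"id": rid, "reason": "unparseable year"})
            continue
        if not (np.isfinite(lon) and np.isfinite(lat)):
            rejects.append({"id": rid, "reason": "non-finite coordinate"})
            continue
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            rejects.append({"id": rid, "reason": "coordinate out of bounds"})
            continue
        if year_range is not None and not (year_range[0] <= year <= year_range[1]):
            rejects.append({"id": rid, "reason": "year outside study window"})
            continue
        rec = {"id": rid, "lon": lon, "lat": lat, "year": year}
        if "source" in table.columns:
            rec["source"] = row["source"]
        records.append(rec)

    df = pd.DataFrame(records, columns=["id", "lon", "lat", "year"] + (
        ["source"] if any("source" in r for r in records) else []))
    result = OccurrenceSet(df, rejected=pd.DataFrame(rejects, columns=["id", "reason"]))
    assert len(result) + len(result.rejected) == len(raw)
    return result


def _load_land_polygons(path: str | Path):
    """GeoJSON (Multi)Polygon features → shapely prepared geometry."""
    from shapely.geometry import shape
    from shapely.ops import unary_union
    from shapely.prepared import prep

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    return prep(unary_union(geoms))


def clean_records(
    occurrences: OccurrenceSet,
    land: ClimateStack | str | Path | None = None,
    exclusion: str | Path | None = None,
) -> OccurrenceSet:
    """Deduplicate and geographically filter records.

    Rules, applied in order and logged per record:

    1. exact duplicates on (lon, lat, year) after rounding coordinates to
       4 decimals collapse to the first record;
    2. suspect (0, 0) coordinates are removed;
    3. when a land mask is supplied (a :class:`ClimateStack`, whose valid
       cells define land, or a GeoJSON polygon file), off-land records are
       removed;
    4. when an exclusion polygon file is supplied, records inside it are
       removed.

    Idempotent: cleaning a cleaned set changes nothing.
    """
    df = occurrences.df.copy()
    rejects: list[dict] = []

    r_lon = df["lon"].round(COORD_DECIMALS)
    r_lat = df["lat"].round(COORD_DECIMALS)
    dup = pd.DataFrame({"lon": r_lon, "lat": r_lat, "year": df["year"]}).duplicated()
    for rid in df.loc[dup, "id"]:
        rejects.append({"id": rid, "reason": "duplicate (lon,lat,year)"})
    df = df.loc[~dup]

    zero = (df["lon"].round(COORD_DECIMALS) == 0.0) & (df["lat"].round(COORD_DECIMALS) == 0.0)
    for rid in df.loc[zero, "id"]:
        rejects.append({"id": rid, "reason": "suspect (0,0) coordinate"})
    df = df.loc[~zero]

    if land is not None and len(df):
        lon = df["lon"].to_numpy(float)
        lat = df["lat"].to_numpy(float)
        if isinstance(land, ClimateStack):
            row, col = land.grid.index_of(lon, lat)
            on_land = np.array(
                [r >= 0 and land.valid_mask[r, c] for r, c in zip(row, col)]
            )
        else:
            from shapely.geometry import Point

            prepared = _load_land_polygons(land)
            on_land = np.array(
                [prepared.covers(Point(x, y)) for x, y in zip(lon, lat)]
            )
        for rid in df.loc[~on_land, "id"]:
            rejects.append({"id": rid, "reason": "off land mask"})
        df = df.loc[on_land]

    if exclusion is not None and len(df):
        from shapely.geometry import Point

        prepared = _load_land_polygons(exclusion)
        inside = np.array(
            [prepared.covers(Point(x, y)) for x, y in zip(df["lon"], df["lat"])]
        )
        for rid in df.loc[inside, "id"]:
            rejects.append({"id": rid, "reason": "inside exclusion polygon"})
        df = df.loc[~inside]

    log = pd.concat(
        [occurrences.rejected, pd.DataFrame(rejects, columns=["id", "reason"])],
        ignore_index=True,
    )
    return OccurrenceSet(df, occurrences.crs, rejected=log)


@dataclass(frozen=True)
class TemporalSlicing:
    """Cumulative period definition: ascending end-years with labels.

    Period *i* covers every record with ``year <= breakpoints[i]`` (and
    ``year >= start_year``), so subsets are nested by construction.
    """

    breakpoints: tuple[int, ...]
    labels: tuple[str, ...]
    start_year: int

    def __post_init__(self) -> None:
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly ascending")
        if len(self.breakpoints) != len(self.labels):
            raise ValueError("one label per breakpoint required")
        if self.breakpoints and self.breakpoints[0] < self.start_year:
            raise ValueError("first breakpoint precedes the start year")

    @classmethod
    def decades(
        cls,
        start_year: int = 1891,
        first_break: int = 1950,
        last_year: int = 2017,
    ) -> "TemporalSlicing":
        """Default study slicing: one long initial window then decade steps.

        The first subset spans *start_year*–*first_break* (a 60-year base so
        the first niche model is fitted on enough records); later breakpoints
        fall at decade ends (1959, 1969, …) with the final one at *last_year*.
        """
        breaks = [first_break]
        labels = [f"pre {first_break}"]
        decade = first_break - first_break % 10  # e.g. 1950
        while decade + 9 < last_year:
            breaks.append(decade + 9)
            labels.append(f"{decade}s")
            decade += 10
        breaks.append(last_year)
        labels.append(f"{decade}s")
        return cls(tuple(breaks), tuple(labels), start_year)


def cumulative_subsets(
    occurrences: OccurrenceSet, slicing: TemporalSlicing
) -> list[tuple[str, OccurrenceSet]]:
    """Nested record subsets: subset i = all records with year ≤ breakpoint i.

    The slicing must cover the data: a record year beyond the last breakpoint
    (or before the start year) is an error, and the last subset equals the
    full set.
    """
    years = occurrences.year
    if len(years):
        if years.max() > slicing.breakpoints[-1]:
            raise ValueError(
                f"record year {years.max()} beyond last breakpoint "
                f"{slicing.breakpoints[-1]}; slicing must cover the data"
            )
        if years.min() < slicing.start_year:
            raise ValueError(
                f"record year {years.min()} precedes start year {slicing.start_year}"
            )
    out = []
    for label, end in zip(slicing.labels, slicing.breakpoints):
        out.append((label, occurrences.subset(years <= end)))
    return out
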