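"""SDM evaluation: minimum convex polygon, pseudo-absences, and the TSS.

A presence-only model is evaluated against pseudo-absences: the minimum
convex polygon (MCP) of the records used to train the model clips the
geographic space, n random points are drawn uniformly over the valid cells
inside it, and a confusion matrix is counted at raster-cell granularity.
The True Skill Statistic is

    TSS = sensitivity + specificity − 1,

prevalence-insensitive and in [−1, 1].  The number of random points scales
with the MCP area relative to a reference period (5000 points for the
reference), so that evaluation effort is comparable between the nested
period models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import MultiPoint, Point, mapping

from .geoprojection import NODATA_BYTE, SuitabilityRaster
from .occurrences import OccurrenceSet
from .rasters import AUTHALIC_RADIUS_KM, ClimateStack

__all__ = [
    "ConvexPolygon",
    "ConfusionMatrix",
    "TSSResult",
    "minimum_convex_polygon",
    "pseudo_absences",
    "scaled_n_random",
    "tss",
]


@dataclass
class ConvexPolygon:
    """Convex hull of occurrence points, dateline-aware.

    When the point cloud spans the dateline, longitudes are re-centered
    (negative longitudes shifted by +360°) before hulling whenever that
    shrinks the longitudinal span; membership tests apply the same shift.
    """

    polygon: "object"  # shapely Polygon, in (possibly shifted) lon/lat
    shifted: bool

    @property
    def area_km2(self) -> float:
        """Spherical area via shoelace in the cylindrical equal-area projection."""
        xs, ys = self.polygon.exterior.xy
        lam = np.radians(np.asarray(xs))
        y = np.sin(np.radians(np.asarray(ys)))
        area = 0.5 * abs(
            np.sum(lam[:-1] * y[1:] - lam[1:] * y[:-1])
        )
        return float(AUTHALIC_RADIUS_KM**2 * area)

    def contains_points(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        if self.shifted:
            lon = np.where(lon < 0, lon + 360.0, lon)
        from shapely.prepared import prep

        prepared = prep(self.polygon)
        return np.array(
            [prepared.covers(Point(x, y)) for x, y in zip(lon, np.asarray(lat))]
        )

    def to_geojson(self, path: str | Path) -> None:
        poly = self.polygon
        if self.shifted:
            from shapely.ops import transform as shp_transform

            poly = shp_transform(
                lambda x, y: (np.where(np.asarray(x) > 180, np.asarray(x) - 360, x), y),
                poly,
            )
        Path(path).write_text(
            json.dumps({"type": "Feature", "geometry": mapping(poly), "properties": {}})
        )


def minimum_convex_polygon(occurrences: OccurrenceSet) -> ConvexPolygon:
    """MCP of occurrence points with automatic dateline re-centering.

    Requires at least three non-collinear points.  The re-centering shift
    (+360° on negative longitudes) is applied only when it reduces the
    longitudinal span of the cloud, so a range straddling 180°E/W is hulled
    as one compact region rather than a near-global band.
    """
    lon = occurrences.lon.copy()
    lat = occurrences.lat
    if len(lon) < 3:
        raise ValueError("minimum convex polygon requires at least 3 points")
    span_plain = lon.max() - lon.min()
    lon_shift = np.where(lon < 0, lon + 360.0, lon)
    span_shift = lon_shift.max() - lon_shift.min()
    shifted = span_shift < span_plain
    use_lon = lon_shift if shifted else lon
    hull = MultiPoint(list(zip(use_lon, lat))).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("points are collinear; convex hull is degenerate")
    return ConvexPolygon(hull, shifted)


def pseudo_absences(
    mcp: ConvexPolygon,
    n: int,
    valid: ClimateStack,
    seed: int = 0,
) -> np.ndarray:
    """n random points uniform over the valid cells inside the MCP.

    Cells are sampled uniformly with replacement among valid cells whose
    center lies in the polygon; each draw returns the cell center.  Output
    is an (n, 2) array of (lon, lat), reproducible under the seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rows, cols = np.nonzero(valid.valid_mask)
    if rows.size == 0:
        raise ValueError("climate stack has no valid cells")
    lon, lat = valid.grid.cell_center(rows, cols)
    inside = mcp.contains_points(lon, lat)
    if not inside.any():
        raise ValueError("no valid cells inside the minimum convex polygon")
    lon, lat = lon[inside], lat[inside]
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, lon.size, size=n)
    return np.column_stack([lon[pick], lat[pick]])


def scaled_n_random(
    mcp_area: float,
    reference_area: float,
    n_ref: int = 5000,
    floor: int = 100,
) -> int:
    """Pseudo-absence count proportional to MCP area, with a floor.

    n = round(n_ref × area / area_ref), never below *floor*; the reference
    period (the full dataset's MCP) receives n_ref points.
    """
    if reference_area <= 0:
        raise ValueError("reference MCP area must be positive")
    return max(floor, round(n_ref * mcp_area / reference_area))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cell-level presence/absence confusion counts."""

    tp: int  # presence cells predicted suitable
    fp: int  # random points predicted suitable
    fn: int  # presence cells predicted unsuitable
    tn: int  # random points predicted unsuitable

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_presence(self) -> int:
        return self.tp + self.fn

    @property
    def n_absence(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class TSSResult:
    """Sensitivity, specificity and TSS = sens + spec − 1."""

    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    tss: float
    n_random: int
    seed: int | None = None
    label: str = ""


def tss_from_confusion(cm: ConfusionMatrix, n_random: int = 0, seed=None, label="") -> TSSResult:
    if cm.n_presence == 0:
        raise ValueError("no evaluable presences")
    if cm.n_absence == 0:
        raise ValueError("no evaluable absences")
    sens = cm.tp / cm.n_presence
    spec = cm.tn / cm.n_absence
    return TSSResult(cm, sens, spec, sens + spec - 1.0, n_random, seed, label)


def tss(
    raster: SuitabilityRaster,
    presences: OccurrenceSet,
    absences: np.ndarray,
    seed: int | None = None,
) -> TSSResult:
    """Confusion matrix and TSS at raster-cell granularity.

    Presence records are deduplicated per cell (one cell = one presence
    unit); each random point counts once.  Points on nodata cells are
    dropped from the respective side.
    """
    grid = raster.grid

    prow, pcol = grid.index_of(presences.lon, presences.lat)
    ok = prow >= 0
    cells = set()
    for r, c in zip(prow[ok], pcol[ok]):
        if raster.grid_data[r, c] != NODATA_BYTE:
            cells.add((int(r), int(c)))
    tp = sum(1 for r, c in cells if raster.grid_data[r, c] == 1)
    fn = len(cells) - tp

    ab = np.atleast_2d(np.asarray(absences, dtype=float))
    arow, acol = grid.index_of(ab[:, 0], ab[:, 1])
    ok = arow >= 0
    vals = raster.grid_data[arow[ok], acol[ok]]
    vals = vals[vals != NODATA_BYTE]
    fp = int((vals == 1).sum())
    tn = int((vals == 0).sum())

    cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    return tss_from_confusion(cm, n_random=len(ab), seed=seed, label=raster.label)
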