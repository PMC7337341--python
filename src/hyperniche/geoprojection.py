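"""Projection of niche hypervolumes into geographic space.

Every valid (envelope-masked) cell's climate vector is transformed into PC
space and classified by the hypervolume's membership function, giving a
binary suitability raster; suitable area is the sum of spherical cell areas
(km²) over suitable cells.  By construction the suitable region is a subset
of the envelope mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hypervolume import NicheHypervolume
from .pca import PCSpace, transform
from .rasters import ClimateStack, GridSpec, cell_area_km2, write_ascii_grid

__all__ = ["SuitabilityRaster", "project", "area_km2"]

NODATA_BYTE = 255


@dataclass
class SuitabilityRaster:
    """Binary geographic projection of one hypervolume.

    ``grid_data`` is uint8: 1 suitable, 0 unsuitable, 255 nodata (outside
    the masked projection space).
    """

    grid_data: np.ndarray
    grid: GridSpec
    label: str = ""
    crs: str = "EPSG:4326"

    @property
    def suitable_mask(self) -> np.ndarray:
        return self.grid_data == 1

    @property
    def n_suitable(self) -> int:
        return int(self.suitable_mask.sum())

    def write(self, path: str | Path) -> None:
        data = np.where(self.grid_data == NODATA_BYTE, np.nan, self.grid_data.astype(float))
        write_ascii_grid(path, data, self.grid, nodata=float(NODATA_BYTE), fmt="%d")

    def summary(self) -> dict:
        return {
            "label": self.label,
            "suitable_cells": self.n_suitable,
            "area_km2": area_km2(self),
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=1))


def project(
    hv: NicheHypervolume, masked: ClimateStack, space: PCSpace
) -> SuitabilityRaster:
    """Classify every valid cell of the masked stack through the hypervolume.

    Cell values (at cell centers, no sub-cell interpolation) are transformed
    with the fitted PC space and tested for membership; nodata cells stay
    nodata.
    """
    if space.k != masked.k:
        raise ValueError(
            f"variable mismatch: PC space has {space.k}, stack has {masked.k}"
        )
    if space.m != hv.m:
        raise ValueError(
            f"dimensionality mismatch: PC space retains {space.m}, hypervolume is {hv.m}-D"
        )
    values, rows, cols = masked.values_table()
    out = np.full(masked.grid.shape, NODATA_BYTE, dtype=np.uint8)
    if len(values):
        pcs = transform(space, values)
        inside = hv.contains(pcs)
        out[rows, cols] = inside.astype(np.uint8)
    return SuitabilityRaster(out, masked.grid, label=hv.label)


def area_km2(raster: SuitabilityRaster) -> float:
    """Total spherical area (km²) of suitable cells."""
    rows, _ = np.nonzero(raster.suitable_mask)
    if rows.size == 0:
        return 0.0
    return float(cell_area_km2(raster.grid, rows).sum())


def plot(raster: SuitabilityRaster, ax=None, **imshow_kwargs):
    """Minimal map of a suitability raster (suitable/unsuitable/masked)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    img = np.where(raster.grid_data == NODATA_BYTE, np.nan, raster.grid_data).astype(float)
    g = raster.grid
    ax.imshow(
        img,
        extent=(g.west, g.east, g.south, g.north),
        origin="upper",
        **imshow_kwargs,
    )
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(raster.label or "suitability")
    return ax
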