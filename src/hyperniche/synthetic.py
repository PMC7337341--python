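"""Synthetic climate rasters and occurrences from a known expanding niche.

Every pipeline stage can be verified against ground truth without external
downloads: K correlated climate layers are built as linear mixes of a few
latent spatial gradients (low-order polynomials plus smoothed Gaussian
noise), and a species' "true niche" is an ellipsoid in the standardized
latent space whose center may drift and whose radii may grow across time
slices.  Occurrences for each slice are sampled uniformly from the cells
currently inside the ellipsoid and stamped with years inside the slice.

The latent-factor construction (default 4 latents → 19 layers) makes the
correlation-matrix PCA non-trivial — the Kaiser rule retains roughly as
many components as there are latents — while the generator records the
truth masks and areas needed for recovery tests.  A "static" scenario
(no drift, no growth) serves as the null against which expansion detection
must stay silent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .occurrences import OccurrenceSet, TemporalSlicing
from .rasters import ClimateStack, GridSpec, cell_area_km2

__all__ = ["SyntheticScenario", "generate_climate", "sample_occurrences", "truth_masks"]

#: new records introduced in each slice; cumulative totals 75, 105, …, 1106
DEFAULT_RECORDS_PER_SLICE = (75, 30, 60, 90, 130, 170, 230, 321)


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterization of a synthetic invasion scenario."""

    nrows: int = 100
    ncols: int = 200
    xll: float = 60.0
    yll: float = -25.0
    cellsize: float = 0.5
    n_layers: int = 19
    n_latents: int = 4
    latent_noise: float = 0.60  # sd of the smoothed-noise part of each latent
    layer_noise: float = 0.10  # sd of per-layer independent smoothed noise
    noise_sigma: float = 4.0  # smoothing radius, in cells
    ocean_fraction: float = 0.15  # fraction of the grid masked as nodata "ocean"
    niche_center0: tuple[float, ...] = (0.3, -0.2, 0.0, 0.1)
    niche_drift: tuple[float, ...] = (0.05, 0.08, 0.11, 0.03)  # per slice
    niche_radii0: tuple[float, ...] = (0.6, 0.55, 0.5, 0.6)
    niche_radii_growth: tuple[float, ...] = (0.05, 0.07, 0.10, 0.05)  # per slice
    records_per_slice: tuple[int, ...] = DEFAULT_RECORDS_PER_SLICE
    slicing: TemporalSlicing = field(default_factory=TemporalSlicing.decades)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.records_per_slice) != len(self.slicing.breakpoints):
            raise ValueError("records_per_slice must match the number of periods")
        for name in ("niche_center0", "niche_drift", "niche_radii0", "niche_radii_growth"):
            if len(getattr(self, name)) != self.n_latents:
                raise ValueError(f"{name} must have n_latents={self.n_latents} entries")
        if any(g < 0 for g in self.niche_radii_growth):
            raise ValueError("an expanding scenario needs non-negative radii growth")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.nrows, self.ncols, self.xll, self.yll, self.cellsize)

    @property
    def n_slices(self) -> int:
        return len(self.slicing.breakpoints)

    def center(self, t: int) -> np.ndarray:
        return np.asarray(self.niche_center0) + t * np.asarray(self.niche_drift)

    def radii(self, t: int) -> np.ndarray:
        return np.asarray(self.niche_radii0) + t * np.asarray(self.niche_radii_growth)

    def slice_years(self, t: int) -> tuple[int, int]:
        start = self.slicing.start_year if t == 0 else self.slicing.breakpoints[t - 1] + 1
        return start, self.slicing.breakpoints[t]

    @classmethod
    def static_niche(cls, **kwargs) -> "SyntheticScenario":
        """Null scenario: same niche in every slice (no drift, no growth)."""
        kwargs.setdefault("niche_drift", (0.0,) * 4)
        kwargs.setdefault("niche_radii_growth", (0.0,) * 4)
        kwargs.setdefault("niche_radii0", (1.2, 1.2, 1.2, 1.2))
        return cls(**kwargs)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially autocorrelated unit-variance noise field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return f / f.std()


def _fields(scn: SyntheticScenario):
    """Deterministic latent fields, land mask, and mixing matrix for a scenario."""
    rng = np.random.default_rng(scn.seed)
    ny, nx = scn.nrows, scn.ncols
    y, x = np.meshgrid(
        np.linspace(1, -1, ny), np.linspace(-1, 1, nx), indexing="ij"
    )
    # low-order deterministic spatial structure, one polynomial per latent
    polys = [y, x, x * y, x**2 - y**2, x + y**2, y - x**2]
    latents = []
    for i in range(scn.n_latents):
        base = polys[i % len(polys)]
        noise = _smooth_noise(rng, (ny, nx), scn.noise_sigma) * scn.latent_noise
        latents.append(base + noise)
    latents = np.stack(latents)

    ocean_field = _smooth_noise(rng, (ny, nx), 2 * scn.noise_sigma)
    if scn.ocean_fraction > 0:
        land = ocean_field > np.quantile(ocean_field, scn.ocean_fraction)
    else:
        land = np.ones((ny, nx), dtype=bool)

    mixing = rng.normal(size=(scn.n_layers, scn.n_latents))
    # guarantee every latent contributes substantially to at least one layer
    for i in range(scn.n_latents):
        mixing[i, i] += 2.0
    layer_rng = np.random.default_rng((scn.seed + 777) % 2**31)
    return latents, land, mixing, layer_rng


def generate_climate(scn: SyntheticScenario) -> ClimateStack:
    """K aligned, correlated layers; bit-identical regeneration under one seed."""
    latents, land, mixing, layer_rng = _fields(scn)
    layers = np.einsum("kl,lij->kij", mixing, latents)
    if scn.layer_noise > 0:
        for j in range(scn.n_layers):
            layers[j] += scn.layer_noise * _smooth_noise(
                layer_rng, land.shape, scn.noise_sigma
            )
    layers[:, ~land] = np.nan
    names = [f"bio{j + 1:02d}" for j in range(scn.n_layers)]
    return ClimateStack(layers, names, scn.grid)


def _standardized_latents(scn: SyntheticScenario):
    """Latent fields standardized over land cells, plus the land mask."""
    latents, land, _, _ = _fields(scn)
    z = np.empty_like(latents)
    for i in range(latents.shape[0]):
        vals = latents[i][land]
        z[i] = (latents[i] - vals.mean()) / vals.std()
    return z, land


def _ellipsoid_mask(z: np.ndarray, land: np.ndarray, c: np.ndarray, r: np.ndarray):
    d2 = np.zeros(land.shape)
    for i in range(z.shape[0]):
        d2 += ((z[i] - c[i]) / r[i]) ** 2
    return land & (d2 <= 1.0)


def truth_masks(scn: SyntheticScenario) -> list[np.ndarray]:
    """Cumulative truth masks: cells ever inside the niche up to each slice.

    Cumulative by union, so mask t is a superset of mask t−1 even when the
    ellipsoid drifts; for a purely growing niche the union equals the
    slice-t ellipsoid itself.
    """
    z, land = _standardized_latents(scn)
    masks, acc = [], np.zeros(land.shape, dtype=bool)
    for t in range(scn.n_slices):
        acc = acc | _ellipsoid_mask(z, land, scn.center(t), scn.radii(t))
        masks.append(acc.copy())
    return masks


def truth_areas_km2(scn: SyntheticScenario) -> list[float]:
    """Spherical area of each cumulative truth mask."""
    out = []
    for mask in truth_masks(scn):
        rows, _ = np.nonzero(mask)
        out.append(float(cell_area_km2(scn.grid, rows).sum()) if rows.size else 0.0)
    return out


def sample_occurrences(scn: SyntheticScenario, jitter: bool = True) -> OccurrenceSet:
    """Occurrence records per slice, drawn from the slice's current niche.

    For slice t, records fall uniformly on cells inside ellipsoid(c_t, r_t),
    with coordinates jittered within the cell and years uniform within the
    slice bounds; a slice whose ellipsoid covers no land cell is an error
    naming the slice.
    """
    z, land = _standardized_latents(scn)
    rng = np.random.default_rng((scn.seed + 424243) % 2**31)
    grid = scn.grid
    rows_all, cols_all, years_all = [], [], []
    for t in range(scn.n_slices):
        mask = _ellipsoid_mask(z, land, scn.center(t), scn.radii(t))
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise ValueError(f"slice {t}: niche ellipsoid covers no land cell")
        pick = rng.integers(0, rows.size, size=scn.records_per_slice[t])
        y0, y1 = scn.slice_years(t)
        years = rng.integers(y0, y1 + 1, size=pick.size)
        rows_all.append(rows[pick])
        cols_all.append(cols[pick])
        years_all.append(years)
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    years = np.concatenate(years_all)
    lon, lat = grid.cell_center(rows, cols)
    if jitter:
        lon = lon + grid.cellsize * rng.uniform(-0.45, 0.45, size=lon.size)
        lat = lat + grid.cellsize * rng.uniform(-0.45, 0.45, size=lat.size)
    df = pd.DataFrame(
        {
            "id": [f"syn{i}" for i in range(lon.size)],
            "lon": lon,
            "lat": lat,
            "year": years,
            "source": "synthetic",
        }
    )
    return OccurrenceSet(df)


def write_truth(scn: SyntheticScenario, path: str | Path) -> None:
    """Truth JSON: per-slice centers, radii, and cumulative areas (km²)."""
    payload = {
        "seed": scn.seed,
        "slices": [
            {
                "label": scn.slicing.labels[t],
                "center": scn.center(t).tolist(),
                "radii": scn.radii(t).tolist(),
            }
            for t in range(scn.n_slices)
        ],
        "cumulative_area_km2": truth_areas_km2(scn),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
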