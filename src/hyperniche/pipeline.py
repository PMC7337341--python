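"""End-to-end orchestration: one config in, the full artifact set out.

``run_all`` reproduces the complete temporal niche-expansion analysis from a
single declarative configuration: cleaned and sliced occurrences, the
envelope-masked climate stack, a PCA summary table, one hypervolume JSON +
suitability raster + area per period, the pairwise overlap matrix, the
per-period TSS table, and density profiles with the expansion report.  Every
random stage draws its seed from the master seed by stable hashing of the
stage name, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import minimum_convex_polygon, pseudo_absences, scaled_n_random, tss
from .geoprojection import area_km2, project
from .hypervolume import fit_hypervolume
from .occurrences import (
    OccurrenceSet,
    TemporalSlicing,
    clean_records,
    cumulative_subsets,
    read_occurrences,
)
from .overlap import matrix_to_frame, overlap_matrix, results_to_frame
from .pca import fit_pca, transform
from .profiles import expansion_report, profiles_by_period, profiles_to_frame
from .rasters import apply_envelope_mask, extract_values, fit_envelope, load_stack

log = logging.getLogger("hyperniche")

__all__ = ["RunConfig", "run_all", "analyze", "stage_seed"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from a master seed."""
    digest = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % 2**31


@dataclass
class RunConfig:
    occurrences: str
    rasters: list[str]
    out_dir: str
    land_mask: str | None = None
    exclusion: str | None = None
    column_map: dict = field(default_factory=dict)
    start_year: int = 1891
    first_break: int = 1950
    last_year: int = 2017
    breakpoints: list[int] | None = None
    labels: list[str] | None = None
    eigenvalue_threshold: float = 1.0
    pca_fit_on: str = "cells"  # or "points"
    gamma: float = 0.5
    nu: float = 0.01
    box_margin: float = 0.10
    mc_draws: int = 100_000
    overlap_draws: int = 200_000
    n_ref: int = 5000
    n_floor: int = 100
    scale_by: str = "mcp_area"  # or "n_records"
    min_records: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def slicing(self) -> TemporalSlicing:
        if self.breakpoints:
            labels = self.labels or [str(b) for b in self.breakpoints]
            return TemporalSlicing(tuple(self.breakpoints), tuple(labels), self.start_year)
        return TemporalSlicing.decades(self.start_year, self.first_break, self.last_year)

    def config_hash(self) -> str:
        return hashlib.blake2b(
            json.dumps(asdict(self), sort_keys=True).encode(), digest_size=8
        ).hexdigest()


def analyze(
    occ: OccurrenceSet,
    stack,
    slicing: TemporalSlicing,
    gamma: float = 0.5,
    nu: float = 0.01,
    mc_draws: int = 100_000,
    overlap_draws: int = 200_000,
    n_ref: int = 5000,
    seed: int = 0,
    pca_fit_on: str = "cells",
    with_tss: bool = True,
    with_overlap: bool = True,
) -> dict:
    """In-memory core analysis: envelope → PCA → hypervolumes → overlap,
    projection areas and (optionally) TSS; returns a results dictionary.

    This is the computational heart of :func:`run_all` without the file
    outputs; useful for simulation studies where inputs already live in
    memory.
    """
    occ = clean_records(occ)
    values_all, kept, _ = extract_values(occ, stack)
    occ = occ.subset(np.isin(np.arange(len(occ)), kept))
    box = fit_envelope(values_all, stack.names)
    masked = apply_envelope_mask(stack, box)
    subsets = cumulative_subsets(occ, slicing)
    fit_values = masked.values_table()[0] if pca_fit_on == "cells" else values_all
    space = fit_pca(fit_values, tuple(stack.names))

    hvs, areas, tss_scores = [], [], []
    mcps = {label: minimum_convex_polygon(sub) for label, sub in subsets}
    ref_area = mcps[subsets[-1][0]].area_km2
    rasters = []
    for label, sub in subsets:
        vals, _, _ = extract_values(sub, masked)
        pcs = transform(space, vals)
        hv = fit_hypervolume(
            pcs, gamma=gamma, nu=nu, mc_draws=mc_draws,
            seed=stage_seed(seed, f"hv:{label}"), label=label,
        )
        hvs.append(hv)
        sr = project(hv, masked, space)
        rasters.append(sr)
        areas.append(area_km2(sr))
        if with_tss:
            n = scaled_n_random(mcps[label].area_km2, ref_area, n_ref)
            absences = pseudo_absences(
                mcps[label], n, masked, stage_seed(seed, f"eval:{label}")
            )
            tss_scores.append(tss(sr, sub, absences).tss)

    jac = sor = None
    if with_overlap and len(hvs) >= 2:
        jac, sor, _ = overlap_matrix(hvs, overlap_draws, stage_seed(seed, "overlap"))
    return {
        "labels": [label for label, _ in subsets],
        "subsets": subsets,
        "space": space,
        "masked": masked,
        "hypervolumes": hvs,
        "rasters": rasters,
        "areas_km2": areas,
        "tss": tss_scores,
        "jaccard": jac,
        "sorensen": sor,
    }


def _stage(out: Path, name: str):
    """Context manager: mark the run failed (with the stage name) on error."""
    import contextlib

    @contextlib.contextmanager
    def guard():
        log.info("stage: %s", name)
        try:
            yield
        except Exception as exc:
            (out / "failed").write_text(f"stage {name!r} failed: {exc}\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    return guard()


def run_all(cfg: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slicing = cfg.slicing()
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "outputs": {},
        "stage_seeds": {},
    }

    with _stage(out, "occurrences"):
        occ = read_occurrences(
            cfg.occurrences, cfg.column_map, year_range=(cfg.start_year, slicing.breakpoints[-1])
        )
        occ = clean_records(occ, exclusion=cfg.exclusion)

    with _stage(out, "climate"):
        stack = load_stack(cfg.rasters)
        if cfg.land_mask is not None:
            occ = clean_records(occ, land=cfg.land_mask)
        values_all, kept, dropped = extract_values(occ, stack)
        occ = occ.subset(np.isin(np.arange(len(occ)), kept))
        box = fit_envelope(values_all, stack.names)
        masked = apply_envelope_mask(stack, box)

    with _stage(out, "slice"):
        subsets = cumulative_subsets(occ, slicing)
        period_of = pd.Series("", index=occ.df.index, dtype=str)
        # first period containing each record = its period of introduction
        for label, sub in reversed(subsets):
            period_of[occ.df["id"].isin(sub.df["id"]).to_numpy()] = label
        occ.df["period"] = period_of.to_numpy()
        occ.to_csv(out / "occurrences_clean.csv")
        occ.write_rejection_log(out / "occurrences_rejected.csv")
        manifest["n_records"] = len(occ)
        manifest["period_counts"] = {label: len(sub) for label, sub in subsets}

    with _stage(out, "pca"):
        if cfg.pca_fit_on == "cells":
            fit_values = masked.values_table()[0]
        elif cfg.pca_fit_on == "points":
            fit_values = values_all
        else:
            raise ValueError("pca_fit_on must be 'cells' or 'points'")
        space = fit_pca(fit_values, tuple(stack.names), cfg.eigenvalue_threshold)
        space.to_json(out / "pca.json")
        space.summary().to_csv(out / "pca_summary.csv")
        manifest["pca_m"] = space.m

    hypervolumes = []
    areas = {}
    with _stage(out, "hypervolumes"):
        for label, sub in subsets:
            if len(sub) < cfg.min_records:
                raise ValueError(f"period {label!r} has {len(sub)} records (<{cfg.min_records})")
            vals, _, _ = extract_values(sub, masked)
            pcs = transform(space, vals)
            seed = stage_seed(cfg.seed, f"hv:{label}")
            manifest["stage_seeds"][f"hv:{label}"] = seed
            hv = fit_hypervolume(
                pcs, gamma=cfg.gamma, nu=cfg.nu, mc_draws=cfg.mc_draws,
                seed=seed, box_margin=cfg.box_margin, label=label,
            )
            hv.to_json(out / f"hypervolume_{label.replace(' ', '_')}.json")
            hypervolumes.append(hv)

    with _stage(out, "projection"):
        for hv in hypervolumes:
            sr = project(hv, masked, space)
            tag = hv.label.replace(" ", "_")
            sr.write(out / f"sdm_{tag}.asc")
            sr.write_summary(out / f"sdm_{tag}.json")
            areas[hv.label] = area_km2(sr)
        pd.Series(areas, name="area_km2").to_csv(out / "areas_km2.csv")
        manifest["areas_km2"] = areas

    if len(hypervolumes) >= 2:
        with _stage(out, "overlap"):
            seed = stage_seed(cfg.seed, "overlap")
            manifest["stage_seeds"]["overlap"] = seed
            jac, sor, results = overlap_matrix(hypervolumes, cfg.overlap_draws, seed)
            labels = [hv.label for hv in hypervolumes]
            matrix_to_frame(jac, sor, labels).to_csv(out / "overlap_matrix.csv")
            results_to_frame(results).to_csv(out / "overlap_long.csv", index=False)
            manifest["jaccard_first_row"] = jac[0].tolist()
    else:
        log.warning("single period: overlap matrix skipped")

    with _stage(out, "evaluation"):
        mcps = {label: minimum_convex_polygon(sub) for label, sub in subsets}
        ref_label = subsets[-1][0]
        rows = []
        for (label, sub), hv in zip(subsets, hypervolumes):
            if cfg.scale_by == "mcp_area":
                n = scaled_n_random(
                    mcps[label].area_km2, mcps[ref_label].area_km2, cfg.n_ref, cfg.n_floor
                )
            else:
                n = max(cfg.n_floor, round(cfg.n_ref * len(sub) / len(subsets[-1][1])))
            seed = stage_seed(cfg.seed, f"eval:{label}")
            manifest["stage_seeds"][f"eval:{label}"] = seed
            absences = pseudo_absences(mcps[label], n, masked, seed)
            pd.DataFrame(absences, columns=["lon", "lat"]).to_csv(
                out / f"pseudo_absences_{label.replace(' ', '_')}.csv", index=False
            )
            sr = project(hv, masked, space)
            res = tss(sr, sub, absences, seed=seed)
            rows.append(
                {
                    "period": label, "n_random": n,
                    "tp": res.confusion.tp, "fp": res.confusion.fp,
                    "fn": res.confusion.fn, "tn": res.confusion.tn,
                    "sensitivity": res.sensitivity, "specificity": res.specificity,
                    "tss": res.tss,
                }
            )
            mcps[label].to_geojson(out / f"mcp_{label.replace(' ', '_')}.geojson")
        tss_table = pd.DataFrame(rows)
        tss_table.to_csv(out / "tss.csv", index=False)
        manifest["tss"] = dict(zip(tss_table["period"], tss_table["tss"]))

    with _stage(out, "profiles"):
        all_profiles = []
        reports = {}
        var_values = {}
        for i, name in enumerate(masked.names):
            per_period = {}
            for label, sub in subsets:
                vals, _, _ = extract_values(sub, masked)
                per_period[label] = vals[:, i]
            profs = profiles_by_period(per_period, variable=name)
            all_profiles.extend(profs)
            if len(profs) >= 2:
                reports[name] = asdict(expansion_report(profs))
        for j in range(space.m):
            per_period = {}
            for label, sub in subsets:
                vals, _, _ = extract_values(sub, masked)
                per_period[label] = transform(space, vals)[:, j]
            profs = profiles_by_period(per_period, variable=f"PC{j + 1}")
            all_profiles.extend(profs)
            if len(profs) >= 2:
                reports[f"PC{j + 1}"] = asdict(expansion_report(profs))
        profiles_to_frame(all_profiles).to_csv(out / "density_profiles.csv", index=False)
        (out / "expansion_report.json").write_text(json.dumps(reports, indent=1))
        manifest["expansion_flags"] = {
            k: bool(v["expanded_low"] or v["expanded_high"]) for k, v in reports.items()
        }

    numeric = json.dumps(
        {
            "areas": manifest["areas_km2"],
            "tss": manifest["tss"],
            "jaccard": manifest.get("jaccard_first_row"),
            "pca_m": manifest["pca_m"],
        },
        sort_keys=True,
    )
    manifest["numeric_hash"] = hashlib.blake2b(numeric.encode(), digest_size=8).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
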