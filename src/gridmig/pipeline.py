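"""End-to-end pipeline orchestration.

Runs the stages — synthesize (or load) inputs, harmonize censuses,
downscale rates, derive migration, delineate urban extents, build
socioclimatic bins, classify units — in dependency order, keeping
intermediate artifacts in memory, writing the canonical outputs (TIFF
rasters + CSV tables) under an output directory and emitting a manifest
of parameters, per-stage summaries and output hashes.  Deterministic
stages are byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from . import classify as gclassify
from . import migration as gmigration
from . import zoning as gzoning
from .downscale import downscale_rates
from .synthetic import SyntheticWorld, WorldConfig, generate_world
from .vital_rates import harmonize
from .zonal import zonal_sum

log = logging.getLogger(__name__)

STAGES = ("synth", "harmonize", "downscale", "migrate", "urban", "bins", "classify")

_DEPENDS = {
    "synth": (),
    "harmonize": ("synth",),
    "downscale": ("harmonize",),
    "migrate": ("downscale",),
    "urban": ("synth",),
    "bins": ("migrate", "urban"),
    "classify": ("migrate", "urban"),
}


@dataclass
class PipelineConfig:
    output_dir: str | Path = "gridmig_run"
    world: WorldConfig = field(default_factory=WorldConfig)
    weighting: str = "population"  # predictor/prediction aggregation
    windows: tuple[int, ...] = (5, 10)
    write_outputs: bool = True


class Pipeline:
    """Holds stage artifacts and executes stages in dependency order."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.artifacts: dict[str, object] = {}
        self.manifest: dict = {
            "config": {
                "world": asdict(config.world),
                "weighting": config.weighting,
                "windows": list(config.windows),
            },
            "stages": {},
            "outputs": {},
        }
        self._done: set[str] = set()

    # -- stage bodies -------------------------------------------------

    def _stage_synth(self) -> dict:
        world = generate_world(self.config.world)
        self.artifacts["world"] = world
        self._write_raster("admin1.tif", world.admin1)
        self._write_raster("population.tif", world.population, world.years)
        self._write_table("censuses.csv", world.censuses)
        self._write_table("national_rates.csv", world.national_reported)
        self._write_table("urban_share.csv", world.urban_share)
        return {
            "units": int(len(world.units)),
            "bookkeeping_error": world.bookkeeping_error(),
            "missingness": {k: len(v) for k, v in world.missingness_applied.items()},
        }

    def _stage_harmonize(self) -> dict:
        world: SyntheticWorld = self.artifacts["world"]
        harmonized = harmonize(
            world.censuses, world.gapfill_ctx, world.national_reported,
            world.units, world.region_of, world.years,
            unit_populations=world.censuses_complete[
                ["unit_id", "year", "population"]
            ].drop_duplicates(["unit_id", "year"]),
        )
        self.artifacts["harmonized"] = harmonized
        self._write_table("harmonized_rates.csv", harmonized)
        return {
            "records": int(len(harmonized)),
            "flags": harmonized["source_flag"].value_counts().to_dict(),
        }

    def _stage_downscale(self) -> dict:
        world: SyntheticWorld = self.artifacts["world"]
        ds = downscale_rates(
            self.artifacts["harmonized"], world.covariates, world.admin1,
            world.admin0, world.income_group_of, weighting=self.config.weighting,
        )
        self.artifacts["downscaled"] = ds
        for rt in ("birth", "death"):
            self._write_raster(f"{rt}_rates.tif", ds.rates[rt], ds.years)
        self._write_table("adjustment_factors.csv", ds.adjustment_factors)
        return {
            "r_squared": {f"{g}/{rt}": m.r_squared for (g, rt), m in ds.models.items()},
            "variograms": {rt: asdict(v) for rt, v in ds.variograms.items()},
        }

    def _stage_migrate(self) -> dict:
        world: SyntheticWorld = self.artifacts["world"]
        ds = self.artifacts["downscaled"]
        nat, mig, mig_years = gmigration.migration_stack(
            ds.rates["birth"], ds.rates["death"], world.population, world.years
        )
        self.artifacts["natural"] = nat
        self.artifacts["net_migration"] = mig
        self.artifacts["migration_years"] = mig_years
        summaries = {
            level: gmigration.aggregate_migration(
                mig, world.population[:-1], labels, mig_years,
                level=level, windows=self.config.windows,
            )
            for level, labels in ((0, world.admin0), (1, world.admin1), (2, world.admin2))
        }
        self.artifacts["summaries"] = summaries
        self._write_raster("net_migration.tif", mig, mig_years)
        for level, summ in summaries.items():
            self._write_table(f"migration_adm{level}.csv", summ)
        closure = float(
            np.abs(mig + nat - (world.population[1:] - world.population[:-1])).max()
        )
        return {"closure_error": closure, "years": mig_years}

    def _stage_urban(self) -> dict:
        world: SyntheticWorld = self.artifacts["world"]
        shares = world.urban_share.set_index(["country_id", "year"])["share"]
        masks = np.zeros_like(world.population, dtype=np.uint8)
        for yi, year in enumerate(world.years):
            share_map = {c: float(shares[(c, year)]) for c in world.region_of}
            masks[yi] = gzoning.urban_mask_by_country(
                world.population[yi], world.covariates.scaled_density[yi],
                world.admin0, share_map,
            )
        self.artifacts["urban_mask"] = masks
        self._write_raster("urban_mask.tif", masks, world.years)
        return {"urban_cells": {int(y): int(m.sum()) for y, m in zip(world.years, masks)}}

    def _stage_bins(self) -> dict:
        world: SyntheticWorld = self.artifacts["world"]
        mig = self.artifacts["net_migration"]
        mean_pop = world.population[:-1].mean(axis=0)  # full-period mean weights
        bins = gzoning.assign_bins(
            world.covariates.hdi[0], world.covariates.aridity, mean_pop
        )
        stats_df = gzoning.bin_statistics(
            bins, mig.sum(axis=0), self.artifacts["urban_mask"][0], mean_pop
        )
        self.artifacts["bins"] = bins
        self.artifacts["bin_statistics"] = stats_df
        self._write_raster("bins.tif", bins.bin_id)
        self._write_table("bin_statistics.csv", stats_df)
        shares = bins.population_shares(mean_pop)
        return {"bin_share_min": float(shares.min()), "bin_share_max": float(shares.max())}

    def _stage_classify(self) -> dict:
        world: SyntheticWorld = self.artifacts["world"]
        mig = self.artifacts["net_migration"]
        urban = self.artifacts["urban_mask"][0].astype(bool)
        results = {}
        for level, labels in ((0, world.admin0), (1, world.admin1), (2, world.admin2)):
            window = _unit_window_table(world, mig, urban, labels)
            classified = gclassify.classify_all_units(window)
            results[level] = classified
            self._write_table(f"classification_adm{level}.csv", classified)
        self.artifacts["classification"] = results
        shares = gclassify.class_population_shares(results[1])
        return {"impact_shares_adm1": {k: float(v) for k, v in shares.items()}}

    # -- plumbing -----------------------------------------------------

    def run(self, stages: tuple[str, ...] | None = None) -> dict:
        """Execute the requested stages (default: all) in order."""
        requested = list(STAGES) if stages is None else list(stages)
        unknown = set(requested) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for stage in STAGES:
            if stage not in requested:
                continue
            missing = [d for d in _DEPENDS[stage] if d not in self._done]
            if missing:
                raise RuntimeError(
                    f"stage {stage!r} requires {missing}; rerun those stages first"
                )
            summary = getattr(self, f"_stage_{stage}")()
            self.manifest["stages"][stage] = summary
            self._done.add(stage)
            log.info("stage %s done", stage)
        return self.manifest

    def _outdir(self) -> Path:
        out = Path(self.config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out

    def _write_raster(self, name: str, data, years=None) -> None:
        if not self.config.write_outputs:
            return
        path = self._outdir() / name
        gio.write_raster(path, np.asarray(data), years)
        self.manifest["outputs"][name] = _sha256(path)

    def _write_table(self, name: str, table: pd.DataFrame) -> None:
        if not self.config.write_outputs:
            return
        path = self._outdir() / name
        gio.write_table(path, table)
        self.manifest["outputs"][name] = _sha256(path)


def _unit_window_table(
    world: SyntheticWorld, mig: np.ndarray, urban: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Full-period per-unit aggregates feeding the classifiers."""
    pop_start, pop_end = world.population[0], world.population[-1]
    total_mig = mig.sum(axis=0)
    rows = []
    for part, sel in (("", np.ones_like(urban, dtype=bool)),
                      ("urban_", urban), ("rural_", ~urban)):
        dpop = zonal_sum(np.where(sel, pop_end - pop_start, 0.0), labels)
        msum = zonal_sum(np.where(sel, total_mig, 0.0), labels)
        pop = zonal_sum(np.where(sel, pop_start, 0.0), labels)
        rows.append((part, dpop, msum, pop))
    uids = sorted(rows[0][1])
    table = []
    for uid in uids:
        rec = dict(unit_id=uid)
        for part, dpop, msum, pop in rows:
            key = "pop_change" if part == "" else f"{part}pop_change"
            mkey = "net_mgr_sum" if part == "" else f"{part}mgr"
            rec[key] = dpop.get(uid, 0.0)
            rec[mkey] = msum.get(uid, 0.0)
            if part == "":
                rec["population"] = pop.get(uid, 0.0)
        table.append(rec)
    return pd.DataFrame(table)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Convenience wrapper: build a :class:`Pipeline` and run it."""
    pipe = Pipeline(config)
    manifest = pipe.run(stages)
    if config.write_outputs:
        (Path(config.output_dir) / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
    return manifest
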