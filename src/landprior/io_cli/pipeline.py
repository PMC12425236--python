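"""The umbrella pipeline: simulate → binarize → prioritize → scenarios → reports.

Every stage writes plain-text artifacts (ESRI ASCII grids and CSVs) into a run
directory; a JSON manifest records the full configuration, the declared
numeric conventions, per-stage timings, and a SHA-256 checksum for every
output file. Rerunning with the same configuration reproduces every file
bit-identically. Logging goes to standard error, with a machine-readable
JSON-lines event log beside the human one.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .. import synthetic_landscape as synth
from ..range_mapping import PERCENTILE_METHOD, evaluate_layer, threshold_10pct
from ..prioritizer import run_prioritization
from ..representativeness import gap_report
from ..scenario import expansion_summary, select_top_fraction
from ..types import Grid, PAMask, SpeciesLayer
from .config import RunConfig
from .raster import read_raster, write_raster

__all__ = ["run_pipeline", "load_ranges_dir", "load_species_csv"]

logger = logging.getLogger("landprior")


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _event(events: list, **kw) -> None:
    events.append(kw)
    logger.info("%s", kw)


def load_species_csv(path: str | Path) -> pd.DataFrame:
    """Species metadata CSV: species_id,iucn_category,weight[,n_presences]."""
    df = pd.read_csv(path)
    required = {"species_id", "iucn_category", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species CSV missing columns {sorted(missing)}")
    for _, row in df.iterrows():
        expected = synth.weight_from_iucn(row["iucn_category"])
        if int(row["weight"]) != expected:
            raise ValueError(
                f"species {row['species_id']}: weight {row['weight']} does not "
                f"match category {row['iucn_category']} (expected {expected})"
            )
    return df


def load_ranges_dir(
    ranges_dir: str | Path, species: pd.DataFrame, grid: Grid | None = None
) -> list[SpeciesLayer]:
    """Load one binary-range raster per species row from a directory."""
    ranges_dir = Path(ranges_dir)
    layers = []
    for _, row in species.iterrows():
        path = ranges_dir / f"{row['species_id']}.asc"
        if not path.exists():
            path = ranges_dir / f"{row['species_id']}.tif"
        data = read_raster(path, grid=grid)
        g = grid if grid is not None else data.to_grid()
        layers.append(
            SpeciesLayer(
                species_id=str(row["species_id"]),
                grid=g,
                values=(data.values > 0.5) & ~data.nodata_mask,
                iucn_category=str(row["iucn_category"]),
            )
        )
    return layers


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    On a stage failure the partial outputs are kept and an empty ``failed/``
    marker directory is created, with the failing stage named in the raised
    error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    events: list[dict] = []
    timings: dict[str, float] = {}
    outputs: list[Path] = []
    stage = "setup"
    try:
        cellsize = math.sqrt(config.cell_area)

        def _write(path: Path, values, nodata_mask=None) -> Path:
            write_raster(path, values, nodata_mask, cellsize=cellsize)
            outputs.append(path)
            return path

        # --- simulate -----------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        grid = Grid(config.rows, config.cols, cell_area=config.cell_area)
        landcover = synth.gen_landcover(
            grid,
            config.n_landcover_types,
            config.natural_fraction,
            config.patchiness,
            seed=config.seed,
        )
        cost = synth.gen_cost(landcover, config.natural_cost, config.human_cost)
        pa = synth.gen_pa_mask(
            grid, config.pa_fraction, config.pa_patches, seed=config.seed + 1
        )
        layers, occs = synth.gen_species_pool(
            grid,
            landcover,
            config.n_species,
            noise_sd=config.noise_sd,
            n_presences=config.n_presences,
            seed=config.seed + 2,
        )
        sim_dir = out / "simulated"
        sim_dir.mkdir(exist_ok=True)
        _write(sim_dir / "landcover.asc", landcover.codes)
        _write(sim_dir / "cost.asc", cost.values)
        _write(sim_dir / "pa.asc", pa.mask.astype(np.uint8))
        for layer in layers:
            _write(sim_dir / f"{layer.species_id}_suitability.asc", layer.values)
        species_df = pd.DataFrame(
            {
                "species_id": [l.species_id for l in layers],
                "iucn_category": [l.iucn_category for l in layers],
                "weight": [l.weight for l in layers],
                "n_presences": [len(o) for o in occs],
            }
        )
        species_csv = sim_dir / "species.csv"
        species_df.to_csv(species_csv, index=False)
        outputs.append(species_csv)
        occ_df = pd.concat(
            [
                pd.DataFrame(
                    {"species_id": o.species_id, "row": o.cells[:, 0], "col": o.cells[:, 1]}
                )
                for o in occs
            ]
        )
        occ_csv = sim_dir / "occurrences.csv"
        occ_df.to_csv(occ_csv, index=False)
        outputs.append(occ_csv)
        timings[stage] = time.perf_counter() - t0
        _event(events, stage=stage, n_species=len(layers), n_cells=grid.n_valid)

        # --- binarize -----------------------------------------------------
        stage = "binarize"
        t0 = time.perf_counter()
        ranges_dir = out / "ranges"
        ranges_dir.mkdir(exist_ok=True)
        binaries, eval_rows = [], []
        for layer, occ in zip(layers, occs):
            thr, binary = threshold_10pct(layer, occ, config.percentile)
            res = evaluate_layer(layer, occ, percentile=config.percentile)
            binaries.append(binary)
            from ..range_mapping import breadth_class

            eval_rows.append(
                {
                    "species_id": layer.species_id,
                    "auc": res.auc,
                    "tss": res.tss,
                    "threshold": thr,
                    "range_km2": binary.range_size_km2,
                    "breadth": breadth_class(binary.range_size_km2),
                }
            )
            _write(ranges_dir / f"{layer.species_id}.asc", binary.values.astype(np.uint8))
        eval_csv = out / "evaluation.csv"
        pd.DataFrame(eval_rows).to_csv(eval_csv, index=False)
        outputs.append(eval_csv)
        timings[stage] = time.perf_counter() - t0
        _event(events, stage=stage, n_species=len(binaries))

        # --- prioritize ---------------------------------------------------
        stage = "prioritize"
        t0 = time.perf_counter()
        weights = [l.weight for l in binaries]
        result = run_prioritization(binaries, weights, cost, pa, config.prioritizer)
        _write(out / "rank.asc", np.nan_to_num(result.rank_map.rank, nan=-9999.0),
               nodata_mask=np.isnan(result.rank_map.rank))
        curves_csv = out / "performance_curves.csv"
        result.curves.to_frame().to_csv(curves_csv)
        outputs.append(curves_csv)
        timings[stage] = time.perf_counter() - t0
        _event(
            events,
            stage=stage,
            iterations=len(result.log),
            removed=int(sum(e["removed"] for e in result.log)),
        )

        # --- scenarios + reports -------------------------------------------
        stage = "report"
        t0 = time.perf_counter()
        baseline = gap_report(binaries, pa.mask, mode=config.interpolation)
        baseline.rows.to_csv(out / "gap_baseline.csv", index=False)
        outputs.append(out / "gap_baseline.csv")
        comparisons = []
        for target in config.targets:
            scen = select_top_fraction(result.rank_map, target, pa)
            rep = gap_report(binaries, scen.mask, mode=config.interpolation)
            rep_csv = out / f"gap_target_{target:g}.csv"
            rep.rows.to_csv(rep_csv, index=False)
            outputs.append(rep_csv)
            summary = expansion_summary(baseline, rep, pa.land_fraction, scen.land_fraction)
            summary.insert(0, "scenario_target", target)
            comparisons.append(summary)
            _event(
                events,
                stage=stage,
                target=target,
                mean_coverage_pct=rep.mean_coverage_pct,
                n_well=rep.n_well,
            )
        comp_csv = out / "expansion_summary.csv"
        pd.concat(comparisons).to_csv(comp_csv, index=False)
        outputs.append(comp_csv)
        timings[stage] = time.perf_counter() - t0

        # --- manifest ------------------------------------------------------
        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "conventions": {
                "percentile_method": PERCENTILE_METHOD,
                "benefit_exponent_z": config.prioritizer.z,
                "interpolation_mode": config.interpolation,
                "neighborhood": config.prioritizer.neighborhood,
                "grid_indexing": "0-based, row-major, origin top-left",
            },
            "timings_s": timings,
            "outputs": {
                str(p.relative_to(out)): _sha256(p) for p in outputs
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        with open(out / "events.jsonl", "w") as fh:
            for ev in events:
                fh.write(json.dumps(ev) + "\n")
        return out
    except Exception as err:
        (out / "failed").mkdir(exist_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        logger.removeHandler(handler)
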