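"""End-to-end pipeline: simulate -> segment -> phenotype -> analyze.

Ties the library modules into one reproducible run that writes the seed
and plant tables, the fitted models, the germination and ant-preference
results, and a run log carrying the RNG seed.  Deterministic stages are
bit-identical across reruns with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import fadseed
from fadseed import io as fio
from fadseed.ant_preference import (
    grid_rank_test,
    grid_state,
    random_removal_null,
    trial_mixed_logistic,
    trial_preference,
)
from fadseed.association_stats import fit_linear, fit_mixed_linear
from fadseed.config import PipelineConfig
from fadseed.germination_analysis import (
    germination_summary,
    logrank_test,
    rank_sum_test,
)
from fadseed.phenotype import aggregate_plants, categorize_seeds
from fadseed.seed_imaging import SeedImage, measure_seed, segment_seed
from fadseed.synthetic_data import (
    AssayGenParams,
    ImageGenParams,
    PopulationGenParams,
    generate_germination,
    generate_grid,
    generate_population,
    generate_seed_image,
    generate_trials,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage."""


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(
    config: PipelineConfig,
    pop_params: Optional[PopulationGenParams] = None,
    assay_params: Optional[AssayGenParams] = None,
) -> dict:
    """Run every stage and return the report bundle (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"rng_seed": config.rng_seed, "version": fadseed.__version__}

    # ------------------------------------------------------------------ inputs
    if config.simulate:
        pop = pop_params or PopulationGenParams(seed=config.rng_seed)
        assay = assay_params or AssayGenParams(seed=config.rng_seed + 1)
        plants, seeds = generate_population(pop)
        germ = generate_germination(assay)
        trials = generate_trials(assay)
        grid = generate_grid(assay)
    elif config.seeds_csv:
        seeds = fio.read_table(config.seeds_csv)
        plants = germ = trials = grid = None
    else:
        raise PipelineError(
            "input stage: no inputs (set simulate=true or provide seeds_csv)"
        )

    # ------------------------------------------------------- segmentation demo
    if config.simulate and config.n_demo_images > 0:
        demo = []
        covers = seeds["spot_cover_pct"].to_numpy()[: config.n_demo_images]
        for i, cover in enumerate(covers):
            target = float(np.clip(cover / 100.0, 0.0, 0.5))
            img, truth = generate_seed_image(
                ImageGenParams(target_cover=target, seed=config.rng_seed + 100 + i)
            )
            m = measure_seed(
                segment_seed(SeedImage(img, source=f"demo_{i}"), config.segmentation)
            )
            demo.append(
                {
                    "image": f"demo_{i}",
                    "true_cover_pct": 100.0 * truth.spot.sum() / truth.seed.sum(),
                    "recovered_cover_pct": m.spot_cover_pct,
                }
            )
        report["segmentation_demo"] = demo

    # -------------------------------------------------------------- phenotype
    try:
        seeds = seeds.copy()
        seeds["category"] = categorize_seeds(
            seeds["spot_cover_pct"].tolist(),
            low_quantile=config.quantile_cut,
            high_quantile=1.0 - config.quantile_cut,
        )
    except ValueError as exc:
        raise PipelineError(f"phenotype stage: {exc}") from exc
    plant_pheno = aggregate_plants(seeds)
    if plants is not None:
        plant_pheno = plant_pheno.merge(
            plants[["plant_id", "total_flowers"]], on="plant_id"
        )
    fio.write_table(seeds, out / "seeds.csv", schema="seeds")
    if plants is not None:
        fio.write_table(plants, out / "plants.csv", schema="plants")
    fio.write_table(plant_pheno, out / "plant_phenotypes.csv")

    # ---------------------------------------------------- fitness association
    if plants is not None:
        lin = fit_linear(
            plant_pheno["total_flowers"].to_numpy(),
            plant_pheno["mean_cover"].to_numpy(),
        )
        report["fitness_cover_regression"] = _jsonable(lin)
        mixed = fit_mixed_linear(
            seeds["spot_cover_pct"].to_numpy(),
            seeds["seed_area_px"].to_numpy(),
            seeds["plant_id"].to_numpy(),
        )
        report["cover_seed_area_mixed"] = _jsonable(mixed)
        by_cat = seeds.merge(plants[["plant_id", "total_flowers"]], on="plant_id")
        report["mean_fitness_by_category"] = {
            cat: float(grp["total_flowers"].mean())
            for cat, grp in by_cat.groupby("category")
        }

    # ------------------------------------------------------------ germination
    if germ is not None:
        fio.write_table(germ, out / "germination.csv", schema="germination")
        report["germination_summary"] = _jsonable(
            germination_summary(germ).to_dict(orient="records")
        )
        report["germination_logrank"] = _jsonable(logrank_test(germ))
        g_un = germ[germ.category == "unspotted"]
        g_sp = germ[germ.category == "spotted"]
        report["germination_rank_sum"] = _jsonable(
            rank_sum_test(
                g_un["germinated"].astype(int).tolist(),
                g_sp["germinated"].astype(int).tolist(),
            )
        )

    # --------------------------------------------------------- ant preference
    if trials is not None:
        fio.write_table(trials, out / "trials.csv", schema="trials")
        report["trial_preference"] = _jsonable(trial_preference(trials))
        report["trial_mixed_logistic"] = _jsonable(trial_mixed_logistic(trials))
    if grid is not None:
        fio.write_table(grid.layout, out / "grid_layout.csv", schema="grid_layout")
        fio.write_table(grid.events, out / "grid_events.csv", schema="grid_events")
        half = len(grid.layout) // 2
        state = grid_state(grid, half)
        report["grid_half_state"] = _jsonable(state.to_dict(orient="records"))
        report["grid_rank_test"] = _jsonable(grid_rank_test(grid))
        row = state[state.category == "unspotted"].iloc[0]
        report["grid_random_removal_null"] = random_removal_null(
            int(row["removed"]),
            half,
            int(row["initial"]),
            int(len(grid.layout)),
        )

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"fadseed {fadseed.__version__}\nrng_seed={config.rng_seed}\n")
    logger.info("pipeline complete: %s", out / "report.json")
    return report
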