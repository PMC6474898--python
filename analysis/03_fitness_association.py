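"""Test whether lower-fitness plants produce less-spotted seeds.

Reads the simulated tables from results/data/, classifies seeds into the
unspotted/spotted extremes (15% tails by rank), aggregates to plant level,
and fits (i) the plant-level regression of mean spot cover on total
flowers and (ii) the seed-level mixed model of cover on seed area with a
per-plant random intercept.  Writes results/fitness_models.json.
"""

import json

from fadseed import io as fio
from fadseed.association_stats import fit_linear, fit_mixed_linear
from fadseed.phenotype import aggregate_plants, categorize_seeds
from fadseed.pipeline import _jsonable

DATA = "results/data"


def main() -> None:
    seeds = fio.read_table(f"{DATA}/seeds.csv")
    plants = fio.read_table(f"{DATA}/plants.csv")

    seeds["category"] = categorize_seeds(seeds["spot_cover_pct"].tolist())
    per_plant = aggregate_plants(seeds).merge(
        plants[["plant_id", "total_flowers"]], on="plant_id"
    )

    ols = fit_linear(per_plant["total_flowers"], per_plant["mean_cover"])
    mixed = fit_mixed_linear(
        seeds["spot_cover_pct"], seeds["seed_area_px"], seeds["plant_id"]
    )
    by_cat = seeds.merge(plants[["plant_id", "total_flowers"]], on="plant_id")
    fitness_by_cat = {
        cat: float(grp["total_flowers"].mean())
        for cat, grp in by_cat.groupby("category")
    }

    out = {
        "plant_level_ols": _jsonable(ols),
        "seed_level_mixed": _jsonable(mixed),
        "mean_fitness_by_category": fitness_by_cat,
    }
    with open("results/fitness_models.json", "w") as fh:
        json.dump(out, fh, indent=2)

    print(
        f"plant-level OLS: slope = {ols.slope:.4f} %/flower "
        f"(SE {ols.slope_se:.4f}, t = {ols.t:.2f}, p = {ols.p_value:.3g}, "
        f"R^2 = {ols.r_squared:.2f}, n = {ols.n} plants)"
    )
    print(
        "mean plant fitness by seed category: "
        + ", ".join(f"{k} = {v:.1f}" for k, v in sorted(fitness_by_cat.items()))
    )
    direction = "lower" if fitness_by_cat["unspotted"] < fitness_by_cat["spotted"] else "higher"
    print(f"=> unspotted seeds come from plants of {direction} fitness")
    print("models: results/fitness_models.json")


if __name__ == "__main__":
    main()
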