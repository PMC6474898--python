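"""Simulate every input of the analysis: plants, seeds, germination, assays.

Writes the tables under results/data/ and prints the headline properties
of the simulated population (scale, cover range, generating slope).
"""

import sys

from fadseed import io as fio
from fadseed.synthetic_data import (
    AssayGenParams,
    PopulationGenParams,
    generate_germination,
    generate_grid,
    generate_population,
    generate_trials,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = "results/data"


def main() -> None:
    pop = PopulationGenParams(seed=SEED)
    plants, seeds = generate_population(pop)
    assay = AssayGenParams(seed=SEED + 1)
    germination = generate_germination(assay)
    trials = generate_trials(assay)
    grid = generate_grid(assay)

    fio.write_table(plants, f"{OUT}/plants.csv", schema="plants")
    fio.write_table(seeds, f"{OUT}/seeds.csv", schema="seeds")
    fio.write_table(germination, f"{OUT}/germination.csv", schema="germination")
    fio.write_table(trials, f"{OUT}/trials.csv", schema="trials")
    fio.write_table(grid.layout, f"{OUT}/grid_layout.csv", schema="grid_layout")
    fio.write_table(grid.events, f"{OUT}/grid_events.csv", schema="grid_events")

    print(f"simulated {len(plants)} plants, {len(seeds)} seeds (1 per whorl)")
    print(
        "seed spot cover range: "
        f"{seeds.spot_cover_pct.min():.1f}-{seeds.spot_cover_pct.max():.1f}% "
        f"(generating slope {pop.slope} %/flower, intercept {pop.intercept}%)"
    )
    print(
        f"germination: {len(germination)} seeds; trials: {len(trials)}; "
        f"grid: {len(grid.events)} removals"
    )
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
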