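"""Posterior prediction on the landscape grid; stratum and area tables.

Reads results/sim/ and results/fit/; writes results/{predictions.csv,
strata.csv, areas.csv}.  The stratum table is the distance-class summary
of predicted lichen species richness with the probability that each class
is lower than the next farther one; the area table partitions the study
area by predicted richness relative to the farthest stratum's mean,
split inside/outside the industrial easement corridor.
"""

import sys
from pathlib import Path

from dustshed import io
from dustshed.model import read_posterior
from dustshed.predict import (
    area_summary,
    point_summary,
    posterior_predict,
    stratum_summary,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    plots = io.read_plot_table(ROOT / "sim" / "plots.csv")
    grid = io.read_grid_table(ROOT / "sim" / "grid.csv")
    draws = read_posterior(ROOT / "fit" / "posterior.csv", plots)

    pdw = posterior_predict(draws, grid, seed=SEED)
    points = point_summary(pdw)
    strata = stratum_summary(pdw, grid)
    top_mean = strata["mean_lsr"].iloc[-1]
    areas = area_summary(pdw.lam.mean(axis=0), grid, top_mean)

    points.to_csv(ROOT / "predictions.csv", index=False)
    strata.to_csv(ROOT / "strata.csv", index=False)
    areas.to_csv(ROOT / "areas.csv", index=False)
    io.write_manifest(ROOT, "04_predict", {"seed": SEED}, SEED,
                      [ROOT / "fit" / "posterior.csv", ROOT / "sim" / "grid.csv"])

    print(f"predicted {len(points)} grid points from {pdw.n_draws} draws\n")
    print("richness by distance class (stratum means over draws):")
    print(strata.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    below = areas["cum_area_km2"].iloc[2]
    print(f"\narea with predicted richness < 75% of the top stratum: "
          f"{below:.1f} km2 ({areas['cum_pct_area'].iloc[2]:.0f}% of the corridor)")


if __name__ == "__main__":
    main()
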