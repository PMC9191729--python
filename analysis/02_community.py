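"""Community analysis: filtering, transform, outliers, MRPP, ISA, summaries.

Reads results/sim/; writes results/community/{mrpp.csv, isa.csv,
outliers.csv, class_summaries.csv}.  The workflow follows the standard
sequence for gradient studies: screen outliers on the raw matrix with
Euclidean distance (the only measure tolerating empty plots), drop empty
plots and taxa with one or fewer occurrences, log-transform cover, then
test community differences between distance classes (MRPP) and identify
the taxa driving them (indicator species analysis).
"""

import sys
from pathlib import Path

import pandas as pd

from dustshed import community as comm
from dustshed import io

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "community"
    out.mkdir(parents=True, exist_ok=True)
    plots = io.read_plot_table(ROOT / "sim" / "plots.csv")
    matrix = io.read_community_matrix(ROOT / "sim" / "community.csv")

    # outlier screen on the raw matrix (Euclidean tolerates empty plots)
    d_raw = comm.distance_matrix(matrix, "euclidean")
    outliers = comm.detect_outliers(d_raw, 2.0)
    print(f"outlier screen (Euclidean, 2 SD): {len(outliers)} plot(s) flagged")

    filtered = comm.filter_matrix(matrix, min_occurrences=1, drop_empty_plots=True)
    print(f"matrix {matrix.shape[0]}x{matrix.shape[1]} -> "
          f"{filtered.shape[0]}x{filtered.shape[1]} after filtering")
    transformed = comm.transform_cover(filtered)

    kept = plots.set_index("plot_id").loc[filtered.index]
    cls = io.distance_class(kept["dist_road"].to_numpy())
    labels = [io.class_labels()[c] for c in cls]

    dm = comm.distance_matrix(transformed, "sorenson")
    pairwise = comm.mrpp_pairwise(dm, labels, n_permutations=999, seed=SEED)
    pairwise.to_csv(out / "mrpp.csv", index=False)
    strong = pairwise[pairwise["A"] >= 0.10]
    print(f"\nMRPP: {len(strong)}/{len(pairwise)} class pairs with strong "
          f"community differences (A >= 0.10); max A = {pairwise['A'].max():.2f}")

    # two-group ISA: < 1000 m vs >= 1000 m, the grouping that separated
    # sensitive from tolerant taxa in the field data
    groups = ["near" if c < 4 else "far" for c in cls]
    isa = comm.indicator_species_analysis(transformed, groups,
                                          n_permutations=999, seed=SEED)
    isa.table.to_csv(out / "isa.csv", index_label="taxon")
    sig = isa.table[isa.table["p"] < 0.05]
    print(f"ISA (<1000 m vs >=1000 m): {len(sig)} significant indicator taxa, "
          f"{(sig['group'] == 'far').sum()} of them for the far group")

    pd.Series(outliers, name="plot_id").to_csv(out / "outliers.csv", index=False)
    rows = []
    for var in ("richness", "Zn", "Pb", "Cd", "pct_blackening"):
        s, anova = comm.summarize_by_class(plots, var, io.DEFAULT_CLASS_EDGES)
        s.insert(0, "variable", var)
        s["anova_F"] = anova["F"] if anova else None
        rows.append(s)
    pd.concat(rows).to_csv(out / "class_summaries.csv", index=False)
    io.write_manifest(out, "02_community", {"seed": SEED}, SEED,
                      [ROOT / "sim" / "plots.csv", ROOT / "sim" / "community.csv"])


if __name__ == "__main__":
    main()
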