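"""Over-representation analysis of the overlap genes against the three
synthetic gene-set libraries, with BH adjustment per library and
bubble-plot exports (term, gene count, q-value).

Usage: python analysis/04_enrichment.py [--in results/synth_inputs] [--out results] [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from netpharm.enrichment import bubble_data, enrich, results_table
from netpharm.io_formats import read_gmt
from netpharm.synth_data import SyntheticTruth


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--in", dest="indir", type=Path, default=Path("results/synth_inputs"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    truth = SyntheticTruth.from_json(args.indir / "truth.json")
    query = set(pd.read_csv(args.out / "overlap_genes.tsv", sep="\t")["gene"])

    for i, name in enumerate(("go_synth", "kegg_synth", "wiki_synth")):
        library = read_gmt(args.indir / f"{name}.gmt")
        results = enrich(query, library, rng=args.seed + i)
        results_table(results).to_csv(args.out / f"enrichment_{name}.tsv",
                                      sep="\t", index=False)
        bubble_data(results).to_csv(args.out / f"bubble_{name}.tsv",
                                    sep="\t", index=False)
        top = results[0]
        planted = top.term_id in truth.planted_enriched_terms
        print(f"{name}: top term {top.term_id} "
              f"(overlap {top.overlap_size}/{top.term_size}, "
              f"p={top.p_value:.3g}, q={top.q_value:.3g}, "
              f"combined score {top.combined_score:.1f}) "
              f"planted={planted}")


if __name__ == "__main__":
    main()
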