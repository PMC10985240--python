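"""Merge compound-predicted and disease-associated targets and intersect.

Reads the generated inputs, applies the score filters (relevance >= 10 for
the GeneCards-style source, score >= 0.3 for the DisGeNET-style source,
curated sources taken whole), unions the survivors, and intersects with
the deduplicated compound-side target union — the Venn step that yields
the candidate genes everything downstream is built on.

Usage: python analysis/02_merge_targets.py [--in results/synth_inputs] [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from netpharm.synth_data import PRESET_FILTERS, PRESET_SOURCE_NAMES
from netpharm.target_sets import (
    intersect,
    merge_compound_targets,
    merge_disease_targets,
    read_disease_source,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--in", dest="indir", type=Path, default=Path("results/synth_inputs"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    pred = pd.read_csv(args.indir / "compound_targets.tsv", sep="\t")
    cmap = merge_compound_targets(
        [(r.compound, r.gene, float(r.score)) for r in pred.itertuples()]
    )
    sources = [
        (name, read_disease_source(args.indir / f"disease_{name}.tsv"))
        for name in PRESET_SOURCE_NAMES
    ]
    disease = merge_disease_targets(sources, PRESET_FILTERS)
    overlap = intersect(cmap, disease)

    args.out.mkdir(parents=True, exist_ok=True)
    counts = pd.DataFrame(
        {
            "quantity": [
                *[f"disease_targets_{name}" for name in disease.per_source],
                "merged_disease_targets",
                "unique_compound_targets",
                "overlap",
            ],
            "count": [
                *disease.counts().values(),
                len(disease.merged),
                cmap.n_unique_targets,
                len(overlap.intersection),
            ],
        }
    )
    counts.to_csv(args.out / "target_counts.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(overlap.intersection), columns=["gene"]).to_csv(
        args.out / "overlap_genes.tsv", sep="\t", index=False
    )
    print(counts.to_string(index=False))
    print(f"status: {overlap.status}")


if __name__ == "__main__":
    main()
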