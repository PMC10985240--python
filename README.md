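# netpharm

Network-pharmacology analysis of an essential-oil mixture: from GC–MS
compound contents and target predictions, through compound–target network
topology and protein–protein interaction (PPI) hub ranking, to pathway
over-representation analysis and a reconstituted w/w mixture recipe.

The study this package reproduces asks which constituents of *Citrus
reticulata* Blanco essential oil (CBEO) plausibly drive its antidepressant
activity. The workflow is the standard network-pharmacology funnel:

1. **Targets.** Predicted protein targets for each GC–MS-detected compound
   (prediction score > 0) are merged and deduplicated; disease-associated
   genes are collected from several sources, each with its own inclusion
   rule (relevance ≥ 10 for a GeneCards-style source, score ≥ 0.3 for a
   DisGeNET-style source, curated sources taken whole), and unioned. The
   intersection of the two sides gives the candidate genes.
2. **Compound–target network.** A bipartite network over compounds and
   candidate genes. For each compound we compute its degree and its
   normalized betweenness centrality (Brandes' algorithm; normalization
   2/((N−1)(N−2)) with N the total node count, disconnected pairs
   contributing 0).
3. **Screening.** Compounds strictly above *both* the mean degree and the
   mean betweenness are selected as putative actives.
4. **PPI hubs.** Candidate genes are mapped onto a PPI network; genes with
   no interactions ("free" genes) are excluded, and the top-k genes by
   degree (ties broken alphabetically, ties at the cut expanded) are the
   hubs.
5. **Enrichment.** Over-representation analysis (ORA) of the candidate
   genes against gene-set libraries: exact hypergeometric upper-tail
   p-values, Benjamini–Hochberg adjustment per library, and an
   Enrichr-style combined score |z · ln p| where z is a rank-based z-score
   from seeded random-query permutations.
6. **Mixture.** The selected compounds' GC–MS relative contents are turned
   into a w/w ratio against a reference compound and into per-dose masses
   (dose in mg/kg × body mass in kg, split by mass fraction).

Because the original databases (SwissTargetPrediction, GeneCards,
DisGeNET, TTD, OMIM, STRING, Enrichr) are not redistributable, the package
ships a **synthetic data generator** (`netpharm.synth_data`) that plants
known actives, a known compound∕disease overlap, known hubs, and known
enriched terms at the same problem sizes as the real study, so the whole
pipeline is exercised end to end with a recoverable ground truth. The two
small measured tables that *are* public — the 18-row GC–MS content table
and the 16-row compound-topology table — are packaged as TSV fixtures
(`netpharm.datasets`).

## Worked example

Generate a synthetic study and run the funnel (all outputs under
`results/`, which is gitignored):

```sh
python analysis/01_generate_inputs.py --seed 1
python analysis/02_merge_targets.py
python analysis/03_network_screening.py
python analysis/04_enrichment.py
python analysis/05_mixture_recipe.py
```

Actual output of steps 2–3 (seed 1):

```text
                 quantity  count
disease_targets_genecards     54
 disease_targets_disgenet    177
      disease_targets_ttd     29
     disease_targets_omim    376
   merged_disease_targets    472
  unique_compound_targets    107
                  overlap     29
status: ok
measured table: mean degree 11.125, mean betweenness 0.049352
  selected: ['α-Terpineol', 'α-Terpinene', 'Linalool', 'Terpinen-4-ol', 'p-Cymene']
synthetic network: 45 nodes, 184 edges (16 compounds, 29 targets; dropped ['Cyclohexane', 'Methylcyclopentane'])
  selected: ['Linalool', 'Terpinen-4-ol', 'p-Cymene', 'α-Terpineol', 'α-Terpinene']
PPI: 28 nodes, 78 edges, mean degree 5.571, free genes ['TG029']
  hubs: [('OPRM1', 17), ('ESR1', 13), ('PTGS2', 11), ('DRD2', 10), ('SLC6A4', 10), ('NR3C1', 9)]
planted actives recovered: True
planted hubs recovered: True
```

The screen on the packaged measured table selects exactly the five
published actives; the synthetic run recovers the planted actives and
hubs. Enrichment (step 4) ranks the planted term first in each library,
e.g. `go_synth: top term GO_SYNTH0025 (overlap 10/13, p=4.63e-12,
q=2.32e-10, combined score 47.4) planted=True`. Step 5 prints the recipe:

```text
content-derived ratio (Linalool, p-Cymene, α-Terpinene, Terpinen-4-ol, α-Terpineol):
  2:5:0.6:0.8:1  (reference: α-Terpineol)
published ratio: 0.8:5:0.6:2:1
per-dose masses at 12.5 mg/kg x 0.028 kg (total 0.35 mg):
  Linalool: 0.0745 mg
  p-Cymene: 0.1862 mg
  α-Terpinene: 0.0223 mg
  Terpinen-4-ol: 0.0298 mg
  α-Terpineol: 0.0372 mg
mass fractions differing from the published vector: ['Linalool', 'Terpinen-4-ol']
```

The content-derived ratio and the published one transpose the linalool and
terpinen-4-ol parts; the package computes both and diffs them rather than
silently adopting either (see `docs/methods.md`).

The same steps as library calls:

```python
from netpharm.datasets import load_cbeo_contents, load_cbeo_topology
from netpharm.network_topology import screen_compounds
from netpharm.mixture import compute_ratio

screening = screen_compounds(load_cbeo_topology())
print(screening.mean_degree)        # 11.125
print(screening.selected)           # the five actives
spec = compute_ratio(screening.selected, load_cbeo_contents(),
                     reference="α-Terpineol")
print(spec.ratio_string())          # 2:5:0.6:0.8:1
```

## Layout

- `src/netpharm/` — the library: `io_formats`, `target_sets`,
  `network_topology`, `enrichment`, `mixture`, `synth_data`, `pipeline`
  (an end-to-end runner with per-stage error wrapping and a JSON run
  summary), `datasets` (packaged fixtures).
- `analysis/` — the numbered narrative drivers shown above.
- `scripts/acceptance.py` — headline-quantity reproduction.
- `tests/` — pytest suite, oracles first; `tests/test_acceptance.py`
  holds the end-to-end checks.
- `docs/methods.md` — methods note: model, statistics, generator design,
  parameter rationale, limitations.
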