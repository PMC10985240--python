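# Methods

## Model and procedure

The package implements the standard network-pharmacology funnel for a
multi-component botanical extract:

1. **Compound targets.** Per-compound target predictions `(compound,
   gene, score)` are kept when score > 0, canonicalized (gene symbols
   upper-cased), merged across compounds, and deduplicated into a target
   union. Compounds whose every prediction has score ≤ 0 are retained as
   empty-set keys so counts stay honest.
2. **Disease targets.** Each source carries its own inclusion rule,
   expressed as a `SourceFilter(score_field, threshold, comparator)`:
   relevance ≥ 10 for the GeneCards-style source, score ≥ 0.3 for the
   DisGeNET-style source, curated sources (TTD-, OMIM-style) taken whole.
   Survivors are unioned; per-source counts are reported.
3. **Overlap.** The intersection of the compound-side union and the
   disease-side union. An empty intersection is a *terminal status*, not
   an error: the pipeline stops cleanly and reports it.
4. **Bipartite network.** Nodes are compounds and overlap genes; edges
   are the surviving predictions restricted to the overlap. Compounds
   with no overlap edge are dropped (and reported), matching the
   published network in which 2 of 18 compounds disappear.
5. **Topology.** Degree, and betweenness centrality by Brandes'
   algorithm (BFS shortest-path counting plus dependency accumulation),
   halved for undirected graphs and normalized by (N−1)(N−2)/2 where N is
   the **whole-graph** node count — so on a graph with disconnected
   pieces, unreachable pairs simply contribute 0. N < 3 gives all zeros.
6. **Screening.** A compound is selected iff degree > mean(degree) AND
   betweenness > mean(betweenness), means taken over all network
   compounds. Strict `>` is the default (`comparator="gt"`); `"ge"` is
   available. Selected compounds are sorted by (−degree, name).
7. **PPI hubs.** Overlap genes with no PPI edge among themselves are
   excluded as *free* genes; mean degree is 2·E/N on the remaining
   network. Hubs are the top k = 6 by degree, ties alphabetical, with
   tie-expansion at the cut (all genes tied with the k-th are included).
8. **ORA.** For a query of size n against a term with K members in a
   universe of M genes, the p-value is the exact hypergeometric upper
   tail P(X ≥ k) = `scipy.stats.hypergeom.sf(k−1, M, K, n)`. Per-library
   BH adjustment uses `statsmodels.stats.multitest.multipletests`
   (`fdr_bh`). The Enrichr-style combined score is |z · ln p| with z a
   rank z-score of the observed p against p-values of seeded
   random same-size queries (default 100 permutations; 0 permutations →
   z = 0). A query disjoint from the universe raises an error that
   mentions casing, the usual culprit.
9. **Mixture.** The selected compounds' GC–MS relative contents (% w/w)
   are divided by a reference compound's content to give the ratio; mass
   fractions are content/Σcontent. Per-dose mass of component i is
   dose(mg/kg) × body mass(kg) × mass-fraction(i).

## Ratio-reference and ratio-conflict handling

The measured contents of the five actives (1, 2.5, 0.3, 0.4, 0.5 % for
linalool, p-cymene, α-terpinene, terpinen-4-ol, α-terpineol) imply the
ratio 2 : 5 : 0.6 : 0.8 : 1 with α-terpineol as reference. The published
mixture used 0.8 : 5 : 0.6 : 2 : 1 — the linalool and terpinen-4-ol parts
transposed. The library computes the content-derived ratio, accepts a
user-supplied override (`spec_from_ratio`), and diffs the two
(`diff_ratios`); it never silently adopts either. The default reference
is the lowest-content selected compound; the analysis driver passes
α-terpineol explicitly so both vectors share the same ":1" tail.

## Synthetic data generator

Real upstream databases are not redistributable, so `synth_data` emits
studies with planted, recoverable structure at the real study's sizes
(18 compounds, ~120 unique targets, four disease sources of sizes
82/260/29/376 pre-filter, 29-gene overlap, ~28-node/~82-edge PPI).

- **Compound–target map** (`gen_compound_target_map`). Per-compound
  degrees are Poisson with mean `base_degree_mean = 13` (≈ 237 predicted
  hits / 18 compounds in the real study); planted actives get mean
  `boost × base` with `active_degree_boost = 3`. Target choice is
  weighted: a 12-gene **core** is strongly favored by inactive compounds
  (weight 10) and mildly by actives (weight 5), a 17-gene **fringe** is
  favored by actives (weight 10), and each active additionally owns 3
  **private fringe** targets (round-robin over the fringe) that are
  force-included for it and nearly excluded (weight 0.05) for everyone
  else. The private targets are what make actives *bridges*: without
  them, the five actives share the fringe, each one's betweenness is
  diluted, and the degree-AND-betweenness screen misses one active in
  ~6–7 % of seeds; with them, active recovery is 97–98 % and hub
  recovery 96–97 % over 200 seeds. `boost = 1` (no separation) is
  allowed for null calibration.
- **Disease sources** (`gen_disease_sources`). Planted-overlap genes are
  assigned round-robin across sources (plus extra memberships with
  probability 0.3) with scores drawn above each source's threshold
  (`ScoreModel.low/high`); noise genes come from a disjoint `DGxxxx`
  namespace with scores that may fall below threshold
  (`planted_low`), so the realized overlap is exactly the planted 29.
- **PPI** (`gen_ppi`). Bernoulli edges with base probability
  `edge_prob = 0.09`; pairs touching a planted hub get probability
  p·(1+hub_boost) and hub–hub pairs p·(1+hub_boost)², capped at 1, with
  `hub_boost = 2.8`. With 28 members and 6 hubs this gives E[edges] ≈ 82
  (`expected_ppi_edges` computes it exactly). One overlap gene is held
  out of all edges as the planted free gene.
- **Libraries** (`gen_library`). 50 terms of size 10–40 from the
  universe; one planted term is forced to share `enriched_term_overlap =
  10` genes with the query. `overlap = 0` yields an all-null library for
  calibration.
- **Naming.** The first six core genes are renamed to the real hub
  symbols (OPRM1, PTGS2, ESR1, SLC6A4, DRD2, NR3C1) across every emitted
  artifact, so outputs read like the real study.
- **Reproducibility.** Every stochastic stream uses
  `numpy.random.default_rng((seed·1000003 + offset) mod 2³¹)` with a
  fixed per-stream offset; a single `--seed` determines everything and
  all derived seeds stay below 2³¹.

What the generator emulates: problem sizes, the planted-signal structure
(actives, overlap, hubs, enriched terms), per-source score regimes, the
free-gene and dropped-compound edge cases. What it does not: real
biology — gene identities beyond the six renamed hubs, correlated
annotation structure, literature-derived edge confidence.

## Numerical and statistical choices

- **Betweenness normalization.** 2/((N−1)(N−2)) with N the whole-graph
  node count; this is the convention under which the published 16-row
  table's mean betweenness reproduces to 0.0493519 (printed 0.049353,
  within 2·10⁻⁶ from 5-decimal inputs). The hand-written Brandes
  implementation is tested against both an exhaustive path-enumeration
  oracle and networkx on hundreds of random graphs.
- **Discrete p-values and calibration.** The hypergeometric upper-tail
  p-value is discrete and superuniform under the null, so a KS test of
  the raw p-values against U(0,1) would reject by construction. The
  calibration test therefore uses the standard randomized p-value
  u = P(X > k) + U·P(X = k), which is exactly U(0,1) under the null
  (`randomized_pvalue`), and checks the raw p-values for one-sided
  superuniformity.
- **P_FLOOR.** Reported p-values are floored at 1e-300 before `ln` in
  the combined score to avoid −inf; the stored p-value itself is exact.
- **Tie policies.** Hub ranking: degree descending, alphabetical within
  a degree, full expansion of the tie spanning the k-th place. Screening
  and enrichment outputs are deterministically sorted ((−degree, name)
  and (p, term_id)) so runs are byte-reproducible.
- **Content-sum check.** GC–MS relative contents should total 100 %;
  deviations beyond ±0.5 raise a warning, not an error, since published
  tables round per-row.
- **Degree-sequence realization.** For the measured 16-compound degree
  sequence (total 178) on 29 targets,
  `realize_bipartite_degree_sequence` builds a concrete simple bipartite
  graph greedily (each compound takes the targets with most residual
  capacity, capacities near-uniform), reproducing the published 45-node
  network arithmetic.

## Limitations

- The synthetic generator plants independence where real databases have
  heavy correlation (shared annotation pipelines, literature bias);
  recovery rates on synthetic data say nothing about real-data accuracy.
- ORA treats genes as exchangeable; no gene-length or expression
  background correction.
- The PPI model is Bernoulli, not degree-corrected; it matches expected
  edge count and hub separation only.
- The measured-table results are only as precise as the 5-decimal
  published inputs (hence the 2·10⁻⁶ tolerance on mean betweenness).
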