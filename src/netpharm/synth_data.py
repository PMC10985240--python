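"""Synthetic study inputs with planted ground truth.

Network-pharmacology studies consume web-service exports (ligand-based
target prediction, disease-gene databases, STRING PPI, GO/KEGG/Wiki
libraries) that are rarely deposited. This module generates every upstream
input from seeded random models with *planted* structure — a known set of
active compounds, a known compound/disease gene overlap, known PPI hubs and
a known enriched term — so the full pipeline can be exercised and its
recovery of the planted truth measured, with no downloads.

Compound–target model: every compound draws a Poisson number of targets;
most compounds sample mainly from a small *shared core* of genes, while
planted active compounds draw a boosted degree and preferentially reach an
*active fringe* of genes that other compounds rarely touch. The core models
the promiscuous, well-annotated receptors every terpene-like compound is
predicted to hit; the fringe gives actives both higher degree and higher
betweenness (they bridge the fringe to the core), which is the structure
the topological screen is designed to detect.

One global seed derives per-stream sub-seeds by fixed offsets, so each
stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import CBEO_ACTIVE_COMPOUNDS, CBEO_HUB_GENES, load_cbeo_contents
from .io_formats import EdgeList, GeneSet, GeneSetLibrary, write_edge_list, write_gmt
from .target_sets import CompoundTargetMap, SourceFilter, merge_compound_targets

_STREAM_OFFSETS = {
    "compound_map": 11,
    "disease": 23,
    "ppi": 37,
    "library": 41,
    "scores": 53,
}


class GeneratorError(ValueError):
    """Generator parameters outside their valid ranges."""


def _stream_rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    """Per-stream RNG derived from the global seed by a fixed offset."""
    offset = _STREAM_OFFSETS[stream] + extra
    return np.random.default_rng((int(seed) * 1000003 + offset) % (2**31))


@dataclass
class SyntheticTruth:
    """What the generator planted, recorded for later recovery checks."""

    seed: int
    planted_active_compounds: set[str] = field(default_factory=set)
    planted_overlap: set[str] = field(default_factory=set)
    planted_hubs: set[str] = field(default_factory=set)
    planted_enriched_terms: set[str] = field(default_factory=set)
    generator_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        for key in (
            "planted_active_compounds",
            "planted_overlap",
            "planted_hubs",
            "planted_enriched_terms",
        ):
            payload[key] = sorted(payload[key])
        Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False, default=sorted))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            planted_active_compounds=set(payload["planted_active_compounds"]),
            planted_overlap=set(payload["planted_overlap"]),
            planted_hubs=set(payload["planted_hubs"]),
            planted_enriched_terms=set(payload["planted_enriched_terms"]),
            generator_params=payload["generator_params"],
        )


# ---------------------------------------------------------------------------
# Compound → target predictions
# ---------------------------------------------------------------------------

def gen_compound_target_map(
    n_compounds: int = 18,
    n_targets: int = 121,
    base_degree_mean: float = 13.0,
    active_set: Sequence[str] = (),
    active_degree_boost: float = 3.0,
    seed: int = 0,
    compound_names: Sequence[str] | None = None,
    core_size: int = 12,
    fringe_size: int = 17,
    inactive_core_weight: float = 10.0,
    active_fringe_weight: float = 10.0,
    active_core_weight: float = 5.0,
    private_fringe_per_active: int = 3,
) -> tuple[CompoundTargetMap, SyntheticTruth]:
    """Simulate per-compound predicted-target lists.

    Per-compound hit counts are Poisson(``base_degree_mean``), boosted by
    ``active_degree_boost`` for compounds in ``active_set``. The first
    ``core_size`` targets form the shared core (over-weighted for every
    compound), the next ``fringe_size`` the active fringe (over-weighted
    for actives only). In addition each active compound is guaranteed
    ``private_fringe_per_active`` fringe targets of its own, assigned
    round-robin: real active ingredients typically carry pharmacology the
    bulk compounds lack, and these private targets are what gives actives
    their betweenness signature (they bridge otherwise-peripheral genes
    into the shared core). Prediction scores are Uniform(0, 1].
    """
    if n_compounds < 1 or n_targets < 1:
        raise GeneratorError("need at least one compound and one target")
    if base_degree_mean <= 0:
        raise GeneratorError("base_degree_mean must be positive")
    if active_degree_boost < 1:
        raise GeneratorError("active_degree_boost must be >= 1")
    if core_size + fringe_size > n_targets:
        raise GeneratorError("core + fringe exceed the target pool")
    if compound_names is None:
        compound_names = [f"compound{i + 1:02d}" for i in range(n_compounds)]
    if len(compound_names) != n_compounds:
        raise GeneratorError("compound_names length does not match n_compounds")
    active_set = set(active_set)
    if not active_set <= set(compound_names):
        raise GeneratorError("active_set must be a subset of the compound names")

    targets = np.array([f"TG{i + 1:03d}" for i in range(n_targets)])
    core = list(targets[:core_size])
    fringe = list(targets[core_size:core_size + fringe_size])

    # round-robin private fringe assignment for the planted actives
    actives_ordered = [n for n in compound_names if n in active_set]
    private: dict[str, list[str]] = {n: [] for n in actives_ordered}
    if actives_ordered and private_fringe_per_active > 0:
        slots = fringe[: len(actives_ordered) * private_fringe_per_active]
        for i, gene in enumerate(slots):
            private[actives_ordered[i % len(actives_ordered)]].append(gene)

    rng = _stream_rng(seed, "compound_map")
    rows: list[tuple[str, str, float]] = []
    for name in compound_names:
        is_active = name in active_set
        lam = base_degree_mean * (active_degree_boost if is_active else 1.0)
        k = int(np.clip(rng.poisson(lam), 1, n_targets))
        weights = np.ones(n_targets)
        if is_active:
            weights[:core_size] = active_core_weight
            weights[core_size:core_size + fringe_size] = active_fringe_weight
        else:
            weights[:core_size] = inactive_core_weight
            # private fringe genes stay (nearly) exclusive to their active
            for genes in private.values():
                for g in genes:
                    weights[int(np.flatnonzero(targets == g)[0])] = 0.05
        probs = weights / weights.sum()
        chosen = set(rng.choice(targets, size=k, replace=False, p=probs))
        if is_active:
            chosen |= set(private[name])
        for gene in sorted(chosen):
            score = float(1.0 - rng.random())  # Uniform(0, 1]
            rows.append((name, gene, score))

    cmap = merge_compound_targets(rows)
    truth = SyntheticTruth(
        seed=seed,
        planted_active_compounds=set(active_set),
        generator_params={
            "n_compounds": n_compounds,
            "n_targets": n_targets,
            "base_degree_mean": base_degree_mean,
            "active_degree_boost": active_degree_boost,
            "core": core,
            "fringe": fringe,
            "private_fringe": private,
            "n_prediction_rows": len(rows),
        },
    )
    return cmap, truth


# ---------------------------------------------------------------------------
# Disease sources
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreModel:
    """Uniform score model: noise in [low, high), planted in [planted_low, high)."""

    low: float
    high: float
    planted_low: float


def gen_disease_sources(
    sizes: Sequence[int],
    target_pool: Sequence[str],
    planted_overlap: Sequence[str],
    score_models: Sequence[ScoreModel | None],
    seed: int = 0,
    source_names: Sequence[str] | None = None,
    noise_pool_size: int = 600,
    extra_membership_prob: float = 0.3,
) -> list[tuple[str, pd.DataFrame]]:
    """Simulate disease-gene database exports.

    Each planted gene is assigned to one source round-robin and joins the
    others with probability ``extra_membership_prob``; remaining slots are
    filled with noise genes (drawn from a shared noise pool disjoint from
    the compound target pool, so the planted overlap stays exact). Scores
    for planted genes are drawn from the passing region of the model, so
    the downstream threshold filters retain all of them.
    """
    n_sources = len(sizes)
    if source_names is None:
        source_names = [f"source{i + 1}" for i in range(n_sources)]
    if len(score_models) != n_sources or len(source_names) != n_sources:
        raise GeneratorError("sizes, score_models and source_names must align")
    planted = list(planted_overlap)
    if not set(planted) <= set(target_pool):
        raise GeneratorError("planted_overlap must be drawn from the target pool")

    rng = _stream_rng(seed, "disease")
    membership: dict[str, set[str]] = {name: set() for name in source_names}
    for i, gene in enumerate(planted):
        membership[source_names[i % n_sources]].add(gene)
        for name in source_names:
            if gene not in membership[name] and rng.random() < extra_membership_prob:
                membership[name].add(gene)
    for name, size in zip(source_names, sizes):
        if size < len(membership[name]):
            raise GeneratorError(
                f"source {name!r} size {size} smaller than its planted share "
                f"{len(membership[name])}"
            )

    noise_pool = np.array([f"DG{i + 1:04d}" for i in range(noise_pool_size)])
    sources: list[tuple[str, pd.DataFrame]] = []
    for name, size, model in zip(source_names, sizes, score_models):
        own_planted = sorted(membership[name])
        n_noise = size - len(own_planted)
        noise = list(rng.choice(noise_pool, size=min(n_noise, noise_pool_size), replace=False))
        genes = own_planted + noise
        if model is None:
            frame = pd.DataFrame({"gene": genes})
        else:
            scores = [float(rng.uniform(model.planted_low, model.high)) for _ in own_planted]
            scores += [float(rng.uniform(model.low, model.high)) for _ in noise]
            frame = pd.DataFrame({"gene": genes, "score": scores})
        sources.append((name, frame))
    return sources


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def gen_ppi(
    members: Sequence[str],
    edge_prob: float = 0.09,
    hub_set: Sequence[str] = (),
    hub_boost: float = 2.8,
    seed: int = 0,
) -> EdgeList:
    """Simulate a STRING-style PPI export over the candidate genes.

    Background edges are Erdős–Rényi at ``edge_prob``; pairs touching a
    planted hub use probability ``edge_prob × (1 + hub_boost)`` (squared
    for hub–hub pairs, capped at 1), so hubs carry clearly higher degree.
    ``hub_boost = 0`` reduces hubs to background.
    """
    if not (0 < edge_prob < 1):
        raise GeneratorError("edge_prob must lie in (0, 1)")
    if hub_boost < 0:
        raise GeneratorError("hub_boost must be non-negative")
    members = list(members)
    hubs = set(hub_set)
    if not hubs <= set(members):
        raise GeneratorError("hub_set must be a subset of members")
    rng = _stream_rng(seed, "ppi")
    factor = 1.0 + hub_boost
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            n_hub_ends = (a in hubs) + (b in hubs)
            p = min(1.0, edge_prob * factor**n_hub_ends)
            if rng.random() < p:
                pairs.append((a, b))
    return EdgeList.from_pairs(pairs)


def expected_ppi_edges(
    n_members: int, n_hubs: int, edge_prob: float = 0.09, hub_boost: float = 2.8
) -> float:
    """Analytic expectation of the edge count under ``gen_ppi``'s model."""
    factor = 1.0 + hub_boost
    n_nonhub = n_members - n_hubs
    p_hh = min(1.0, edge_prob * factor**2)
    p_hn = min(1.0, edge_prob * factor)
    n_hh = n_hubs * (n_hubs - 1) / 2
    n_hn = n_hubs * n_nonhub
    n_nn = n_nonhub * (n_nonhub - 1) / 2
    return n_hh * p_hh + n_hn * p_hn + n_nn * edge_prob


# ---------------------------------------------------------------------------
# Gene-set libraries
# ---------------------------------------------------------------------------

def gen_library(
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 40),
    universe: Sequence[str] = (),
    enriched_term_overlap: int = 10,
    query: Sequence[str] = (),
    seed: int = 0,
    name: str = "synthetic",
) -> tuple[GeneSetLibrary, str]:
    """Simulate a GMT library with one planted enriched term.

    A randomly positioned term absorbs ``enriched_term_overlap`` genes of
    the query (its remaining genes, like every null term's, are sampled
    uniformly from the universe). Returns the library and the planted
    term's id. ``enriched_term_overlap = 0`` plants nothing (an all-null
    library for calibration runs).
    """
    universe = np.array(sorted(set(universe)))
    query = sorted(set(query))
    if len(universe) == 0:
        raise GeneratorError("universe must be non-empty")
    if not set(query) <= set(universe):
        raise GeneratorError("query must be a subset of the universe")
    if enriched_term_overlap > len(query):
        raise GeneratorError("enriched overlap exceeds the query size")
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise GeneratorError("term_size_range outside the universe size")
    rng = _stream_rng(seed, "library")
    planted_idx = int(rng.integers(n_terms)) if enriched_term_overlap > 0 else -1
    terms: list[GeneSet] = []
    planted_id = ""
    for i in range(n_terms):
        term_id = f"{name.upper()}{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i == planted_idx:
            planted_id = term_id
            absorbed = list(rng.choice(np.array(query), size=enriched_term_overlap, replace=False))
            rest_pool = np.array([g for g in universe if g not in set(absorbed)])
            n_rest = max(0, size - enriched_term_overlap)
            rest = list(rng.choice(rest_pool, size=n_rest, replace=False))
            genes = absorbed + rest
        else:
            genes = list(rng.choice(universe, size=size, replace=False))
        terms.append(GeneSet(term_id, f"synthetic term {i + 1}", frozenset(genes)))
    return GeneSetLibrary(name, terms), planted_id


# ---------------------------------------------------------------------------
# The study-scale preset
# ---------------------------------------------------------------------------

#: Source sizes mirroring typical disease-database exports at study scale.
PRESET_SOURCE_SIZES = (82, 260, 29, 376)
PRESET_SOURCE_NAMES = ("genecards", "disgenet", "ttd", "omim")
PRESET_SCORE_MODELS: tuple[ScoreModel | None, ...] = (
    ScoreModel(low=0.0, high=30.0, planted_low=12.0),   # relevance-score style, filter >= 10
    ScoreModel(low=0.0, high=1.0, planted_low=0.35),    # gene-disease score style, filter >= 0.3
    None,                                               # curated source, taken whole
    None,                                               # curated source, taken whole
)
PRESET_FILTERS = {
    "genecards": SourceFilter("score", 10.0, "ge"),
    "disgenet": SourceFilter("score", 0.3, "ge"),
}

#: Compounds given no overlap targets so they drop out of the drawn network.
PRESET_DISCONNECTED = ("Cyclohexane", "Methylcyclopentane")


@dataclass
class SyntheticStudy:
    """A full set of generated inputs plus the planted truth."""

    compound_rows: list[tuple[str, str, float]]
    compound_map: CompoundTargetMap
    disease_sources: list[tuple[str, pd.DataFrame]]
    filters: dict[str, SourceFilter]
    ppi_edges: EdgeList
    libraries: list[GeneSetLibrary]
    planted_term_ids: dict[str, str]
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> None:
        """Emit every input in the dialect the readers expect, plus truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.compound_rows, columns=["compound", "gene", "score"]).to_csv(
            out / "compound_targets.tsv", sep="\t", index=False
        )
        for name, frame in self.disease_sources:
            frame.to_csv(out / f"disease_{name}.tsv", sep="\t", index=False)
        write_edge_list(self.ppi_edges, out / "ppi_edges.tsv", dialect="tsv")
        for lib in self.libraries:
            write_gmt(lib, out / f"{lib.name}.gmt")
        self.truth.to_json(out / "truth.json")


def generate_study(seed: int = 0, enriched_term_overlap: int = 10) -> SyntheticStudy:
    """Generate a full study-scale input set with planted truth.

    Scales mirror the reference study: 18 compounds (the packaged GC–MS
    names) hitting a 121-gene target pool, four disease sources sized
    (82, 260, 29, 376) with threshold filters on the first two, a planted
    29-gene overlap, a 28-member PPI (one overlap gene left free) with six
    planted hubs, and three 50-term gene-set libraries each planting one
    enriched term over the overlap query.
    """
    table = load_cbeo_contents()
    names = table.names

    # compound → target predictions, with 2 compounds kept off the overlap
    cmap, truth = gen_compound_target_map(
        n_compounds=len(names),
        active_set=list(CBEO_ACTIVE_COMPOUNDS),
        seed=seed,
        compound_names=names,
    )
    core: list[str] = truth.generator_params["core"]
    fringe: list[str] = truth.generator_params["fringe"]
    overlap = core + fringe  # 29 genes

    # detach the designated compounds from the overlap so the drawn
    # network keeps 16 of 18 compounds, as GC-MS trace compounds often do
    overlap_set = set(overlap)
    rows = [
        (r.compound, r.gene, float(r.score))
        for r in cmap.provenance.itertuples()
        if not (r.compound in PRESET_DISCONNECTED and r.gene in overlap_set)
    ]
    for name in PRESET_DISCONNECTED:
        if all(r[0] != name for r in rows):  # keep the compound present off-overlap
            rows.append((name, "TG121", 0.5))
    cmap = merge_compound_targets(rows)
    truth.planted_overlap = set(overlap)
    truth.generator_params["disconnected_compounds"] = list(PRESET_DISCONNECTED)

    sources = gen_disease_sources(
        sizes=PRESET_SOURCE_SIZES,
        target_pool=[f"TG{i + 1:03d}" for i in range(121)],
        planted_overlap=overlap,
        score_models=PRESET_SCORE_MODELS,
        seed=seed,
        source_names=PRESET_SOURCE_NAMES,
    )

    hubs = list(CBEO_HUB_GENES)
    # planted hubs take over six core gene identities so downstream tables
    # carry recognizable symbols; rename consistently everywhere
    rename = dict(zip(core[:6], hubs))
    overlap = [rename.get(g, g) for g in overlap]
    rows = [(c, rename.get(g, g), s) for (c, g, s) in rows]
    cmap = merge_compound_targets(rows)
    truth.planted_overlap = set(overlap)
    truth.planted_hubs = set(hubs)
    sources = [
        (name, frame.assign(gene=[rename.get(g, g) for g in frame["gene"]]))
        for name, frame in sources
    ]

    free_gene = overlap[-1]  # one overlap gene left out of the PPI export
    ppi = gen_ppi(
        members=[g for g in overlap if g != free_gene],
        hub_set=hubs,
        seed=seed,
    )
    truth.generator_params["ppi_free_gene"] = free_gene

    universe = sorted(set(overlap) | {f"DG{i + 1:04d}" for i in range(600)})
    libraries: list[GeneSetLibrary] = []
    planted_terms: dict[str, str] = {}
    for offset, lib_name in enumerate(("go_synth", "kegg_synth", "wiki_synth")):
        lib, planted_id = gen_library(
            universe=universe,
            enriched_term_overlap=enriched_term_overlap,
            query=overlap,
            seed=seed + 7919 * (offset + 1),
            name=lib_name,
        )
        libraries.append(lib)
        planted_terms[lib_name] = planted_id
    truth.planted_enriched_terms = {t for t in planted_terms.values() if t}

    return SyntheticStudy(
        compound_rows=rows,
        compound_map=cmap,
        disease_sources=sources,
        filters=dict(PRESET_FILTERS),
        ppi_edges=ppi,
        libraries=libraries,
        planted_term_ids=planted_terms,
        truth=truth,
    )
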