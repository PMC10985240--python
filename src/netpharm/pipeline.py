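"""End-to-end orchestration: targets → network → screening → hubs →
enrichment → mixture, as one configured, logged run producing a single
report directory of TSV tables plus a structured run summary.

Every stage's dedup/drop counts are logged into the summary so headline
numbers (unique targets, overlap size, node/edge counts) stay traceable to
the merges that produced them. An empty compound/disease overlap is a
defined terminal state, not a crash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment as enrich_mod
from . import mixture as mix_mod
from .io_formats import read_compound_table, read_edge_list, read_gmt
from .network_topology import (
    build_bipartite,
    build_ppi,
    export_network,
    rank_hubs,
    screen_compounds,
    topology_records,
)
from .target_sets import (
    SourceFilter,
    intersect,
    merge_compound_targets,
    merge_disease_targets,
    read_disease_source,
)

logger = logging.getLogger(__name__)

STATUS_COMPLETE = "complete"
STATUS_NO_SHARED_TARGETS = "no shared targets"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    compound_table: str
    compound_targets: str
    disease_sources: dict[str, str]  # source name -> path
    ppi_edges: str
    gmt_libraries: list[str]
    out_dir: str
    filters: dict[str, SourceFilter] = field(default_factory=dict)
    comparator: str = "gt"
    k_hubs: int = 6
    alpha: float = 0.05
    universe: str | None = None  # optional background gene list (one per line)
    reference_compound: str | None = None
    override_ratio: list[float] | None = None
    dose_mg_per_kg: float = 12.5
    body_mass_kg: float = 0.028
    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["filters"] = {
            k: {"score_field": f.score_field, "threshold": f.threshold, "comparator": f.comparator}
            for k, f in self.filters.items()
        }
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload["filters"] = {
            k: SourceFilter(v["score_field"], v["threshold"], v.get("comparator", "ge"))
            for k, v in payload.get("filters", {}).items()
        }
        return cls(**payload)


@dataclass
class RunReport:
    status: str
    config: dict
    input_hashes: dict[str, str]
    per_source_counts: dict[str, int] = field(default_factory=dict)
    n_unique_compound_targets: int = 0
    n_merged_disease_targets: int = 0
    overlap_size: int = 0
    network_nodes: int = 0
    network_edges: int = 0
    topology: pd.DataFrame | None = None
    mean_degree: float = 0.0
    mean_betweenness: float = 0.0
    selected_compounds: list[str] = field(default_factory=list)
    ppi_summary: dict = field(default_factory=dict)
    hubs: list[tuple[str, int]] = field(default_factory=list)
    enrichment_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    mixture_recipe: pd.DataFrame | None = None

    def summary_dict(self) -> dict:
        return {
            "status": self.status,
            "config": self.config,
            "input_hashes": self.input_hashes,
            "per_source_counts": self.per_source_counts,
            "n_unique_compound_targets": self.n_unique_compound_targets,
            "n_merged_disease_targets": self.n_merged_disease_targets,
            "overlap_size": self.overlap_size,
            "network_nodes": self.network_nodes,
            "network_edges": self.network_edges,
            "mean_degree": self.mean_degree,
            "mean_betweenness": self.mean_betweenness,
            "selected_compounds": self.selected_compounds,
            "ppi_summary": self.ppi_summary,
            "hubs": [[g, d] for g, d in self.hubs],
        }


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run(config: RunConfig) -> RunReport:
    """Execute the full screening pipeline and write its report.

    Stages run in order; any failure raises :class:`StageError` naming the
    stage. An empty overlap terminates the run with status
    ``"no shared targets"`` and no downstream sections.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {
        "compound_table": config.compound_table,
        "compound_targets": config.compound_targets,
        "ppi_edges": config.ppi_edges,
        **{f"disease:{k}": v for k, v in config.disease_sources.items()},
        **{f"gmt:{i}": p for i, p in enumerate(config.gmt_libraries)},
    }
    hashes = {k: _sha256(v) for k, v in inputs.items()}
    report = RunReport(status=STATUS_COMPLETE, config=config.to_dict(), input_hashes=hashes)

    # ---- stage: targets -------------------------------------------------
    try:
        table = read_compound_table(config.compound_table)
        pred = pd.read_csv(config.compound_targets, sep="\t")
        cmap = merge_compound_targets(
            [(r.compound, r.gene, float(r.score)) for r in pred.itertuples()],
            compound_table=table,
        )
        sources = [
            (name, read_disease_source(path)) for name, path in config.disease_sources.items()
        ]
        disease = merge_disease_targets(sources, config.filters)
        overlap = intersect(cmap, disease)
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise StageError("targets", exc) from exc
    report.per_source_counts = disease.counts()
    report.n_unique_compound_targets = cmap.n_unique_targets
    report.n_merged_disease_targets = len(disease.merged)
    report.overlap_size = len(overlap.intersection)
    pd.DataFrame(
        {"section": ["unique_compound_targets", "merged_disease_targets", "overlap"],
         "count": [cmap.n_unique_targets, len(disease.merged), len(overlap.intersection)]}
    ).to_csv(out / "target_counts.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(overlap.intersection), columns=["gene"]).to_csv(
        out / "overlap_genes.tsv", sep="\t", index=False
    )

    if overlap.is_empty:
        report.status = STATUS_NO_SHARED_TARGETS
        _write_summary(report, out)
        logger.warning("terminal: no shared targets between compounds and disease")
        return report

    # ---- stage: network -------------------------------------------------
    try:
        network = build_bipartite(overlap, cmap)
        records = topology_records(network, side="compound")
        screening = screen_compounds(records, comparator=config.comparator)
        export_network(network, out / "network.sif", out / "network_attributes.tsv")
    except Exception as exc:
        raise StageError("network", exc) from exc
    report.network_nodes = network.n_nodes
    report.network_edges = network.n_edges
    report.topology = pd.DataFrame(
        {"compound": [r.node for r in records],
         "betweenness": [r.betweenness for r in records],
         "degree": [r.degree for r in records]}
    )
    report.topology.to_csv(out / "compound_topology.tsv", sep="\t", index=False)
    report.mean_degree = screening.mean_degree
    report.mean_betweenness = screening.mean_betweenness
    report.selected_compounds = screening.selected

    # ---- stage: ppi ------------------------------------------------------
    try:
        edges = read_edge_list(config.ppi_edges, dialect="tsv")
        ppi = build_ppi(edges, overlap.intersection)
        hubs = rank_hubs(ppi, k=config.k_hubs) if ppi.nodes else []
    except Exception as exc:
        raise StageError("ppi", exc) from exc
    report.ppi_summary = {
        "n_nodes": ppi.n_nodes,
        "n_edges": ppi.n_edges,
        "mean_degree": ppi.mean_degree,
        "excluded_free_nodes": sorted(ppi.excluded_free_nodes),
    }
    report.hubs = hubs
    pd.DataFrame(hubs, columns=["gene", "degree"]).to_csv(
        out / "hub_genes.tsv", sep="\t", index=False
    )

    # ---- stage: enrichment ----------------------------------------------
    try:
        universe = None
        if config.universe:
            universe = {
                g.strip().upper()
                for g in Path(config.universe).read_text().splitlines()
                if g.strip()
            }
        for i, gmt_path in enumerate(config.gmt_libraries):
            library = read_gmt(gmt_path)
            results = enrich_mod.enrich(
                overlap.intersection, library, universe=universe,
                rng=config.seed + i,
            )
            frame = enrich_mod.results_table(results)
            report.enrichment_tables[library.name] = frame
            frame.to_csv(out / f"enrichment_{library.name}.tsv", sep="\t", index=False)
            enrich_mod.bubble_data(results).to_csv(
                out / f"bubble_{library.name}.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise StageError("enrichment", exc) from exc

    # ---- stage: mixture --------------------------------------------------
    try:
        if screening.selected:
            spec = mix_mod.compute_ratio(
                screening.selected, table, reference=config.reference_compound
            )
            masses = dict(
                mix_mod.component_masses(spec, config.dose_mg_per_kg, config.body_mass_kg)
            )
            recipe = spec.to_frame()
            recipe["mass_per_dose_mg"] = [masses[c] for c in recipe["compound"]]
            if config.override_ratio:
                override = mix_mod.spec_from_ratio(screening.selected, config.override_ratio)
                mix_mod.diff_ratios(spec, override).to_csv(
                    out / "mixture_ratio_diff.tsv", sep="\t", index=False
                )
            report.mixture_recipe = recipe
            recipe.to_csv(out / "mixture_recipe.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("mixture", exc) from exc

    _write_summary(report, out)
    return report


def _write_summary(report: RunReport, out: Path) -> None:
    (out / "run_summary.json").write_text(
        json.dumps(report.summary_dict(), indent=2, ensure_ascii=False) + "\n"
    )
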