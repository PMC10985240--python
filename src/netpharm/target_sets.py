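"""Merging predicted compound targets and multi-source disease gene sets.

Per-compound target predictions (SwissTargetPrediction-style rows of
``compound, gene, score``) are deduplicated under a ``score > 0`` retention
rule. Disease gene sets from several databases are filtered by
source-specific score thresholds (inclusive by default, e.g. GeneCards
relevance ≥ 10 and DisGeNET score ≥ 0.3), unioned, and intersected with the
compound-side union — the Venn step that defines the candidate genes the
downstream networks are built on. Gene identity is the bare upper-cased
symbol string; no alias resolution is attempted so counts stay reproducible.
"""

from __future__ import annotations

import logging
import operator
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import CompoundTable, canonical_compound, canonical_gene

logger = logging.getLogger(__name__)

_COMPARATORS = {"ge": operator.ge, "gt": operator.gt, "le": operator.le, "lt": operator.lt}


class ConfigurationError(ValueError):
    """A filter or option references something that does not exist."""


@dataclass
class CompoundTargetMap:
    """Predicted targets per compound, with provenance scores.

    ``entries`` maps compound name to its set of gene symbols. Only
    predictions with score strictly greater than zero are retained.
    """

    entries: dict[str, set[str]]
    provenance: pd.DataFrame  # columns: compound, gene, score
    n_dropped_zero_score: int = 0
    n_duplicate_rows: int = 0

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.entries.values():
            out |= genes
        return out

    @property
    def n_unique_targets(self) -> int:
        return len(self.union)

    def degree(self, compound: str) -> int:
        return len(self.entries[compound])


def merge_compound_targets(
    rows: Iterable[tuple[str, str, float]],
    compound_table: CompoundTable | None = None,
    unknown_compound: str = "warn",
) -> CompoundTargetMap:
    """Deduplicate per-compound predicted targets.

    Parameters
    ----------
    rows
        ``(compound, gene, score)`` triples with scores in [0, 1].
    compound_table
        When given, compounds absent from the table are rejected or kept
        with a warning according to ``unknown_compound`` (``"reject"`` or
        ``"warn"``).
    """
    if unknown_compound not in ("warn", "reject"):
        raise ConfigurationError(f"unknown_compound must be warn|reject, got {unknown_compound!r}")
    known = (
        {canonical_compound(n) for n in compound_table.names}
        if compound_table is not None
        else None
    )
    entries: dict[str, set[str]] = {}
    kept_rows: list[tuple[str, str, float]] = []
    n_zero = n_dup = 0
    seen_pairs: set[tuple[str, str]] = set()
    for compound, gene, score in rows:
        compound = compound.strip()
        score = float(score)
        if not (0 <= score <= 1):
            raise ValueError(f"prediction score {score} for {compound!r}/{gene!r} outside [0, 1]")
        if known is not None and canonical_compound(compound) not in known:
            msg = f"compound {compound!r} not in the run's compound table"
            if unknown_compound == "reject":
                raise ConfigurationError(msg)
            warnings.warn(msg, stacklevel=2)
        entries.setdefault(compound, set())
        if score <= 0:  # "probability > 0" retention rule
            n_zero += 1
            continue
        symbol = canonical_gene(gene)
        pair = (canonical_compound(compound), symbol)
        if pair in seen_pairs:
            n_dup += 1
            continue
        seen_pairs.add(pair)
        entries[compound].add(symbol)
        kept_rows.append((compound, symbol, score))
    provenance = pd.DataFrame(kept_rows, columns=["compound", "gene", "score"])
    logger.info(
        "merged %d prediction rows -> %d unique targets "
        "(%d zero-score dropped, %d duplicates collapsed)",
        len(kept_rows) + n_zero + n_dup,
        len({g for s in entries.values() for g in s}),
        n_zero,
        n_dup,
    )
    return CompoundTargetMap(entries, provenance, n_zero, n_dup)


@dataclass(frozen=True)
class SourceFilter:
    """Inclusion rule for one disease-database export."""

    score_field: str
    threshold: float
    comparator: str = "ge"

    def passes(self, value: float) -> bool:
        return _COMPARATORS[self.comparator](value, self.threshold)


@dataclass
class DiseaseTargetSet:
    per_source: dict[str, set[str]]
    filters: dict[str, SourceFilter] = field(default_factory=dict)

    @property
    def merged(self) -> set[str]:
        out: set[str] = set()
        for genes in self.per_source.values():
            out |= genes
        return out

    def counts(self) -> dict[str, int]:
        return {src: len(genes) for src, genes in self.per_source.items()}


def merge_disease_targets(
    sources: Sequence[tuple[str, pd.DataFrame]],
    filters: Mapping[str, SourceFilter] | None = None,
) -> DiseaseTargetSet:
    """Filter each source by its score rule and union the survivors.

    Each source is a ``(name, frame)`` pair where the frame has a ``gene``
    column and, for filtered sources, the filter's score column. Sources
    without a filter are taken whole.
    """
    filters = dict(filters or {})
    per_source: dict[str, set[str]] = {}
    for name, frame in sources:
        if "gene" not in frame.columns:
            raise ConfigurationError(f"source {name!r}: no 'gene' column")
        flt = filters.get(name)
        if flt is None:
            kept = frame
        else:
            if flt.score_field not in frame.columns:
                raise ConfigurationError(
                    f"source {name!r}: filter references absent column {flt.score_field!r}"
                )
            mask = frame[flt.score_field].astype(float).map(flt.passes)
            kept = frame[mask]
        per_source[name] = {canonical_gene(g) for g in kept["gene"]}
        logger.info("source %s: %d/%d genes pass filter", name, len(per_source[name]), len(frame))
    return DiseaseTargetSet(per_source, filters)


def read_disease_source(path: str | Path) -> pd.DataFrame:
    """Read one disease-database export: TSV with header ``gene[\\tscore]``."""
    frame = pd.read_csv(path, sep="\t")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "gene" not in frame.columns:
        raise ConfigurationError(f"{path}: no 'gene' column in header")
    return frame


@dataclass
class OverlapResult:
    """Intersection of compound-side and disease-side gene sets."""

    compound_side: set[str]
    disease_side: set[str]

    @property
    def intersection(self) -> set[str]:
        return self.compound_side & self.disease_side

    @property
    def is_empty(self) -> bool:
        return not self.intersection

    @property
    def status(self) -> str:
        return "no shared targets" if self.is_empty else "ok"


def intersect(compound_map: CompoundTargetMap, disease: DiseaseTargetSet) -> OverlapResult:
    """Compute the Venn overlap of predicted and disease-associated genes."""
    compound_side = compound_map.union
    disease_side = disease.merged
    if not compound_side or not disease_side:
        raise ValueError("both compound-side and disease-side gene sets must be non-empty")
    result = OverlapResult(compound_side, disease_side)
    logger.info(
        "overlap: %d compound-side ∩ %d disease-side = %d shared",
        len(compound_side), len(disease_side), len(result.intersection),
    )
    return result
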