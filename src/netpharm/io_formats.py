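"""Readers and writers for every external file the pipeline touches.

All formats are plain text: CSV/TSV compound tables (GC–MS composition
exports), GMT gene-set libraries, and TSV/SIF edge lists of the kind
exchanged with Cytoscape or exported from STRING. Gene symbols are
upper-cased at ingest so that sources with mixed HGNC casing compare
equal; duplicate undirected edges are collapsed on load and the collapse
is counted so deduplication stays auditable.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Acceptable half-width of the band around 100% for relative-content sums.
CONTENT_SUM_TOLERANCE = 0.5


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def canonical_compound(name: str) -> str:
    """Canonical form used for *comparison only*: trimmed and case-folded."""
    return name.strip().casefold()


def canonical_gene(symbol: str) -> str:
    """Gene symbols are compared upper-cased (sources mix HGNC casing)."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Compound tables (GC–MS relative contents)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    name: str
    retention_time: float  # minutes
    relative_content: float  # percent, in (0, 100]


@dataclass
class CompoundTable:
    """GC–MS compound records with peak-area relative contents.

    Invariants: compound names are unique after canonicalization, and the
    relative contents are expected to sum to 100 ± 0.5 (a warning, not an
    error, since trace compounds may be omitted upstream).
    """

    rows: list[CompoundRecord]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for row in self.rows:
            key = canonical_compound(row.name)
            if key in seen:
                raise FormatError(
                    f"duplicate compound name {row.name!r} "
                    f"(collides with {seen[key]!r} after canonicalization)"
                )
            seen[key] = row.name
            if row.retention_time < 0:
                raise FormatError(f"negative retention time for {row.name!r}")
            if not (0 < row.relative_content <= 100):
                raise FormatError(
                    f"relative content {row.relative_content} for {row.name!r} "
                    "outside (0, 100]"
                )
        total = self.content_sum()
        if self.rows and abs(total - 100.0) > CONTENT_SUM_TOLERANCE:
            warnings.warn(
                f"relative contents sum to {total:.3f}%, outside "
                f"100 ± {CONTENT_SUM_TOLERANCE}",
                stacklevel=2,
            )

    def content_sum(self) -> float:
        return float(sum(r.relative_content for r in self.rows))

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rows]

    def content(self, compound: str) -> float:
        key = canonical_compound(compound)
        for row in self.rows:
            if canonical_compound(row.name) == key:
                return row.relative_content
        raise KeyError(compound)

    def __contains__(self, compound: str) -> bool:
        key = canonical_compound(compound)
        return any(canonical_compound(r.name) == key for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)


_DEFAULT_HEADER_HINTS = {
    "compound": ("compound", "name", "component"),
    "rt": ("rt", "retention"),
    "content": ("content", "relative", "area", "percent"),
}


def _resolve_columns(
    header: Sequence[str], header_map: Mapping[str, str] | None
) -> dict[str, int]:
    """Map the roles compound/rt/content onto header positions."""
    lowered = [h.strip().lower() for h in header]
    resolved: dict[str, int] = {}
    for role in ("compound", "rt", "content"):
        if header_map and role in header_map:
            target = header_map[role].strip().lower()
            if target not in lowered:
                raise FormatError(f"mapped column {header_map[role]!r} not in header")
            resolved[role] = lowered.index(target)
            continue
        for idx, col in enumerate(lowered):
            if any(h in col for h in _DEFAULT_HEADER_HINTS[role]) and idx not in resolved.values():
                resolved[role] = idx
                break
        else:
            raise FormatError(f"missing mandatory column for {role!r} in header {header!r}")
    return resolved


def read_compound_table(
    path: str | Path, header_map: Mapping[str, str] | None = None
) -> CompoundTable:
    """Read a tab- or comma-separated GC–MS compound table.

    The header must name compound, retention-time and content columns
    (fuzzy-matched by default, overridable via ``header_map`` with keys
    ``compound``, ``rt``, ``content``). Rows are returned in file order.
    """
    text = Path(path).read_text(encoding="utf-8")
    # newline normalization so \r\n inputs parse identically
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delimiter)
    header = next(reader)
    cols = _resolve_columns(header, header_map)
    rows: list[CompoundRecord] = []
    for lineno, rec in enumerate(reader, start=2):
        if not rec or all(not f.strip() for f in rec):
            continue
        try:
            rt = float(rec[cols["rt"]])
            content = float(rec[cols["content"]])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric or missing field ({exc})") from exc
        rows.append(CompoundRecord(rec[cols["compound"]].strip(), rt, content))
    table = CompoundTable(rows)
    logger.info("read %d compounds from %s (content sum %.3f%%)",
                len(rows), path, table.content_sum())
    return table


# ---------------------------------------------------------------------------
# GMT gene-set libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (GO/KEGG/Wiki-style GMT library)."""

    name: str
    terms: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise FormatError(f"library {self.name!r}: duplicate term ids")
        for t in self.terms:
            if not t.genes:
                raise FormatError(f"library {self.name!r}: empty gene set {t.term_id!r}")

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> GeneSet:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT library: one term per line, ``id TAB desc TAB gene...``."""
    path = Path(path)
    terms: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        # drop empty trailing fields (Excel-style padded exports)
        while fields and not fields[-1].strip():
            fields.pop()
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        genes = frozenset(canonical_gene(g) for g in fields[2:] if g.strip())
        terms.append(GeneSet(fields[0].strip(), fields[1].strip(), genes))
    return GeneSetLibrary(name or path.stem, terms)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in library.terms:
            fh.write("\t".join([t.term_id, t.description, *sorted(t.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Edge lists (TSV / SIF)
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Undirected edges with an interaction label.

    ``(a, b)`` and ``(b, a)`` are the same edge; duplicates are collapsed at
    construction and counted in ``n_duplicates``. Self-loops are dropped and
    counted in ``n_self_loops``.
    """

    edges: list[tuple[str, str, str]] = field(default_factory=list)  # (source, label, target)
    n_duplicates: int = 0
    n_self_loops: int = 0

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str] | tuple[str, str, str]]
    ) -> "EdgeList":
        seen: set[frozenset[str]] = set()
        edges: list[tuple[str, str, str]] = []
        dups = loops = 0
        for pair in pairs:
            if len(pair) == 2:
                a, b = pair
                label = "pp"
            else:
                a, label, b = pair
            a, b = a.strip(), b.strip()
            if a == b:
                loops += 1
                continue
            key = frozenset((a, b))
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            edges.append((a, label, b))
        if dups:
            logger.info("collapsed %d duplicate edges", dups)
        if loops:
            logger.warning("dropped %d self-loops", loops)
        return cls(edges=edges, n_duplicates=dups, n_self_loops=loops)

    def pairs(self) -> list[frozenset[str]]:
        return [frozenset((a, b)) for a, _, b in self.edges]

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, _, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def read_edge_list(path: str | Path, dialect: str = "tsv") -> EdgeList:
    """Read an undirected edge list.

    ``tsv``: ``source TAB target [TAB weight]`` with optional header.
    ``sif``: ``source SPACE interaction SPACE target``.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    triples: list[tuple[str, str, str]] = []
    first_data_line = True
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        if dialect == "tsv":
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
            a, b = fields[0], fields[1]
            if first_data_line and {a.strip().lower(), b.strip().lower()} & {
                "source", "target", "node1", "node2", "gene1", "gene2", "protein1", "protein2",
            }:
                first_data_line = False
                continue  # header row
            first_data_line = False
            triples.append((a, "pp", b))
        else:
            fields = line.split()
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: SIF line must have 3 whitespace fields")
            triples.append((fields[0], fields[1], fields[2]))
    return EdgeList.from_pairs(triples)


def write_edge_list(edge_list: EdgeList, path: str | Path, dialect: str = "tsv") -> None:
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if dialect == "tsv":
            fh.write("source\ttarget\n")
            for a, _, b in edge_list.edges:
                fh.write(f"{a}\t{b}\n")
        else:
            for a, label, b in edge_list.edges:
                fh.write(f"{a} {label} {b}\n")
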