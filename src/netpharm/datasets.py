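"""Packaged reference tables.

Two small measured tables for *Citrus reticulata* Blanco essential oil
(CBEO) ship with the package: its GC–MS composition (18 compounds with
retention times and peak-area relative contents) and the per-compound
topology table of its compound–target network against depression-associated
genes (16 connected compounds with degree and normalized betweenness).
"""

from __future__ import annotations

from importlib.resources import files

from .io_formats import CompoundTable, read_compound_table
from .network_topology import TopologyRecord, read_topology_table

#: The five compounds selected by the above-both-means topological screen.
CBEO_ACTIVE_COMPOUNDS = ("Linalool", "p-Cymene", "α-Terpinene", "Terpinen-4-ol", "α-Terpineol")

#: Published w/w mixture ratio for the five actives, in the order above.
CBEO_REPORTED_RATIO = (0.8, 5.0, 0.6, 2.0, 1.0)

#: Hub genes of the candidate-gene PPI network, ranked by degree.
CBEO_HUB_GENES = ("OPRM1", "PTGS2", "ESR1", "SLC6A4", "DRD2", "NR3C1")


def _data_path(name: str):
    return files("netpharm.data").joinpath(name)


def load_cbeo_contents() -> CompoundTable:
    """GC–MS composition of CBEO (compound, RT in min, relative content %)."""
    return read_compound_table(str(_data_path("cbeo_gcms_contents.tsv")))


def load_cbeo_topology() -> list[TopologyRecord]:
    """Per-compound degree and betweenness in the CBEO compound–target network."""
    return read_topology_table(str(_data_path("cbeo_compound_topology.tsv")))
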