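"""Abundance table -> attributed bipartite composition graph.

Every sample (row) and taxon (column) becomes a node; every strictly
positive cell becomes a directed sample -> taxon edge carrying the
absolute count and the within-sample relative abundance. The
transformation is lossless: the positive cells of the table are exactly
recoverable from the edge list.

Node attributes attached at build time:

* taxa — taxonomy ranks (when provided), ``prevalence`` (number of samples
  the taxon is observed in) and ``total_relative_abundance`` (column sum
  over the table grand total);
* samples — alpha diversity (``chao1``, ``shannon``, ``inverse_simpson``)
  and any metadata key/values, including the grouping variable.
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from . import diversity
from .errors import DegenerateInputError, UnknownIdentifierError, ValidationError
from .types import RANKS, AbundanceTable, SampleMetadata, TaxonomyTable

logger = logging.getLogger(__name__)

SAMPLE = "sample"
TAXON = "taxon"


class CompositionGraph:
    """Attributed bipartite directed graph of samples and taxa.

    Thin wrapper over a :class:`networkx.DiGraph`; the underlying graph is
    available as ``.g`` for interoperability.
    """

    def __init__(self, g: nx.DiGraph):
        self.g = g

    # -- node access ----------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["node_class"] == SAMPLE]

    @property
    def taxa(self) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["node_class"] == TAXON]

    @property
    def node_ids(self) -> list[str]:
        return list(self.g.nodes)

    def node_class(self, node_id: str) -> str:
        self._require(node_id)
        return self.g.nodes[node_id]["node_class"]

    def attributes(self, node_id: str) -> dict:
        self._require(node_id)
        return dict(self.g.nodes[node_id])

    def edges(self) -> Iterable[tuple[str, str, dict]]:
        return self.g.edges(data=True)

    def neighbors(self, node_id: str) -> list[str]:
        """Connected nodes regardless of edge direction."""
        self._require(node_id)
        return sorted(set(self.g.successors(node_id)) | set(self.g.predecessors(node_id)))

    def edge_weight_relative(self, a: str, b: str) -> float:
        data = self.g.get_edge_data(a, b) or self.g.get_edge_data(b, a)
        if data is None:
            raise UnknownIdentifierError(f"no edge between {a!r} and {b!r}")
        return data["weight_relative"]

    def _require(self, node_id: str) -> None:
        if node_id not in self.g:
            raise UnknownIdentifierError(f"unknown node {node_id!r}")

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompositionGraph):
            return NotImplemented
        return (
            dict(self.g.nodes(data=True)) == dict(other.g.nodes(data=True))
            and {(u, v): d for u, v, d in self.g.edges(data=True)}
            == {(u, v): d for u, v, d in other.g.edges(data=True)}
        )


def prevalence(table: AbundanceTable, taxon_id: str) -> int:
    """Number of samples in which the taxon has a strictly positive count."""
    if taxon_id not in table.data.columns:
        raise UnknownIdentifierError(f"unknown taxon {taxon_id!r}")
    return int((table.data[taxon_id] > 0).sum())


def total_relative_abundance(table: AbundanceTable, taxon_id: str) -> float:
    """Column sum of the taxon divided by the table grand total."""
    if taxon_id not in table.data.columns:
        raise UnknownIdentifierError(f"unknown taxon {taxon_id!r}")
    grand = table.counts.sum()
    if grand == 0:
        raise DegenerateInputError("table grand total is zero")
    return float(table.data[taxon_id].sum() / grand)


def _drop_empty(table: AbundanceTable) -> AbundanceTable:
    counts = table.counts
    zero_rows = [s for s, t in zip(table.sample_ids, counts.sum(axis=1)) if t == 0]
    zero_cols = [t for t, c in zip(table.taxon_ids, counts.sum(axis=0)) if c == 0]
    if not zero_rows and not zero_cols:
        return table
    if zero_rows:
        logger.warning("dropping all-zero samples: %s", zero_rows)
    if zero_cols:
        logger.warning("dropping all-zero taxa: %s", zero_cols)
    data = table.data.drop(index=zero_rows, columns=zero_cols)
    return AbundanceTable(data)


def build_graph(
    table: AbundanceTable,
    taxonomy: Optional[TaxonomyTable] = None,
    metadata: Optional[SampleMetadata] = None,
) -> CompositionGraph:
    """Build the attributed bipartite composition graph from a table.

    All-zero rows/columns are dropped with a logged warning (they would
    create isolated nodes with undefined relative weights). Metadata keys
    that are not sample ids of the table raise; taxonomy entries for taxa
    absent from the table are ignored with a warning.
    """
    table = _drop_empty(table)
    sample_set = set(table.sample_ids)
    taxon_set = set(table.taxon_ids)

    if metadata is not None:
        unknown = sorted(set(metadata.records) - sample_set)
        if unknown:
            raise UnknownIdentifierError(
                f"metadata refers to unknown samples: {unknown}"
            )
    if taxonomy is not None:
        extra = sorted(set(taxonomy.assignments) - taxon_set)
        if extra:
            logger.warning(
                "taxonomy entries for %d taxa absent from the table "
                "are ignored: %s", len(extra), extra[:10],
            )

    g = nx.DiGraph()
    counts = table.counts
    row_totals = counts.sum(axis=1)
    grand = counts.sum()

    for i, sid in enumerate(table.sample_ids):
        attrs: dict = {
            "node_class": SAMPLE,
            "chao1": diversity.chao1(counts[i]),
            "shannon": diversity.shannon(counts[i]),
            "inverse_simpson": diversity.inverse_simpson(counts[i]),
        }
        if metadata is not None and sid in metadata.records:
            attrs.update(metadata.records[sid])
            if metadata.group_key is not None:
                attrs["group"] = metadata.group_of(sid)
        g.add_node(sid, **attrs)

    for j, tid in enumerate(table.taxon_ids):
        attrs = {
            "node_class": TAXON,
            "prevalence": int((counts[:, j] > 0).sum()),
            "total_relative_abundance": float(counts[:, j].sum() / grand),
        }
        if taxonomy is not None and tid in taxonomy:
            for rank, value in zip(RANKS, taxonomy.assignments[tid]):
                attrs[rank] = value
        g.add_node(tid, **attrs)

    rows, cols = np.nonzero(counts)
    for i, j in zip(rows, cols):
        sid = table.sample_ids[i]
        tid = table.taxon_ids[j]
        g.add_edge(
            sid,
            tid,
            weight_absolute=float(counts[i, j]),
            weight_relative=float(counts[i, j] / row_totals[i]),
        )
    return CompositionGraph(g)


def subset_samples(graph: CompositionGraph, sample_ids: list[str]) -> CompositionGraph:
    """Induced subgraph on the named samples.

    Keeps their edges and any taxon with at least one remaining edge;
    relative weights are untouched (still relative to the original row
    totals).
    """
    sample_set = set(graph.samples)
    unknown = [s for s in sample_ids if s not in sample_set]
    if unknown:
        raise UnknownIdentifierError(f"unknown sample ids: {unknown}")
    keep_samples = set(sample_ids)
    keep_taxa = {
        v for u, v, _ in graph.edges() if u in keep_samples
    }
    sub = graph.g.subgraph(keep_samples | keep_taxa).copy()
    return CompositionGraph(sub)
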