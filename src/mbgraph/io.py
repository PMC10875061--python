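"""Reading and writing the standard on-disk formats.

Tables travel as TSV (tab-separated, UTF-8, first row and column are
identifiers; a leading ``#`` on the header — as in QIIME-era ``#OTU ID``
exports — is tolerated). Abundance tables may also arrive as BIOM 1.0
(JSON) or BIOM 2.1 (HDF5); graphs are serialised as JSON node-link or
GraphML, losslessly.
"""
from __future__ import annotations

import json
import logging
import os
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    ParseError,
    ValidationError,
)
from .graph import CompositionGraph
from .types import RANKS, UNASSIGNED, AbundanceTable, SampleMetadata, TaxonomyTable

logger = logging.getLogger(__name__)

ORIENTATIONS = ("samples_as_rows", "taxa_as_rows")
GRAPH_DIALECTS = ("json_nodelink", "graphml")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_abundance_table(path, orientation: str = "samples_as_rows") -> AbundanceTable:
    """Read a counts table from TSV.

    ``orientation`` states how the file is laid out; the returned table is
    always canonical samples x taxa (transposed when the file stores taxa
    as rows).
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(
            f"orientation must be one of {ORIENTATIONS}, got {orientation!r}"
        )
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty table") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise EmptyInputError(f"{path}: table has no data cells")
    raw.index = raw.index.astype(str).str.strip()
    if raw.index.name and str(raw.index.name).startswith("#"):
        raw.index.name = str(raw.index.name).lstrip("#").strip()

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at row "
            f"{raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ParseError(
            f"{path}: negative count at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    table = AbundanceTable(numeric)
    if orientation == "taxa_as_rows":
        table = table.transpose()
    return table


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy_table(path) -> TaxonomyTable:
    """Read taxon -> rank assignments from TSV (taxon_id + up to 8 ranks)."""
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna(UNASSIGNED)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty taxonomy table") from None
    assignments = {
        str(taxon): tuple(str(v) for v in row)
        for taxon, row in raw.iterrows()
    }
    return TaxonomyTable(assignments)


def write_taxonomy_table(taxonomy: TaxonomyTable, path) -> None:
    frame = pd.DataFrame.from_dict(
        taxonomy.assignments, orient="index", columns=list(RANKS)
    )
    frame.to_csv(path, sep="\t", index_label="taxon_id")


def read_sample_metadata(path, group_key: Optional[str] = None) -> SampleMetadata:
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty metadata table") from None
    records = {
        str(sid): {k: _coerce_scalar(v) for k, v in row.items() if pd.notna(v)}
        for sid, row in raw.iterrows()
    }
    return SampleMetadata(records=records, group_key=group_key)


def write_sample_metadata(metadata: SampleMetadata, path) -> None:
    frame = pd.DataFrame.from_dict(metadata.records, orient="index")
    frame.to_csv(path, sep="\t", index_label="sample_id")


def _coerce_scalar(value: str):
    """Best-effort typing of a metadata cell (int, float, else string)."""
    for cast in (int, float):
        try:
            return cast(value)
        except (TypeError, ValueError):
            continue
    return str(value)


# ---------------------------------------------------------------------------
# BIOM
# ---------------------------------------------------------------------------

def read_biom(path) -> tuple[AbundanceTable, Optional[TaxonomyTable]]:
    """Read a BIOM table (1.0 JSON, or 2.1 HDF5 when h5py can open it).

    BIOM stores observations (taxa) as rows and samples as columns; the
    result is transposed into the canonical samples x taxa orientation.
    Taxonomy strings found in observation metadata are returned alongside.
    """
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        return _read_biom_hdf5(path)
    return _read_biom_json(path)


def _read_biom_json(path) -> tuple[AbundanceTable, Optional[TaxonomyTable]]:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not valid BIOM JSON ({exc})") from None
    for key in ("rows", "columns", "data", "shape", "matrix_type"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM JSON missing key {key!r}")
    n_obs, n_samp = doc["shape"]
    obs_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    if len(obs_ids) != n_obs or len(sample_ids) != n_samp:
        raise FormatError(f"{path}: BIOM shape does not match row/column lists")

    dense = np.zeros((n_obs, n_samp))
    if doc["matrix_type"] == "dense":
        data = np.asarray(doc["data"], dtype=float)
        if data.shape != (n_obs, n_samp):
            raise FormatError(f"{path}: dense data shape mismatch")
        dense = data
    elif doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            dense[int(r), int(c)] = float(v)
    else:
        raise FormatError(
            f"{path}: unsupported matrix_type {doc['matrix_type']!r}"
        )

    table = AbundanceTable(
        pd.DataFrame(dense.T, index=sample_ids, columns=obs_ids)
    )
    taxonomy = _taxonomy_from_metadata(
        obs_ids, [r.get("metadata") for r in doc["rows"]]
    )
    return table, taxonomy


def _read_biom_hdf5(path) -> tuple[AbundanceTable, Optional[TaxonomyTable]]:
    try:
        import h5py
    except ImportError:  # pragma: no cover - capability check
        raise FormatError(
            "HDF5 BIOM support requires h5py, which is not available"
        ) from None
    from scipy import sparse

    try:
        with h5py.File(path, "r") as fh:
            obs_ids = [x.decode() for x in fh["observation/ids"][:]]
            sample_ids = [x.decode() for x in fh["sample/ids"][:]]
            grp = fh["observation/matrix"]
            matrix = sparse.csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
                shape=(len(obs_ids), len(sample_ids)),
            )
            tax_meta = None
            if "observation/metadata/taxonomy" in fh:
                raw = fh["observation/metadata/taxonomy"][:]
                tax_meta = [
                    {"taxonomy": [x.decode() for x in row]} for row in raw
                ]
    except (OSError, KeyError) as exc:
        raise FormatError(f"{path}: not a readable BIOM 2.1 file ({exc})") from None

    table = AbundanceTable(
        pd.DataFrame(
            matrix.toarray().T.astype(float), index=sample_ids, columns=obs_ids
        )
    )
    return table, _taxonomy_from_metadata(obs_ids, tax_meta)


#: greengenes/SILVA-style rank prefixes -> our rank slots
_RANK_PREFIX = {"d": 0, "k": 1, "p": 2, "c": 3, "o": 4, "f": 5, "g": 6, "s": 7}


def _taxonomy_from_metadata(obs_ids, metadata_rows) -> Optional[TaxonomyTable]:
    if metadata_rows is None:
        return None
    assignments = {}
    for tid, meta in zip(obs_ids, metadata_rows):
        if not meta or "taxonomy" not in meta or meta["taxonomy"] is None:
            continue
        levels = [str(x).strip() for x in meta["taxonomy"]]
        slots = [UNASSIGNED] * len(RANKS)
        prefixed = all(
            len(lv) >= 3 and lv[1:3] == "__" and lv[0].lower() in _RANK_PREFIX
            for lv in levels
            if lv
        )
        if prefixed and levels:
            for lv in levels:
                if not lv or lv.endswith("__"):
                    continue
                slots[_RANK_PREFIX[lv[0].lower()]] = lv
        else:
            # unprefixed lists are assumed to start at domain
            for i, lv in enumerate(levels[: len(RANKS)]):
                slots[i] = lv
        # 7-rank conventions lack a domain; mirror the kingdom there so the
        # prefix property (no gaps above an assigned rank) holds
        if slots[0] == UNASSIGNED and slots[1] != UNASSIGNED:
            slots[0] = slots[1]
        # enforce the prefix property: stop at the first unassigned rank
        cleaned: list[str] = []
        for lv in slots:
            if lv == UNASSIGNED:
                break
            cleaned.append(lv)
        if not cleaned:
            continue
        assignments[str(tid)] = tuple(cleaned) + (UNASSIGNED,) * (
            len(RANKS) - len(cleaned)
        )
    if not assignments:
        return None
    return TaxonomyTable(assignments)


# ---------------------------------------------------------------------------
# Graph serialisation
# ---------------------------------------------------------------------------

def write_graph(graph: CompositionGraph, path, dialect: str = "json_nodelink") -> None:
    """Serialise a composition graph (JSON node-link or GraphML).

    The JSON dialect emits ``{"nodes": [...], "links": [...]}`` with every
    link carrying ``source`` (the sample), ``target`` (the taxon) and both
    weight properties; a write -> read roundtrip reproduces the graph
    exactly.
    """
    if dialect not in GRAPH_DIALECTS:
        raise ValidationError(
            f"dialect must be one of {GRAPH_DIALECTS}, got {dialect!r}"
        )
    if dialect == "graphml":
        nx.write_graphml(graph.g, path)
        return
    doc = {
        "nodes": [
            {"id": node, **attrs} for node, attrs in graph.g.nodes(data=True)
        ],
        "links": [
            {"source": u, "target": v, **attrs}
            for u, v, attrs in graph.g.edges(data=True)
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def read_graph(path, dialect: Optional[str] = None) -> CompositionGraph:
    """Read a graph written by :func:`write_graph` (dialect inferred from
    the extension when not given: ``.graphml`` vs anything else = JSON)."""
    if dialect is None:
        dialect = "graphml" if str(path).endswith(".graphml") else "json_nodelink"
    if dialect == "graphml":
        g = nx.read_graphml(path)
        return CompositionGraph(nx.DiGraph(g))
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid graph JSON ({exc})") from None
    if "nodes" not in doc or "links" not in doc:
        raise FormatError(f"{path}: graph JSON must have 'nodes' and 'links'")
    g = nx.DiGraph()
    for node in doc["nodes"]:
        attrs = dict(node)
        nid = attrs.pop("id")
        g.add_node(nid, **attrs)
    for link in doc["links"]:
        attrs = dict(link)
        u = attrs.pop("source")
        v = attrs.pop("target")
        g.add_edge(u, v, **attrs)
    return CompositionGraph(g)


# ---------------------------------------------------------------------------
# Layout serialisation
# ---------------------------------------------------------------------------

def write_layout(positions: dict, path, config: Optional[dict] = None,
                 seed: Optional[int] = None) -> None:
    doc = {
        "positions": {k: [float(x), float(y)] for k, (x, y) in positions.items()},
        "config": config or {},
        "seed": seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def read_layout(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if "positions" not in doc:
        raise FormatError(f"{path}: layout JSON must have 'positions'")
    return {k: (float(x), float(y)) for k, (x, y) in doc["positions"].items()}
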