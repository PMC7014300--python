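"""Reading, filtering and querying STRING-format protein-link tables.

STRING ships protein-link tables as whitespace-delimited text with a header
naming at least ``protein1``, ``protein2`` and ``combined_score`` (an integer
confidence in [0, 1000]).  Human identifiers carry a ``9606.`` taxon prefix
and every undirected pair is usually listed in both directions.  This module
normalises all of that into a single undirected weighted network and exposes
the score-ranked neighborhood query that seed-set construction builds on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_TAXON_PREFIX = re.compile(r"^\d+\.")

REQUIRED_COLUMNS = ("protein1", "protein2", "combined_score")


class FormatError(ValueError):
    """A protein-links file violates the expected dialect."""


@dataclass(frozen=True, order=True)
class PPIEdge:
    """One undirected protein pair with its integer combined score.

    Endpoints are stored in lexicographic order so each undirected pair has
    a single canonical representation.
    """

    protein_a: str
    protein_b: str
    combined_score: int

    def __post_init__(self) -> None:
        if self.protein_a >= self.protein_b:
            raise ValueError(
                f"endpoints must be lexicographically ordered and distinct: "
                f"{self.protein_a!r} vs {self.protein_b!r}"
            )
        if not 0 <= self.combined_score <= 1000:
            raise ValueError(f"combined_score {self.combined_score} outside [0, 1000]")


@dataclass
class LoadReport:
    """Bookkeeping from one :func:`read_string_edges` call."""

    n_rows: int = 0
    n_unmapped: int = 0
    n_below_threshold: int = 0
    n_self_loops: int = 0
    n_duplicates_collapsed: int = 0


class PPINetwork:
    """Undirected weighted protein network filtered at a combined-score threshold.

    Wraps :class:`networkx.Graph`; edge weights live in the ``score``
    attribute.  All retained edges satisfy ``score > score_threshold``
    strictly.
    """

    def __init__(self, score_threshold: int = 0) -> None:
        if not 0 <= score_threshold <= 1000:
            raise ValueError(f"score_threshold {score_threshold} outside [0, 1000]")
        self.score_threshold = int(score_threshold)
        self.graph = nx.Graph()
        self.report = LoadReport()

    # -- construction ------------------------------------------------------

    def add_edge(self, protein_a: str, protein_b: str, combined_score: int) -> None:
        """Add one undirected edge if it passes the strict score filter.

        Symmetric duplicates collapse to a single edge keeping the maximum
        score; self-loops are dropped and counted.
        """
        a, b = sorted((protein_a, protein_b))
        if a == b:
            self.report.n_self_loops += 1
            return
        score = int(combined_score)
        if not 0 <= score <= 1000:
            raise ValueError(f"combined_score {score} outside [0, 1000]")
        if score <= self.score_threshold:
            self.report.n_below_threshold += 1
            return
        if self.graph.has_edge(a, b):
            self.report.n_duplicates_collapsed += 1
            if score <= self.graph.edges[a, b]["score"]:
                return
        self.graph.add_edge(a, b, score=score)

    # -- views -------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[PPIEdge]:
        return sorted(
            PPIEdge(*sorted((a, b)), d["score"])
            for a, b, d in self.graph.edges(data=True)
        )

    def __contains__(self, protein: str) -> bool:
        return protein in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return (
            self.score_threshold == other.score_threshold
            and self.edges == other.edges
            and self.nodes == other.nodes
        )

    def __repr__(self) -> str:
        return (
            f"PPINetwork({self.graph.number_of_nodes()} nodes, "
            f"{self.graph.number_of_edges()} edges, "
            f"score > {self.score_threshold})"
        )


def strip_taxon_prefix(identifier: str) -> str:
    """Remove a leading NCBI taxon prefix such as ``9606.`` if present."""
    return _TAXON_PREFIX.sub("", identifier)


def read_string_edges(
    path,
    score_threshold: int = 700,
    id_mapping: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Read a STRING protein-links table into a filtered :class:`PPINetwork`.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited file with a header naming at least
        ``protein1``, ``protein2``, ``combined_score``.  Extra columns are
        ignored.
    score_threshold
        Only edges with ``combined_score`` STRICTLY greater than this are
        retained (the conventional high-confidence cut is 700).
    id_mapping
        Optional STRING-identifier → gene-symbol map applied after taxon
        prefixes are stripped.  Rows with an unmappable endpoint are dropped
        and counted in the network's load report.

    Raises
    ------
    FormatError
        Missing required column, or a non-integer score (reported with its
        1-based data line number).
    """
    try:
        table = pd.read_csv(path, sep=r"\s+", dtype=str, comment=None)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file has no header row") from exc

    for column in REQUIRED_COLUMNS:
        if column not in table.columns:
            raise FormatError(f"{path}: missing required column {column!r}")

    network = PPINetwork(score_threshold=score_threshold)
    network.report.n_rows = len(table)
    if table.empty:
        return network

    scores = pd.to_numeric(table["combined_score"], errors="coerce")
    bad = scores.isna() | (scores != scores.round())
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(
            f"{path}: non-integer combined_score "
            f"{table['combined_score'][bad.idxmax()]!r} at line {line}"
        )

    a = table["protein1"].map(strip_taxon_prefix)
    b = table["protein2"].map(strip_taxon_prefix)
    if id_mapping is not None:
        mapped_a = a.map(id_mapping)
        mapped_b = b.map(id_mapping)
        unmapped = mapped_a.isna() | mapped_b.isna()
        n_unmapped = int(unmapped.sum())
        if n_unmapped:
            logger.warning("%d rows dropped: unmappable identifiers", n_unmapped)
        network.report.n_unmapped = n_unmapped
        keep = ~unmapped
        a, b, scores = mapped_a[keep], mapped_b[keep], scores[keep]

    for pa, pb, score in zip(a, b, scores.astype(int)):
        network.add_edge(pa, pb, score)
    return network


def read_id_mapping(path) -> dict[str, str]:
    """Read a two-column (string_id, symbol) TSV into a dict."""
    table = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if table.shape[1] < 2:
        raise FormatError(f"{path}: identifier map needs two columns")
    return dict(zip(table[0], table[1]))


def write_edges(network: PPINetwork, path) -> None:
    """Export the network as a three-column TSV (re-readable by
    :func:`read_string_edges` at threshold 0 or the original threshold)."""
    rows = [
        (e.protein_a, e.protein_b, e.combined_score) for e in network.edges
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def neighbors_ranked(network: PPINetwork, protein: str) -> list[tuple[str, int]]:
    """Neighbors of ``protein`` sorted by combined score descending.

    Ties are broken by ascending lexicographic order of the neighbor
    identifier so that downstream fixed-size set construction is
    deterministic.  A protein absent from the network yields an empty list.
    """
    if protein not in network.graph:
        return []
    pairs = [
        (neighbor, data["score"])
        for neighbor, data in network.graph[protein].items()
    ]
    pairs.sort(key=lambda item: (-item[1], item[0]))
    return pairs
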