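"""Cross-RCS aggregation of enriched terms.

After per-RCS over-representation analysis, significant terms are pooled
across all RCSs and ranked by how many RCSs support each term — the "global
tendencies" view.  Collections are kept separate (a term hit in GO-BP and
GO-MF for one seed yields one row per collection), and each seed counts at
most once per (collection, term) row.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .ora import EnrichmentResult

FREQUENCY_COLUMNS = [
    "collection",
    "term_id",
    "description",
    "frequency",
    "supporting_seeds",
]


def aggregate_enrichments(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Rank terms by the number of distinct RCS seeds calling them significant.

    Returns a table with columns ``collection, term_id, description,
    frequency, supporting_seeds`` (seeds semicolon-joined, in input catalog
    order), sorted by frequency descending then term_id ascending.  Terms
    significant in no RCS are absent.
    """
    support: dict[tuple[str, str], dict] = {}
    for result in results:
        for record in result.significant:
            key = (record.collection_name, record.term_id)
            entry = support.setdefault(
                key, {"description": record.description, "seeds": []}
            )
            if result.rcs_seed not in entry["seeds"]:
                entry["seeds"].append(result.rcs_seed)
    rows = [
        (
            collection,
            term_id,
            entry["description"],
            len(entry["seeds"]),
            ";".join(entry["seeds"]),
        )
        for (collection, term_id), entry in support.items()
    ]
    table = pd.DataFrame(rows, columns=FREQUENCY_COLUMNS)
    table.sort_values(
        ["frequency", "term_id", "collection"],
        ascending=[False, True, True],
        inplace=True,
        kind="mergesort",
    )
    return table.reset_index(drop=True)


def term_seed_matrix(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Binary incidence matrix: rows (collection, term), columns seeds.

    Entry 1 iff the term is significant in that seed's RCS.  Column order
    follows first appearance of each seed in ``results``; rows are sorted
    by (collection, term_id).  Row sums equal the frequencies reported by
    :func:`aggregate_enrichments`.
    """
    seeds: list[str] = []
    for result in results:
        if result.rcs_seed not in seeds:
            seeds.append(result.rcs_seed)
    cells: dict[tuple[str, str], set[str]] = {}
    for result in results:
        for record in result.significant:
            cells.setdefault(
                (record.collection_name, record.term_id), set()
            ).add(result.rcs_seed)
    index = pd.MultiIndex.from_tuples(
        sorted(cells), names=["collection", "term_id"]
    )
    matrix = pd.DataFrame(0, index=index, columns=seeds, dtype=int)
    for key, supporting in cells.items():
        for seed in supporting:
            matrix.loc[key, seed] = 1
    return matrix


def to_edge_list(matrix: pd.DataFrame) -> pd.DataFrame:
    """Flatten the incidence matrix into a bipartite term–seed edge list."""
    rows = [
        (collection, term_id, seed)
        for (collection, term_id), row in matrix.iterrows()
        for seed, hit in row.items()
        if hit
    ]
    return pd.DataFrame(rows, columns=["collection", "term_id", "seed"])


def write_graphml(matrix: pd.DataFrame, path) -> None:
    """Export the bipartite term–seed graph as GraphML."""
    import networkx as nx

    graph = nx.Graph()
    for (collection, term_id), row in matrix.iterrows():
        term_node = f"{collection}:{term_id}"
        graph.add_node(term_node, kind="term", collection=collection)
        for seed, hit in row.items():
            if hit:
                graph.add_node(seed, kind="seed")
                graph.add_edge(term_node, seed)
    nx.write_graphml(graph, path)
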