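"""GMT gene-set collections and the pre-enrichment term-size filter.

Collections (GO slices, MSigDB hallmark) are consumed flat from GMT: one
tab-delimited line per term — term id, description, then gene symbols.
Terms are size-filtered BEFORE testing (default: keep 10–2000 genes) so the
multiple-testing burden reflects only the terms actually tested; very large
terms are uninformative and excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


class GMTFormatError(ValueError):
    """A GMT file violates the expected dialect."""


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """A named list of gene sets with their symbol universe.

    The universe is the union of all member sets and serves as the default
    background population for over-representation testing.
    """

    name: str
    sets: list[GeneSet] = field(default_factory=list)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for gene_set in self.sets:
            out |= gene_set.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.name == other.name and set(self.sets) == set(other.sets)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file.

    Duplicate genes within a line are de-duplicated with a logged count;
    blank lines are skipped.  A line with fewer than three fields or a
    repeated term id raises :class:`GMTFormatError` naming the line.
    """
    if name is None:
        name = str(path)
    collection = GeneSetCollection(name=name)
    seen: set[str] = set()
    n_duplicate_genes = 0
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path}:{line_no}: expected term, description and at "
                    f"least one gene, got {len(fields)} fields"
                )
            term_id, description, *genes = fields
            genes = [g for g in genes if g]
            if term_id in seen:
                raise GMTFormatError(f"{path}:{line_no}: duplicate term {term_id!r}")
            seen.add(term_id)
            unique = frozenset(genes)
            n_duplicate_genes += len(genes) - len(unique)
            collection.sets.append(GeneSet(term_id, description, unique))
    if n_duplicate_genes:
        logger.warning(
            "%s: %d duplicate gene entries de-duplicated", path, n_duplicate_genes
        )
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection back to GMT (genes sorted for determinism)."""
    with open(path, "w") as handle:
        for gene_set in collection.sets:
            handle.write(
                "\t".join(
                    [gene_set.term_id, gene_set.description, *sorted(gene_set.genes)]
                )
                + "\n"
            )


def filter_by_size(
    collection: GeneSetCollection,
    max_size: int = 2000,
    min_size: int = 10,
) -> GeneSetCollection:
    """Retain sets with ``min_size <= |genes| <= max_size``.

    Term sizes are measured within the collection as shipped (no
    intersection with an expression universe).  The universe is recomputed
    from the retained sets.
    """
    if not 1 <= min_size <= max_size:
        raise ValueError(
            f"need 1 <= min_size <= max_size, got ({min_size}, {max_size})"
        )
    kept = [s for s in collection.sets if min_size <= len(s) <= max_size]
    return GeneSetCollection(name=collection.name, sets=kept)
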