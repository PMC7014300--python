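"""Ranked Correlated Set (RCS) construction.

An RCS is a seed protein together with its highest-combined-score neighbors
in a score-filtered STRING network, built at a fixed target size (default 15
proteins including the seed) so that every seed's downstream enrichment test
has the same statistical power.  Seeds with fewer than a minimum number of
eligible neighbors (default 10) are discarded rather than tested on an
under-powered set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ppi_io import PPINetwork, neighbors_ranked

logger = logging.getLogger(__name__)

RETAINED = "retained"
DISCARDED = "discarded"


@dataclass
class RCS:
    """One seed's ranked correlated set.

    ``members`` lists the seed first, then neighbors in descending score
    order.  ``status`` is ``"retained"`` when the seed had at least
    ``min_neighbors`` eligible neighbors, ``"discarded"`` otherwise (in which
    case ``members`` is empty).  A retained set with fewer than
    ``target_size`` members (seed had between ``min_neighbors`` and
    ``target_size - 2`` neighbors) is flagged ``undersized``.
    """

    seed: str
    members: list[str]
    target_size: int
    min_neighbors: int
    status: str
    n_eligible: int

    @property
    def retained(self) -> bool:
        return self.status == RETAINED

    @property
    def undersized(self) -> bool:
        return self.retained and len(self.members) < self.target_size


@dataclass
class RCSCatalog:
    """Partition of a seed list into retained RCSs and discards."""

    rcs_list: list[RCS] = field(default_factory=list)
    discard_report: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.rcs_list)

    @property
    def n_discarded(self) -> int:
        return len(self.discard_report)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.seed, r.status, len(r.members), ";".join(r.members))
            for r in self.rcs_list
        ] + [(seed, DISCARDED, 0, "") for seed, _ in self.discard_report]
        return pd.DataFrame(rows, columns=["seed", "status", "n_members", "members"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "retained": [
                {
                    "seed": r.seed,
                    "members": r.members,
                    "n_eligible": r.n_eligible,
                    "undersized": r.undersized,
                }
                for r in self.rcs_list
            ],
            "discarded": [
                {"seed": seed, "n_eligible": n} for seed, n in self.discard_report
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")


def build_rcs(
    network: PPINetwork,
    seed: str,
    target_size: int = 15,
    min_neighbors: int = 10,
) -> RCS:
    """Build the RCS for one seed.

    With ``m`` eligible neighbors in the score-filtered network: discard if
    ``m < min_neighbors``; otherwise retain the seed plus the top
    ``min(m, target_size - 1)`` neighbors from the ranked neighborhood.
    A seed absent from the network has 0 eligible neighbors and is discarded.
    """
    if target_size < 2:
        raise ValueError(f"target_size must be at least 2, got {target_size}")
    if target_size < min_neighbors + 1:
        raise ValueError(
            f"target_size ({target_size}) must be at least min_neighbors + 1 "
            f"({min_neighbors + 1}) for the discard rule to be consistent"
        )
    ranked = neighbors_ranked(network, seed)
    m = len(ranked)
    if m < min_neighbors:
        return RCS(seed, [], target_size, min_neighbors, DISCARDED, m)
    members = [seed] + [name for name, _ in ranked[: target_size - 1]]
    return RCS(seed, members, target_size, min_neighbors, RETAINED, m)


def build_catalog(
    network: PPINetwork,
    seeds: Sequence[str],
    target_size: int = 15,
    min_neighbors: int = 10,
) -> RCSCatalog:
    """Build one RCS per unique seed, preserving input order.

    Duplicate seed names collapse to their first occurrence with a logged
    warning; the catalog partitions the unique seeds into retained and
    discarded so that ``n_retained + n_discarded`` equals their count.
    """
    unique: list[str] = []
    seen: set[str] = set()
    for seed in seeds:
        if seed in seen:
            logger.warning("duplicate seed %r collapsed to first occurrence", seed)
            continue
        seen.add(seed)
        unique.append(seed)
    if not unique:
        raise ValueError("seed list is empty")

    catalog = RCSCatalog()
    for seed in unique:
        rcs = build_rcs(network, seed, target_size, min_neighbors)
        if rcs.retained:
            if rcs.undersized:
                logger.warning(
                    "seed %s retained undersized (%d members < target %d)",
                    seed,
                    len(rcs.members),
                    target_size,
                )
            catalog.rcs_list.append(rcs)
        else:
            catalog.discard_report.append((seed, rcs.n_eligible))
    return catalog


def read_seed_list(path) -> list[str]:
    """Read a plain-text seed list: one identifier per line, '#' comments."""
    seeds = []
    with open(path) as handle:
        for line in handle:
            name = line.split("#", 1)[0].strip()
            if name:
                seeds.append(name)
    return seeds
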