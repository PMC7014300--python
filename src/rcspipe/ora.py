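"""Over-representation analysis of one RCS against a gene-set collection.

For each term the overlap between the RCS members and the term's genes is
tested with the exact hypergeometric upper tail (the one-sided Fisher test),
taking the collection universe as the background population.  P-values are
Benjamini–Hochberg adjusted per (RCS, collection) block and a term is called
significant only when BOTH the raw p-value and the adjusted q-value pass
their cutoffs (default 0.05 each).  Terms with zero overlap are not tested
and therefore do not inflate the multiple-testing burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSetCollection
from .rcs import RCS

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    The probability that a uniformly drawn size-``n`` subset of an
    ``N``-element universe containing ``K`` annotated genes hits the
    annotation at least ``k`` times.  Computed via the survival function of
    :class:`scipy.stats.hypergeom` (log-gamma based, numerically stable).
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N} "
            f"(need 0 <= k <= n <= N and k <= K <= N)"
        )
    # sf(k-1) = P(X >= k); clip guards against tiny negative rounding.
    return float(min(1.0, max(0.0, stats.hypergeom.sf(k - 1, N, K, n))))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, scale p_(i) by m/i, enforce monotone non-decrease from
    the largest rank down, cap at 1.  Delegates to statsmodels'
    ``fdr_bh``.
    """
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (RCS, term) hypergeometric result.

    ``k`` of the ``n`` in-universe RCS members are annotated to the term,
    which covers ``K`` of the ``N`` universe genes; ``driver_genes`` are the
    k overlapping members that drive the significance.
    """

    rcs_seed: str
    collection_name: str
    term_id: str
    description: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float
    driver_genes: frozenset[str]


@dataclass
class EnrichmentResult:
    """All tested terms for one (RCS, collection) pair."""

    rcs_seed: str
    collection_name: str
    records: list[EnrichmentRecord] = field(default_factory=list)
    significant: list[EnrichmentRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.rcs_seed,
                r.collection_name,
                r.term_id,
                r.description,
                r.k,
                r.n,
                r.K,
                r.N,
                r.p_value,
                r.q_value,
                ";".join(sorted(r.driver_genes)),
            )
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "seed",
                "collection",
                "term_id",
                "description",
                "k",
                "n",
                "K",
                "N",
                "p_value",
                "q_value",
                "driver_genes",
            ],
        )


def enrich_rcs(
    rcs: RCS,
    collection: GeneSetCollection,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> EnrichmentResult:
    """Test every overlapping term of ``collection`` against the RCS members.

    The foreground is the RCS members (seed included) intersected with the
    collection universe; members outside the universe are logged and do not
    count toward ``n``.  BH adjustment spans all tested terms of this
    (RCS, collection) pair only.  ``significant`` holds records with
    ``p <= p_cut`` and ``q <= q_cut``, sorted by (q, p, term_id).
    """
    if not rcs.retained:
        raise ValueError(f"RCS for seed {rcs.seed!r} was discarded; cannot enrich")
    universe = collection.universe
    members = set(rcs.members)
    foreground = members & universe
    missing = members - universe
    if missing:
        logger.warning(
            "seed %s: %d members outside the %s universe: %s",
            rcs.seed,
            len(missing),
            collection.name,
            ",".join(sorted(missing)),
        )
    result = EnrichmentResult(rcs_seed=rcs.seed, collection_name=collection.name)
    if not foreground:
        logger.warning(
            "seed %s: no members in the %s universe; empty result",
            rcs.seed,
            collection.name,
        )
        return result

    n = len(foreground)
    N = len(universe)
    tested: list[tuple] = []
    for gene_set in collection.sets:
        drivers = foreground & gene_set.genes
        k = len(drivers)
        if k == 0:
            continue
        p = hypergeom_tail(k, n, len(gene_set.genes), N)
        tested.append((gene_set, k, p, frozenset(drivers)))
    if not tested:
        return result

    q_values = bh_adjust([p for _, _, p, _ in tested])
    for (gene_set, k, p, drivers), q in zip(tested, q_values):
        result.records.append(
            EnrichmentRecord(
                rcs_seed=rcs.seed,
                collection_name=collection.name,
                term_id=gene_set.term_id,
                description=gene_set.description,
                k=k,
                n=n,
                K=len(gene_set.genes),
                N=N,
                p_value=p,
                q_value=q,
                driver_genes=drivers,
            )
        )
    result.significant = sorted(
        (r for r in result.records if r.p_value <= p_cut and r.q_value <= q_cut),
        key=lambda r: (r.q_value, r.p_value, r.term_id),
    )
    return result


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Concatenate per-RCS results into one long-format table."""
    frames = [r.to_frame() for r in results]
    if not frames:
        return EnrichmentResult("", "").to_frame()
    return pd.concat(frames, ignore_index=True)


def results_from_frame(
    frame: pd.DataFrame,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> list[EnrichmentResult]:
    """Rebuild per-(RCS, collection) results from a long-format table.

    Inverse of :func:`results_to_frame`; the significance call is re-derived
    from the stored p/q values at the given cutoffs.
    """
    results = []
    for (seed, collection), chunk in frame.groupby(
        ["seed", "collection"], sort=False
    ):
        result = EnrichmentResult(rcs_seed=seed, collection_name=collection)
        for row in chunk.itertuples(index=False):
            drivers = (
                frozenset(str(row.driver_genes).split(";"))
                if isinstance(row.driver_genes, str) and row.driver_genes
                else frozenset()
            )
            result.records.append(
                EnrichmentRecord(
                    rcs_seed=seed,
                    collection_name=collection,
                    term_id=row.term_id,
                    description=row.description,
                    k=int(row.k),
                    n=int(row.n),
                    K=int(row.K),
                    N=int(row.N),
                    p_value=float(row.p_value),
                    q_value=float(row.q_value),
                    driver_genes=drivers,
                )
            )
        result.significant = sorted(
            (
                r
                for r in result.records
                if r.p_value <= p_cut and r.q_value <= q_cut
            ),
            key=lambda r: (r.q_value, r.p_value, r.term_id),
        )
        results.append(result)
    return results
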