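"""Quantitative proteomics statistics.

Two independent analyses share this module:

* **Spectral-count correlation** — a protein-by-sample spectral-count matrix
  is normalized by per-sample totals (counts are a sampling-depth-dependent
  abundance proxy), log2-transformed, and each candidate protein is rank
  correlated (Spearman) against a reference protein across samples.

* **2-DE spot differential testing** — spot volumes from two-dimensional
  gel electrophoresis are background-subtracted and normalized to the total
  valid-spot quantity per gel, then each spot is compared between two
  replicate groups with a two-sided pooled-variance Student t-test at
  alpha = 0.05.

The Spearman coefficient is the Pearson correlation of mid-ranks (so ties
are handled); its p-value comes from the exact permutation distribution for
n < 10 with untied data and from the t-approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` with n-2 degrees of freedom otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED = "normalized"


# ---------------------------------------------------------------------------
# Count matrix and normalization
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Protein-by-sample matrix of spectral counts.

    ``values`` is a proteins x samples DataFrame (row index = protein
    identifiers, columns = sample identifiers).  ``state`` tracks whether
    the values are raw non-negative counts or normalized log2 fractions.
    """

    values: pd.DataFrame
    state: str = RAW

    def __post_init__(self) -> None:
        if self.state not in (RAW, NORMALIZED):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == RAW and (self.values.values < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path, state: str = RAW) -> "CountMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, state=state)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def normalize_counts(matrix: CountMatrix, pseudocount: float = 0.5) -> CountMatrix:
    """Total-count normalize and log2-transform a raw count matrix.

    Each count (plus ``pseudocount``) is divided by its sample's total of
    pseudocounted counts, then log2-transformed.  With ``pseudocount = 0``
    the per-sample fractions sum to exactly 1; a zero count then has no
    defined logarithm, so zero is only permitted when the matrix has no
    zeros.
    """
    if matrix.state != RAW:
        raise ValueError("matrix is already normalized")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = matrix.values.astype(float)
    if pseudocount == 0 and (counts.values == 0).any():
        raise ValueError(
            "matrix contains zero counts; use a positive pseudocount "
            "(e.g. 0.5) so log2 is defined"
        )
    shifted = counts + pseudocount
    totals = shifted.sum(axis=0)
    zero_total = totals[totals == 0]
    if len(zero_total):
        raise ValueError(
            f"sample(s) with zero total counts: {', '.join(map(str, zero_total.index))}"
        )
    fractions = shifted.div(totals, axis=1)
    return CountMatrix(values=np.log2(fractions), state=NORMALIZED)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

EXACT_PERMUTATION_MAX_N = 9  # exact p below this+1 samples (and no ties)


def _exact_spearman_p(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for untied ranks (n <= 9).

    Without ties rho is a monotone function of the sum of squared rank
    differences, so the permutation distribution is enumerated over all n!
    orderings of one margin.
    """
    n = len(rank_x)
    d2_obs = float(np.sum((rank_x - rank_y) ** 2))
    denom = n * (n * n - 1)
    rho_obs = 1.0 - 6.0 * d2_obs / denom
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    d2 = np.sum((perms - rank_x) ** 2, axis=1)
    rho = 1.0 - 6.0 * d2 / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p-value.

    Pairs with a missing value (NaN) in either vector are dropped.  Returns
    ``(nan, nan)`` for a constant vector (undefined rho — flagged, not
    raised).  Requires at least 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (math.nan, math.nan)

    rank_x = stats.rankdata(x)  # mid-ranks for ties
    rank_y = stats.rankdata(y)
    rho = float(np.corrcoef(rank_x, rank_y)[0, 1])

    has_ties = len(set(rank_x)) < n or len(set(rank_y)) < n
    if n <= EXACT_PERMUTATION_MAX_N and not has_ties:
        p = _exact_spearman_p(rank_x, rank_y)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return (rho, min(1.0, p))


@dataclass(frozen=True)
class CorrelationRecord:
    protein_a: str
    protein_b: str
    rho: float
    p_value: float
    n_used: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def correlate_with_reference(
    matrix: CountMatrix,
    reference: str,
    candidates: Sequence[str],
) -> list[CorrelationRecord]:
    """Spearman-correlate each candidate protein against a reference.

    Operates on a normalized matrix; one record per candidate, sorted by
    rho descending (undefined-rho records last).
    """
    if matrix.state != NORMALIZED:
        raise ValueError("correlate_with_reference expects a normalized matrix")
    missing = [p for p in [reference, *candidates] if p not in matrix.values.index]
    if missing:
        raise KeyError(f"protein(s) not in matrix: {', '.join(missing)}")
    ref = matrix.values.loc[reference].to_numpy(dtype=float)
    records = []
    for candidate in candidates:
        row = matrix.values.loc[candidate].to_numpy(dtype=float)
        n_used = int(np.sum(~(np.isnan(ref) | np.isnan(row))))
        rho, p = spearman(ref, row)
        records.append(CorrelationRecord(reference, candidate, rho, p, n_used))
    records.sort(key=lambda r: (-r.rho if r.defined else math.inf, r.protein_b))
    return records


def correlations_to_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_a, r.protein_b, r.rho, r.p_value, r.n_used) for r in records],
        columns=["reference", "candidate", "rho", "p_value", "n_used"],
    )


# ---------------------------------------------------------------------------
# 2-DE spot volumes
# ---------------------------------------------------------------------------

@dataclass
class SpotVolumeTable:
    """Long-format 2-DE spot volumes with per-gel background.

    ``data`` has columns ``spot, gel, group, volume, valid``; ``background``
    maps each gel to its background level.  ``state`` is "raw" until
    :func:`normalize_spot_volumes` converts volumes to per-gel fractions of
    the total valid-spot quantity.
    """

    data: pd.DataFrame
    background: dict[str, float]
    state: str = RAW

    REQUIRED = ("spot", "gel", "group", "volume", "valid")

    def __post_init__(self) -> None:
        for column in self.REQUIRED:
            if column not in self.data.columns:
                raise ValueError(f"spot table missing column {column!r}")
        missing = set(self.data["gel"]) - set(self.background)
        if missing:
            raise ValueError(
                f"no background value for gel(s): {', '.join(sorted(missing))}"
            )

    @classmethod
    def read_tsv(cls, spot_path, background_path, state: str = RAW) -> "SpotVolumeTable":
        data = pd.read_csv(spot_path, sep="\t")
        data["valid"] = data["valid"].astype(bool)
        bg = pd.read_csv(background_path, sep="\t")
        return cls(
            data=data,
            background=dict(zip(bg["gel"], bg["background"].astype(float))),
            state=state,
        )

    def to_tsv(self, spot_path, background_path) -> None:
        self.data.to_csv(spot_path, sep="\t", index=False)
        pd.DataFrame(
            sorted(self.background.items()), columns=["gel", "background"]
        ).to_csv(background_path, sep="\t", index=False)


def normalize_spot_volumes(table: SpotVolumeTable) -> SpotVolumeTable:
    """Background-subtract and normalize volumes per gel.

    Per gel: ``volume' = max(volume - background, 0)`` divided by the sum of
    corrected volumes over VALID spots of that gel.  Invalid spots are
    excluded from the denominator and their normalized volume is missing.
    """
    if table.state != RAW:
        raise ValueError("spot table is already normalized")
    data = table.data.copy()
    corrected = np.maximum(
        data["volume"].to_numpy(dtype=float)
        - data["gel"].map(table.background).to_numpy(dtype=float),
        0.0,
    )
    data["volume"] = corrected
    valid = data["valid"].to_numpy(dtype=bool)
    totals = data[valid].groupby("gel")["volume"].sum()
    bad = [gel for gel in data["gel"].unique() if totals.get(gel, 0.0) == 0.0]
    if bad:
        raise ValueError(
            f"gel(s) with zero total corrected valid volume: {', '.join(map(str, bad))}"
        )
    data["volume"] = data["volume"] / data["gel"].map(totals).to_numpy(dtype=float)
    data.loc[~valid, "volume"] = np.nan
    return SpotVolumeTable(data=data, background=dict(table.background), state=NORMALIZED)


def spot_t_test(table: SpotVolumeTable, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided pooled-variance Student t-test per spot between two groups.

    A spot is testable when both groups have >= 2 gels with non-missing
    normalized volumes; untestable spots are reported with
    ``testable = False`` rather than raised.  Returns a table with columns
    ``spot, group_a, group_b, mean_a, mean_b, t, p_value, significant,
    testable`` (significant iff testable and p <= alpha).
    """
    if table.state != NORMALIZED:
        raise ValueError("spot_t_test expects a normalized table")
    groups = sorted(table.data["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    rows = []
    for spot, chunk in table.data.groupby("spot", sort=True):
        a = chunk.loc[chunk["group"] == ga, "volume"].dropna().to_numpy(dtype=float)
        b = chunk.loc[chunk["group"] == gb, "volume"].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append((spot, ga, gb, np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            # identical constant groups: no variation at all
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            (
                spot,
                ga,
                gb,
                float(np.mean(a)),
                float(np.mean(b)),
                float(t_stat),
                float(p),
                bool(p <= alpha),
                True,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "spot",
            "group_a",
            "group_b",
            "mean_a",
            "mean_b",
            "t",
            "p_value",
            "significant",
            "testable",
        ],
    )
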