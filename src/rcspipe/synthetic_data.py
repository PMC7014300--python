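"""Synthetic pipeline inputs with known planted ground truth.

Every input the pipeline consumes can be generated here with a planted
structure whose recovery downstream is checkable:

* a STRING-dialect protein-links file in which each seed protein owns a
  high-confidence module (edges scored above the 700 cut), written with
  taxon prefixes and symmetric duplicate rows to exercise the reader;
* a GMT collection with one planted term per module (the module members
  plus random padding), null terms of assorted sizes, and at least one
  oversized term to exercise the 2000-gene cap;
* a protein-by-sample spectral-count matrix (default 95 samples, emulating
  a tumor-cohort spectral-count table) with unequal per-sample depths,
  negative-binomial marginals and Gaussian-copula-planted rank
  correlations;
* a 2-DE spot-volume table in replicate groups (default triplicates) with
  log-normally varying volumes and planted fold changes.

A single integer ``rng_seed`` determines all outputs; each generator draws
from its own fixed stream (``numpy.random.SeedSequence(rng_seed,
spawn_key=(stream,))``) so generators can be re-run independently without
perturbing each other.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TAXON_PREFIX = "9606."

_STREAM_NETWORK = 0
_STREAM_GENESETS = 1
_STREAM_COUNTS = 2
_STREAM_SPOTS = 3


def _rng(rng_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(rng_seed), spawn_key=(stream,))
    )


@dataclass
class PlantedModule:
    seed: str
    members: list[str]
    term_id: str


@dataclass
class SyntheticTruth:
    """Ground truth behind one set of generated inputs."""

    rng_seed: int
    planted_modules: list[PlantedModule] = field(default_factory=list)
    planted_correlations: list[tuple[str, str, float]] = field(default_factory=list)
    planted_spots: list[tuple[str, float]] = field(default_factory=list)
    proteins: list[str] = field(default_factory=list)
    seeds: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "planted_modules": [asdict(m) for m in self.planted_modules],
            "planted_correlations": [list(t) for t in self.planted_correlations],
            "planted_spots": [list(t) for t in self.planted_spots],
            "proteins": self.proteins,
            "seeds": self.seeds,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")


# ---------------------------------------------------------------------------
# STRING-like network
# ---------------------------------------------------------------------------

def generate_network(
    path,
    n_proteins: int = 400,
    n_seeds: int = 8,
    module_size: int = 18,
    background_edge_prob: float = 0.005,
    score_ranges: tuple[tuple[int, int], tuple[int, int]] = ((701, 1000), (150, 700)),
    rng_seed: int = 0,
    module_sizes: Sequence[int] | None = None,
    member_edge_prob: float = 0.3,
) -> SyntheticTruth:
    """Write a STRING-dialect links file with one planted module per seed.

    Seeds are the first ``n_seeds`` proteins; each owns ``module_size``
    dedicated neighbors (``module_sizes`` overrides per seed, e.g. to plant
    under-connected seeds that the minimum-neighbor rule should discard)
    connected at scores drawn from the in-module range.  Background edges
    between random pairs are drawn at ``background_edge_prob`` from the
    background score range, which by default stays at or below 700 so the
    planted neighborhoods are exactly the post-filter neighborhoods.  The
    file carries taxon prefixes and both orientations of every pair.
    """
    (lo_in, hi_in), (lo_bg, hi_bg) = score_ranges
    if not (0 <= lo_bg <= hi_bg <= 1000 and 0 <= lo_in <= hi_in <= 1000):
        raise ValueError("score ranges must lie within [0, 1000]")
    if lo_in <= 700:
        raise ValueError("in-module score range must sit entirely above 700")
    sizes = list(module_sizes) if module_sizes is not None else [module_size] * n_seeds
    if len(sizes) != n_seeds:
        raise ValueError(f"module_sizes has {len(sizes)} entries for {n_seeds} seeds")
    if n_proteins < n_seeds + sum(sizes):
        raise ValueError(
            f"n_proteins={n_proteins} too small for {n_seeds} seeds with "
            f"disjoint modules totalling {sum(sizes)} members"
        )

    rng = _rng(rng_seed, _STREAM_NETWORK)
    proteins = [f"GENE{i:04d}" for i in range(1, n_proteins + 1)]
    seeds = proteins[:n_seeds]
    truth = SyntheticTruth(rng_seed=rng_seed, proteins=proteins, seeds=seeds)

    edges: dict[tuple[str, str], int] = {}

    def put(a: str, b: str, score: int) -> None:
        key = (a, b) if a < b else (b, a)
        edges[key] = max(score, edges.get(key, 0))

    cursor = n_seeds
    for seed, size in zip(seeds, sizes):
        members = proteins[cursor : cursor + size]
        cursor += size
        for member in members:
            put(seed, member, int(rng.integers(lo_in, hi_in + 1)))
        for i in range(len(members)):  # intra-module edges, high confidence
            for j in range(i + 1, len(members)):
                if rng.random() < member_edge_prob:
                    put(members[i], members[j], int(rng.integers(lo_in, hi_in + 1)))
        truth.planted_modules.append(
            PlantedModule(seed=seed, members=members, term_id=f"PLANTED_{seed}")
        )

    if background_edge_prob > 0:
        n_bg = rng.binomial(n_proteins * (n_proteins - 1) // 2, background_edge_prob)
        for _ in range(int(n_bg)):
            i, j = rng.choice(n_proteins, size=2, replace=False)
            put(proteins[i], proteins[j], int(rng.integers(lo_bg, hi_bg + 1)))

    with open(path, "w") as handle:
        handle.write("protein1 protein2 combined_score\n")
        for (a, b), score in sorted(edges.items()):
            handle.write(f"{TAXON_PREFIX}{a} {TAXON_PREFIX}{b} {score}\n")
            handle.write(f"{TAXON_PREFIX}{b} {TAXON_PREFIX}{a} {score}\n")
    return truth


# ---------------------------------------------------------------------------
# Gene-set collection
# ---------------------------------------------------------------------------

def generate_genesets(
    path,
    truth: SyntheticTruth,
    universe_size: int = 3000,
    n_null_terms: int = 60,
    null_size_range: tuple[int, int] = (10, 2500),
    planted_padding: int = 15,
    rng_seed: int = 0,
) -> list[str]:
    """Write a GMT collection with one planted term per planted module.

    Planted terms contain the module's seed and members plus
    ``planted_padding`` random filler genes.  Null terms draw their sizes
    log-uniformly from ``null_size_range``; when the range and universe
    allow, at least one term above 2000 genes is guaranteed so the size
    filter has something to remove.  Returns the gene universe.
    """
    if universe_size < len(truth.proteins):
        raise ValueError("universe must cover all network proteins")
    rng = _rng(rng_seed, _STREAM_GENESETS)
    filler = [f"FILL{i:05d}" for i in range(1, universe_size - len(truth.proteins) + 1)]
    universe = truth.proteins + filler
    lo, hi = null_size_range
    hi = min(hi, universe_size)
    lines = []
    for module in truth.planted_modules:
        genes = [module.seed, *module.members]
        pad = rng.choice(filler, size=min(planted_padding, len(filler)), replace=False)
        lines.append((module.term_id, f"planted term for {module.seed}", genes + list(pad)))
    sizes = np.exp(
        rng.uniform(math.log(lo), math.log(hi), size=n_null_terms)
    ).astype(int)
    sizes = np.clip(sizes, lo, hi)
    if hi > 2000 and n_null_terms and not (sizes > 2000).any():
        sizes[0] = hi  # guarantee one oversized term
    for idx, size in enumerate(sizes, start=1):
        members = rng.choice(universe, size=int(size), replace=False)
        lines.append((f"NULL{idx:04d}", f"null term {idx}", list(members)))
    with open(path, "w") as handle:
        for term_id, description, genes in lines:
            handle.write("\t".join([term_id, description, *genes]) + "\n")
    return universe


# ---------------------------------------------------------------------------
# Spectral-count matrix
# ---------------------------------------------------------------------------

def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent Gaussian correlation that induces a target Spearman rho.

    For a bivariate Gaussian copula, ``rho_s = (6/pi) * arcsin(rho_p / 2)``;
    inverting gives the latent Pearson correlation to plant.
    """
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_counts(
    path,
    truth: SyntheticTruth | None = None,
    n_proteins: int = 120,
    n_samples: int = 95,
    dispersion: float = 0.3,
    depth_range: tuple[int, int] = (20000, 60000),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Write a protein-by-sample spectral-count TSV with planted correlations.

    Marginals are negative binomial around depth-scaled abundances (depths
    drawn per sample from ``depth_range`` so totals are unequal and
    normalization matters; protein weights span ~3.5 decades so zeros occur
    at the low end).  Dependence for pairs listed in
    ``truth.planted_correlations`` is a Gaussian copula calibrated so the
    population Spearman correlation equals the planted value: counts are
    the NB quantile of the Gaussian CDF of correlated latent normals.
    Pairs may share their first protein (a common reference hub); a second
    protein may appear in only one pair.
    """
    if not -1e-9 <= dispersion:
        raise ValueError("dispersion must be non-negative")
    planted = list(truth.planted_correlations) if truth is not None else []
    for _, _, r in planted:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target rank correlation {r} outside [-1, 1]")
    b_names = [b for _, b, _ in planted]
    a_names = list(dict.fromkeys(a for a, _, _ in planted))
    if len(set(b_names)) != len(b_names) or set(b_names) & set(a_names):
        raise ValueError(
            "planted pairs must be disjoint apart from a shared first protein"
        )

    rng = _rng(rng_seed, _STREAM_COUNTS)
    special = a_names + b_names
    background = [f"PROT{i:04d}" for i in range(1, n_proteins + 1)]
    background = [p for p in background if p not in special]
    proteins = special + background
    m, s = len(proteins), n_samples

    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=s)
    # relative abundance weights, log-uniform; planted proteins sit high so
    # sampling zeros/ties do not erode the planted rank correlation
    log_w = rng.uniform(-2.0, 1.5, size=m)
    log_w[: len(special)] = rng.uniform(0.8, 1.5, size=len(special))
    weights = 10.0 ** log_w
    weights /= weights.sum()

    # latent Gaussian field with the copula structure
    z = rng.standard_normal(size=(m, s))
    index = {p: i for i, p in enumerate(proteins)}
    for a, b, r in planted:
        rho_latent = spearman_to_pearson_latent(r)
        za = z[index[a]]
        eps = rng.standard_normal(size=s)
        z[index[b]] = rho_latent * za + math.sqrt(1.0 - rho_latent**2) * eps

    mu = np.outer(weights, depths)
    u = stats.norm.cdf(z)
    if dispersion <= 1e-12:
        counts = stats.poisson.ppf(u, mu)
    else:
        r_nb = 1.0 / dispersion
        p_nb = r_nb / (r_nb + mu)
        counts = stats.nbinom.ppf(u, r_nb, p_nb)
    frame = pd.DataFrame(
        counts.astype(int),
        index=pd.Index(proteins, name="protein"),
        columns=[f"SAMPLE{j:03d}" for j in range(1, s + 1)],
    )
    frame.to_csv(path, sep="\t")
    return frame


# ---------------------------------------------------------------------------
# 2-DE spot table
# ---------------------------------------------------------------------------

def generate_spot_table(
    spot_path,
    background_path,
    n_spots: int = 96,
    n_planted: int = 8,
    fold_changes: float | Sequence[float] = 4.0,
    cv: float = 0.2,
    replicates: int = 3,
    rng_seed: int = 0,
    groups: tuple[str, str] = ("control", "modulated"),
    invalid_frac: float = 0.0,
) -> SyntheticTruth:
    """Write a long-format spot-volume TSV plus per-gel background TSV.

    Volumes are log-normal around spot-specific baselines with coefficient
    of variation ``cv``; the first ``n_planted`` spots are multiplied by
    their fold change in the second group.  Per-gel background is added to
    every emitted volume so that background subtraction recovers the
    simulated signal.  ``truth.planted_spots`` records (spot, fold change).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicate gels per group")
    if np.isscalar(fold_changes):
        fcs = [float(fold_changes)] * n_planted
    else:
        fcs = [float(f) for f in fold_changes]
        if len(fcs) != n_planted:
            raise ValueError("one fold change per planted spot required")
    rng = _rng(rng_seed, _STREAM_SPOTS)
    truth = SyntheticTruth(rng_seed=rng_seed)
    spots = [f"SPOT{i:03d}" for i in range(1, n_spots + 1)]
    truth.planted_spots = list(zip(spots[:n_planted], fcs))
    gels = [f"{g}_{r}" for g in groups for r in range(1, replicates + 1)]
    gel_group = {gel: gel.rsplit("_", 1)[0] for gel in gels}
    background = {gel: float(rng.uniform(10.0, 50.0)) for gel in gels}

    sigma = math.sqrt(math.log(1.0 + cv * cv))
    base = 10.0 ** rng.uniform(3.0, 5.0, size=n_spots)
    # planted spots sit in the lower-abundance half so the fold change
    # barely shifts per-gel totals; otherwise total-quantity normalization
    # would induce compositional significance in unchanged spots
    base[:n_planted] = 10.0 ** rng.uniform(3.0, 4.0, size=n_planted)
    rows = []
    for i, spot in enumerate(spots):
        fc = fcs[i] if i < n_planted else 1.0
        for gel in gels:
            level = base[i] * (fc if gel_group[gel] == groups[1] else 1.0)
            volume = level * math.exp(rng.normal(0.0, sigma) - sigma * sigma / 2.0)
            valid = rng.random() >= invalid_frac
            rows.append(
                (spot, gel, gel_group[gel], round(volume + background[gel], 4), valid)
            )
    pd.DataFrame(rows, columns=["spot", "gel", "group", "volume", "valid"]).to_csv(
        spot_path, sep="\t", index=False
    )
    pd.DataFrame(
        sorted(background.items()), columns=["gel", "background"]
    ).to_csv(background_path, sep="\t", index=False, float_format="%.4f")
    return truth


# ---------------------------------------------------------------------------
# One-call fixture set
# ---------------------------------------------------------------------------

def simulate_all(
    outdir,
    rng_seed: int = 0,
    n_proteins: int = 400,
    n_seeds: int = 10,
    n_underconnected: int = 3,
    module_size: int = 18,
    universe_size: int = 3000,
    n_samples: int = 95,
) -> SyntheticTruth:
    """Generate a complete, mutually consistent input set under ``outdir``.

    Produces ``network.tsv``, ``genesets.gmt``, ``counts.tsv``,
    ``spots.tsv`` + ``background.tsv``, ``seeds.txt`` and ``truth.json``.
    The last ``n_underconnected`` seeds get 9-member modules (below the
    default minimum of 10 eligible neighbors) so the discard rule always
    has work to do; the first seed doubles as the reference protein for two
    planted correlations (0.6 and 0.0).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if n_underconnected >= n_seeds:
        raise ValueError("need at least one well-connected seed")
    sizes = [module_size] * (n_seeds - n_underconnected) + [9] * n_underconnected
    truth = generate_network(
        outdir / "network.tsv",
        n_proteins=n_proteins,
        n_seeds=n_seeds,
        module_sizes=sizes,
        rng_seed=rng_seed,
    )
    generate_genesets(
        outdir / "genesets.gmt",
        truth,
        universe_size=universe_size,
        rng_seed=rng_seed,
    )
    ref, c1, c2 = truth.seeds[0], truth.seeds[1], truth.seeds[2]
    truth.planted_correlations = [(ref, c1, 0.6), (ref, c2, 0.0)]
    generate_counts(
        outdir / "counts.tsv",
        truth=truth,
        n_samples=n_samples,
        rng_seed=rng_seed,
    )
    spot_truth = generate_spot_table(
        outdir / "spots.tsv",
        outdir / "background.tsv",
        rng_seed=rng_seed,
    )
    truth.planted_spots = spot_truth.planted_spots
    with open(outdir / "seeds.txt", "w") as handle:
        handle.write("# synthetic seed proteins\n")
        for seed in truth.seeds:
            handle.write(seed + "\n")
    truth.to_json(outdir / "truth.json")
    return truth
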