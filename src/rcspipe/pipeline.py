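"""End-to-end orchestration: network → RCS catalog → per-RCS ORA →
aggregation, plus the count-correlation and spot-test arms.

A :class:`RunConfig` collects the input paths and the analysis parameters
(defaults match the procedure's standard values: score threshold 700, RCS
size 15, minimum 10 neighbors, term sizes 10–2000, p/q cutoffs 0.05,
pseudocount 0.5, spot-test alpha 0.05).  :func:`run_all` executes the
stages in dependency order, writes every stage's output before the next
begins, and finishes with a manifest recording input checksums, effective
parameters and per-stage row counts.  Identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aggregate import aggregate_enrichments, term_seed_matrix, to_edge_list
from .genesets import filter_by_size, read_gmt
from .ora import EnrichmentRecord, EnrichmentResult, enrich_rcs, results_to_frame
from .ppi_io import read_id_mapping, read_string_edges, write_edges
from .quant_stats import (
    CountMatrix,
    SpotVolumeTable,
    correlate_with_reference,
    correlations_to_frame,
    normalize_counts,
    normalize_spot_volumes,
    spot_t_test,
)
from .rcs import build_catalog, read_seed_list

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"  # fixed float rendering keeps outputs byte-stable


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    # inputs
    network: str | None = None
    id_mapping: str | None = None
    seed_lists: list[str] = field(default_factory=list)
    gmt_files: dict[str, str] = field(default_factory=dict)
    count_matrix: str | None = None
    reference: str | None = None
    candidates: list[str] = field(default_factory=list)
    spot_table: str | None = None
    spot_background: str | None = None
    # parameters (defaults are the procedure's standard values)
    score_threshold: int = 700
    rcs_size: int = 15
    min_neighbors: int = 10
    term_min_size: int = 10
    term_max_size: int = 2000
    p_cut: float = 0.05
    q_cut: float = 0.05
    pseudocount: float = 0.5
    alpha: float = 0.05
    rng_seed: int = 0
    outdir: str = "rcspipe_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)

    def input_paths(self) -> dict[str, str]:
        paths = {}
        if self.network:
            paths["network"] = self.network
        if self.id_mapping:
            paths["id_mapping"] = self.id_mapping
        for i, p in enumerate(self.seed_lists):
            paths[f"seed_list_{i}"] = p
        for name, p in self.gmt_files.items():
            paths[f"gmt_{name}"] = p
        for key in ("count_matrix", "spot_table", "spot_background"):
            value = getattr(self, key)
            if value:
                paths[key] = value
        return paths


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage and return the manifest dict.

    Stages with unset inputs are skipped and recorded as such.  A stage
    failure aborts the run with :class:`PipelineError`; outputs written so
    far are retained and the manifest is written with a FAILED marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for name, path in config.input_paths().items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} does not exist: {path}")

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rcspipe")
    root.addHandler(log_handler)

    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {k: _sha256(v) for k, v in config.input_paths().items()},
        "stages": {},
        "status": "RUNNING",
    }
    config.to_yaml(outdir / "config_effective.yaml")

    stage = "setup"
    try:
        results: list[EnrichmentResult] = []
        if config.network:
            stage = "network"
            mapping = read_id_mapping(config.id_mapping) if config.id_mapping else None
            network = read_string_edges(
                config.network, config.score_threshold, id_mapping=mapping
            )
            write_edges(network, outdir / "network_filtered.tsv")
            manifest["stages"]["network"] = {
                "n_nodes": len(network.nodes),
                "n_edges": len(network.edges),
                "report": dataclasses.asdict(network.report),
            }

            stage = "catalog"
            seeds: list[str] = []
            for path in config.seed_lists:
                seeds.extend(read_seed_list(path))
            catalog = build_catalog(
                network, seeds, config.rcs_size, config.min_neighbors
            )
            catalog.to_tsv(outdir / "catalog.tsv")
            catalog.to_json(outdir / "catalog.json")
            manifest["stages"]["catalog"] = {
                "n_seeds": catalog.n_retained + catalog.n_discarded,
                "n_retained": catalog.n_retained,
                "n_discarded": catalog.n_discarded,
                "discard_report": [
                    {"seed": s, "n_eligible": n} for s, n in catalog.discard_report
                ],
            }

            stage = "enrichment"
            for name, gmt_path in sorted(config.gmt_files.items()):
                collection = filter_by_size(
                    read_gmt(gmt_path, name=name),
                    max_size=config.term_max_size,
                    min_size=config.term_min_size,
                )
                for rcs in catalog.rcs_list:
                    results.append(
                        enrich_rcs(rcs, collection, config.p_cut, config.q_cut)
                    )
            enrichment = results_to_frame(results)
            enrichment.to_csv(
                outdir / "enrichment.tsv",
                sep="\t",
                index=False,
                float_format=FLOAT_FORMAT,
            )
            manifest["stages"]["enrichment"] = {
                "n_pairs": len(results),
                "n_records": int(len(enrichment)),
                "n_significant": int(
                    sum(len(r.significant) for r in results)
                ),
            }

            stage = "aggregate"
            frequency = aggregate_enrichments(results)
            frequency.to_csv(outdir / "term_frequency.tsv", sep="\t", index=False)
            matrix = term_seed_matrix(results)
            to_edge_list(matrix).to_csv(
                outdir / "term_seed_edges.tsv", sep="\t", index=False
            )
            manifest["stages"]["aggregate"] = {
                "n_terms": int(len(frequency)),
                "total_support": int(frequency["frequency"].sum())
                if len(frequency)
                else 0,
            }

        if config.count_matrix and config.reference:
            stage = "correlation"
            matrix = normalize_counts(
                CountMatrix.read_tsv(config.count_matrix),
                pseudocount=config.pseudocount,
            )
            candidates = config.candidates or [
                p for p in matrix.proteins if p != config.reference
            ]
            records = correlate_with_reference(matrix, config.reference, candidates)
            correlations_to_frame(records).to_csv(
                outdir / "correlations.tsv",
                sep="\t",
                index=False,
                float_format=FLOAT_FORMAT,
            )
            manifest["stages"]["correlation"] = {
                "n_candidates": len(records),
                "n_significant": sum(
                    1 for r in records if r.defined and r.p_value <= config.alpha
                ),
            }

        if config.spot_table and config.spot_background:
            stage = "spot_test"
            table = normalize_spot_volumes(
                SpotVolumeTable.read_tsv(config.spot_table, config.spot_background)
            )
            tests = spot_t_test(table, alpha=config.alpha)
            tests.to_csv(
                outdir / "spot_tests.tsv",
                sep="\t",
                index=False,
                float_format=FLOAT_FORMAT,
            )
            manifest["stages"]["spot_test"] = {
                "n_spots": int(len(tests)),
                "n_untestable": int((~tests["testable"]).sum()),
                "n_significant": int(tests["significant"].sum()),
            }

        manifest["status"] = "OK"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, outdir)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        log_handler.close()

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
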