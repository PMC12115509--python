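"""End-to-end orchestration: config validation, the full multimetric
workflow, and a manifest of produced artifacts.

A run computes each requested metric's all-against-all matrix, writes the
matrix TSV, clustered heatmap (JPG + SVG), dendrogram Newick and frequency
table/plot, then (when bounds are configured) partitions the dataset and
writes per-cluster outputs.  Runs are fully reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import yaml

from . import evodist, pairwise, seqio, structcmp, viz
from .partition import partition as partition_dataset, write_partition_outputs

__all__ = ["RunConfig", "validate_config", "run", "ALL_METRICS"]

ALL_METRICS = ["identity_pct", "similarity_pct", "ml_distance", "tm_score", "threedi_similarity_pct"]

logger = logging.getLogger("mpact")


@dataclass
class RunConfig:
    """The workflow switchboard.  Structure metrics require structure input;
    ml_distance requires sequences (self-contained MSA), an external MSA, or
    an external tree."""

    metrics: list[str] = field(default_factory=lambda: ["identity_pct", "similarity_pct"])
    sequences: str | None = None
    alphabet: str = "amino_acid"
    structures: list[str] = field(default_factory=list)
    threedi_sequences: str | None = None
    msa: str | None = None
    tree: str | None = None
    model: str | None = None
    gap_open: float = pairwise.DEFAULT_GAP_OPEN
    gap_extend: float = pairwise.DEFAULT_GAP_EXTEND
    end_gaps_penalized: bool = False
    bounds: dict[str, list[float]] = field(default_factory=dict)
    partition_mode: str = "clades"
    ladderize_key: str = "height"
    out_dir: str = "./mpact_out"
    seed: int = 0
    log_level: str = "INFO"

    def errors(self) -> list[str]:
        errs = []
        if not self.metrics:
            errs.append("at least one metric must be requested")
        for metric in self.metrics:
            if metric not in ALL_METRICS:
                errs.append(f"unknown metric {metric!r}")
        if self.alphabet not in seqio.ALPHABETS:
            errs.append(f"unknown alphabet {self.alphabet!r}")
        seq_metrics = {"identity_pct", "similarity_pct", "ml_distance"} & set(self.metrics)
        if seq_metrics and not (self.sequences or self.msa or (self.tree and self.metrics == ["ml_distance"])):
            errs.append(f"metrics {sorted(seq_metrics)} require sequence input")
        if "tm_score" in self.metrics and not self.structures:
            errs.append("metric tm_score requires structure (PDB) input")
        if "threedi_similarity_pct" in self.metrics and not self.threedi_sequences:
            errs.append("metric threedi_similarity_pct requires 3Di sequence input")
        for metric, bnds in self.bounds.items():
            if metric not in ALL_METRICS:
                errs.append(f"bounds given for unknown metric {metric!r}")
            elif len(bnds) != 2 or bnds[0] > bnds[1]:
                errs.append(f"invalid bounds for metric {metric!r}: lower must be <= upper")
        if self.partition_mode not in ("clades", "runs"):
            errs.append(f"unknown partition mode {self.partition_mode!r}")
        return errs


def validate_config(path) -> RunConfig:
    """Load and validate a YAML config; raises ValueError listing every
    problem found.  Defaults are filled and echoed into the run directory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    errs = [f"unknown config key {k!r}" for k in sorted(unknown)]
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    errs += cfg.errors()
    if errs:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errs))
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _compute_matrix(metric: str, cfg: RunConfig, cache: dict) -> seqio.PairMatrix:
    if metric in ("identity_pct", "similarity_pct"):
        if "seq_matrices" not in cache:
            records = cache["records"]
            logger.info("aligning %d sequences all-against-all", len(records))
            cache["seq_matrices"] = pairwise.all_vs_all_sequences(
                records,
                gap_open=cfg.gap_open,
                gap_extend=cfg.gap_extend,
                end_gaps_penalized=cfg.end_gaps_penalized,
            )
        ident, simil = cache["seq_matrices"]
        return ident if metric == "identity_pct" else simil
    if metric == "ml_distance":
        if cfg.tree:
            logger.info("patristic mode: reading tree %s", cfg.tree)
            return evodist.patristic_matrix(seqio.read_newick(cfg.tree))
        if cfg.msa:
            msa = seqio.read_msa(cfg.msa, cfg.alphabet)
        else:
            logger.info("no MSA supplied: building progressive MSA")
            msa = evodist.progressive_msa(cache["records"])
        model = cfg.model or ("JC69" if cfg.alphabet == "nucleotide" else "Poisson")
        return evodist.ml_distance_matrix(msa, model)
    if metric == "tm_score":
        chains = [seqio.read_pdb_ca(p) for p in cfg.structures]
        logger.info("comparing %d structures all-against-all", len(chains))
        return structcmp.all_vs_all_structures(chains)
    if metric == "threedi_similarity_pct":
        records = seqio.read_fasta(cfg.threedi_sequences, "threedi")
        return pairwise.threedi_similarity(
            records,
            gap_open=cfg.gap_open,
            gap_extend=cfg.gap_extend,
            end_gaps_penalized=cfg.end_gaps_penalized,
        )
    raise ValueError(f"unknown metric {metric!r}")


def run(cfg: RunConfig) -> dict:
    """Execute the workflow; returns the manifest (also written as JSON)."""
    errs = cfg.errors()
    if errs:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errs))
    os.makedirs(cfg.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    t0 = time.time()

    # echo the fully defaulted config so runs are self-documenting
    echo_path = os.path.join(cfg.out_dir, "config_echo.yml")
    with open(echo_path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)

    cache: dict = {}
    if cfg.sequences:
        cache["records"] = seqio.read_fasta(cfg.sequences, cfg.alphabet)

    artifacts: list[str] = [echo_path]
    results: dict = {"metrics": {}}
    for metric in cfg.metrics:
        stage_t = time.time()
        try:
            matrix = _compute_matrix(metric, cfg, cache)
        except Exception as exc:
            raise RuntimeError(f"stage {metric!r} failed: {exc}") from exc
        prefix = os.path.join(cfg.out_dir, metric)
        mat_path = f"{prefix}_matrix.tsv"
        seqio.write_matrix(matrix, mat_path)
        heat = viz.clustered_heatmap(matrix, prefix)
        freq = viz.frequency_plot(matrix, out_prefix=prefix)
        artifacts += [mat_path, *heat["paths"].values(),
                      f"{prefix}_freq.tsv", f"{prefix}_freq.jpg", f"{prefix}_freq.svg"]
        results["metrics"][metric] = {"n": matrix.n, "matrix": mat_path}

        if metric in cfg.bounds:
            lower, upper = cfg.bounds[metric]
            pset = partition_dataset(matrix, lower, upper, mode=cfg.partition_mode)
            part_dir = os.path.join(cfg.out_dir, f"partition_{metric}")
            records = cache.get("records", [])
            if metric == "threedi_similarity_pct" and cfg.threedi_sequences:
                records = seqio.read_fasta(cfg.threedi_sequences, "threedi")
            if records and set(r.id for r in records) >= set(pset.labels):
                paths = write_partition_outputs(pset, records, part_dir, matrix)
                artifacts += paths["fasta"] + [paths["membership"]]
                if "tree" in paths:
                    artifacts.append(paths["tree"])
            results["metrics"][metric]["n_clusters"] = len(pset.clusters)
            results["metrics"][metric]["clusters"] = pset.clusters
        logger.info("stage %s done in %.1fs", metric, time.time() - stage_t)

    manifest = {
        "config": asdict(cfg),
        "results": results,
        "artifacts": [
            {"path": p, "sha256": _sha256(p)} for p in artifacts if os.path.exists(p)
        ],
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
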