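"""End-to-end pipeline orchestration: simulate -> profile -> score -> species.

A single plain-text (YAML) config drives every stage with one global seed,
deterministically partitioned per stage so stages can also run standalone
reproducibly. Every run writes a machine-readable manifest with the config
hash, the seed, and a SHA-256 checksum of each output; re-running the same
config yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import cross_species, definition_score, end_profile, synthetic_data
from .io_formats import Interval, IntervalSet, write_reads

logger = logging.getLogger(__name__)

__all__ = ["load_config", "stage_seed", "run_pipeline"]

_STAGE_INDEX = {"simulate": 0, "endprofile": 1, "score": 2, "species": 3}


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    return config


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    ss = np.random.SeedSequence((int(seed), _STAGE_INDEX[stage]))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run all configured stages in dependency order; return the output manifest.

    Config keys: ``seed`` (int), ``out_dir``, and optional per-stage mappings
    ``simulate`` (cluster length, cleavage fold, trimming, chain count),
    ``score`` (window/gate/bins), ``species`` (library-table grid). Missing
    stage sections use the stage defaults. The config is validated before any
    stage runs, so an invalid config produces no partial outputs.
    """
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir or config.get("out_dir", "pistop_out"))
    sim_cfg = dict(config.get("simulate", {}))
    score_cfg = dict(config.get("score", {}))
    species_cfg = dict(config.get("species", {}))
    for section, allowed in (
        (sim_cfg, {"length", "fold", "trimming", "n_initiations", "cpg_depletion"}),
        (score_cfg, {"upstream_window", "downstream_window", "min_local_reads", "n_bins"}),
        (species_cfg, {"n_species", "libraries_per_species", "effect", "depth"}),
    ):
        unknown = set(section) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- simulate ---------------------------------------------------------
    sim_seed = stage_seed(seed, "simulate")
    comp = synthetic_data.CompositionModel(
        cpg_depletion=float(sim_cfg.get("cpg_depletion", 0.25))
    )
    cluster = synthetic_data.generate_cluster(
        length=int(sim_cfg.get("length", 20_000)), model=comp, seed=sim_seed
    )
    model = synthetic_data.CleavageModel.stop_preference(
        fold=float(sim_cfg.get("fold", 4.0))
    )
    reads, truth = synthetic_data.simulate_phased_reads(
        cluster,
        model,
        n_initiations=int(sim_cfg.get("n_initiations", 2000)),
        trimming=str(sim_cfg.get("trimming", "untrimmed")),
        seed=sim_seed,
    )
    (name,) = cluster.keys()
    cluster.to_fasta(out_dir / "cluster.fa")
    write_reads(reads, out_dir / "reads.bed")
    truth_df = truth.cleavage_model.weight_vector().rename("weight").to_frame()
    truth_df.index.name = "trinucleotide"
    truth_df.to_csv(out_dir / "truth_weights.tsv", sep="\t")
    outputs["cluster_fasta"] = out_dir / "cluster.fa"
    outputs["reads_bed"] = out_dir / "reads.bed"
    outputs["truth_weights"] = out_dir / "truth_weights.tsv"
    logger.info("simulate: %d reads from %d chains", len(reads), truth.n_chains)

    # --- end profile ------------------------------------------------------
    table = end_profile.tabulate_five_prime(
        reads, cluster, window=end_profile.LengthWindow(15, 70),
        seed=stage_seed(seed, "endprofile"), library="simulated",
    )
    table.to_tsv(out_dir / "five_prime_table.tsv")
    outputs["five_prime_table"] = out_dir / "five_prime_table.tsv"

    # --- definition score -------------------------------------------------
    cfg = definition_score.ScoreConfig(
        upstream_window=int(score_cfg.get("upstream_window", 10)),
        downstream_window=int(score_cfg.get("downstream_window", 20)),
        min_local_reads=int(score_cfg.get("min_local_reads", 100)),
        n_bins=int(score_cfg.get("n_bins", 20)),
    )
    regions = IntervalSet([Interval(name, 0, len(cluster[name]), "+", name)])
    scored = definition_score.compute_scores(reads, regions, cfg)
    binned = definition_score.bin_positions(scored, cfg)
    binned.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
    outputs["scores"] = out_dir / "scores.tsv"
    context = definition_score.score_by_context(scored, cluster, "trinucleotide")
    context.to_csv(out_dir / "score_by_context.tsv", sep="\t")
    outputs["score_by_context"] = out_dir / "score_by_context.tsv"

    # --- cross-species ----------------------------------------------------
    tables = synthetic_data.simulate_library_tables(
        n_species=int(species_cfg.get("n_species", 5)),
        libraries_per_species=int(species_cfg.get("libraries_per_species", 2)),
        effect=float(species_cfg.get("effect", 2.0)),
        depth=int(species_cfg.get("depth", 100_000)),
        seed=stage_seed(seed, "species"),
    )
    summaries = [cross_species.summarize_library(t) for t in tables]
    rows = [
        {
            "library": s.table.metadata.get("library"),
            "species": s.species,
            "tissue": s.tissue,
            "class": s.taxon_class,
            "one_u_fraction": s.one_u_fraction,
            "stop_ratio": s.stop_ratio.ratio,
            "robustness": s.robustness,
        }
        for s in summaries
    ]
    import pandas as pd

    pd.DataFrame.from_records(rows).to_csv(
        out_dir / "library_summaries.tsv", sep="\t", index=False
    )
    outputs["library_summaries"] = out_dir / "library_summaries.tsv"

    manifest = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
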