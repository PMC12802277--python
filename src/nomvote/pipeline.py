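"""Configuration handling and the end-to-end pipeline driver.

A single YAML config file (flat key-value sections per stage) plus one
master seed reproduces a whole in-silico study: raw-community synthesis,
dilution-cultivation-sequencing, the occurrence analysis, and optional
consumer-resource campaigns.  Every stage writes TSV artifacts plus a
machine-readable JSON manifest recording versions, seeds, thresholds and
per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crm, occurrence as occ, synthetic
from .otu_table import OtuTable

__all__ = [
    "PipelineConfig",
    "load_config",
    "occurrence_analysis",
    "write_occurrence_outputs",
    "run_pipeline",
]

log = logging.getLogger("nomvote")

RAW_SEQ_DEPTH = 50000  # reads used to render the raw community as counts


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run, with study-scale defaults."""

    out_dir: str = "nomvote_out"
    seed: int = 0
    # occurrence thresholds
    min_reads: int = 5000
    dominance_threshold: float = occ.DOMINANCE_THRESHOLD
    min_occurrence: int = 10
    top_n: int = 5
    # stage sub-specs
    raw_community: synthetic.RawCommunitySpec = field(
        default_factory=synthetic.RawCommunitySpec
    )
    dilution: synthetic.DilutionSpec = field(default_factory=synthetic.DilutionSpec)
    cultivation: synthetic.CultivationSpec = field(
        default_factory=synthetic.CultivationSpec
    )
    # optional simulation campaigns
    run_crm: bool = False
    crm_replicates: int = 25
    crm_resource_levels: tuple = (1, 5, 10, 20)
    crm_targeted: int = 10

    def validate(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not 0 < self.dominance_threshold < 1:
            raise ValueError("dominance_threshold must lie in (0, 1)")
        if self.min_occurrence < 0:
            raise ValueError("min_occurrence must be >= 0")
        self.raw_community.validate()
        self.dilution.validate()
        self.cultivation.validate()


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a sectioned YAML file.

    Unknown keys raise, so typos do not silently fall back to defaults.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    section_types = {
        "raw_community": synthetic.RawCommunitySpec,
        "dilution": synthetic.DilutionSpec,
        "cultivation": synthetic.CultivationSpec,
    }
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, value in doc.items():
        if key in section_types:
            spec = getattr(cfg, key)
            valid = {f.name for f in dataclasses.fields(section_types[key])}
            for k, v in (value or {}).items():
                if k not in valid:
                    raise ValueError(f"unknown key {k!r} in section {key!r}")
                if isinstance(v, list):
                    v = tuple(v)
                setattr(spec, k, v)
        elif key in top_fields:
            if isinstance(value, list):
                value = tuple(value)
            setattr(cfg, key, value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


def occurrence_analysis(
    table: OtuTable,
    raw_profile: occ.CommunityProfile,
    min_reads: int = 5000,
    threshold: float = occ.DOMINANCE_THRESHOLD,
    min_occurrence: int = 10,
    top_n: int = 5,
) -> dict:
    """Run the full occurrence stage on an OTU table; returns all artifacts."""
    filtered = occ.filter_low_depth(table, min_reads)
    profiles = occ.label_status(filtered, threshold)
    parts = occ.partition_raw_vs_subs(raw_profile, profiles)
    turnover = occ.classify_turnover(raw_profile, profiles)
    universe = sorted(parts.universe)
    groups = occ.group_by_dominance_frequency(turnover, universe=universe)
    poc = occ.poc_table(profiles, min_occurrence)
    pairs = occ.pair_interactions(profiles, min_occurrence)
    ranks = occ.rank_top_n(profiles, top_n)
    return {
        "filtered": filtered,
        "n_removed_samples": table.n_samples - filtered.n_samples,
        "profiles": profiles,
        "partition": parts,
        "turnover": turnover,
        "groups": groups,
        "poc": poc,
        "pairs": pairs,
        "ranks": ranks,
    }


def write_occurrence_outputs(out_dir, results: dict) -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(name: str, df: pd.DataFrame, index=False):
        p = out_dir / name
        df.to_csv(p, sep="\t", index=index)
        written.append(str(p))

    prof_rows = []
    for p in results["profiles"]:
        present = p.rel_abundance[p.rel_abundance > 0]
        for otu, rel in present.items():
            prof_rows.append((p.sample_id, otu, rel, p.status[otu]))
    _write(
        "profiles.tsv",
        pd.DataFrame(
            prof_rows, columns=["sample_id", "otu_id", "rel_abundance", "status"]
        ),
    )
    parts = results["partition"]
    _write(
        "partition.tsv",
        pd.DataFrame(
            [(otu, part) for part, otus in
             (("shared", parts.shared), ("disappeared", parts.disappeared),
              ("appeared", parts.appeared)) for otu in sorted(otus)],
            columns=["otu_id", "partition"],
        ),
    )
    tv = results["turnover"]
    _write("turnover_occurrences.tsv", tv.occurrences)
    _write("turnover_otu_summary.tsv", tv.otu_summary.reset_index())
    shares = tv.sample_shares.copy()
    shares["label"] = tv.sample_labels
    _write("turnover_sample_shares.tsv", shares.reset_index())
    _write(
        "otu_groups.tsv",
        results["groups"].rename("group").rename_axis("otu_id").reset_index(),
    )
    _write("poc.tsv", results["poc"])
    _write("pair_interactions.tsv", results["pairs"])
    _write("dominance_ranks.tsv", results["ranks"].ranks)
    _write(
        "top1_tally.tsv",
        results["ranks"].top1_tally.rename("top1_count").rename_axis("otu_id").reset_index(),
    )
    return written


def _raw_counts_table(raw: synthetic.RawCommunity) -> OtuTable:
    """Render the raw community as a single-sample count table."""
    obs = raw.observed_profile()
    counts = np.rint(obs.rel_abundance * RAW_SEQ_DEPTH).astype(np.int64)
    return OtuTable(pd.DataFrame({"RAW": counts}, index=raw.otu_ids))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage in order; returns the run manifest.

    A stage failure aborts the run but the partial manifest (with the
    failing stage named) is still written to ``manifest.json``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "nomvote",
        "seed": config.seed,
        "parameters": {
            "min_reads": config.min_reads,
            "dominance_threshold": config.dominance_threshold,
            "min_occurrence": config.min_occurrence,
            "top_n": config.top_n,
        },
        "stages": [],
        "completed": False,
    }

    def _stage(name: str):
        log.info("stage %s", name)
        entry = {"name": name, "outputs": []}
        manifest["stages"].append(entry)
        return entry

    try:
        entry = _stage("generate")
        raw, table = synthetic.generate_campaign(
            config.raw_community, config.dilution, config.cultivation,
            seed=config.seed,
        )
        raw_table = _raw_counts_table(raw)
        raw_path = out_dir / "raw_community.tsv"
        table_path = out_dir / "sub_communities.tsv"
        raw_table.write_tsv(raw_path)
        table.write_tsv(table_path)
        entry["outputs"] = [str(raw_path), str(table_path)]
        entry["wells"] = table.n_samples
        entry["otus"] = table.n_otus

        entry = _stage("occurrence")
        log.info(
            "thresholds: min_reads=%d dominance=%.4f min_occurrence=%d",
            config.min_reads, config.dominance_threshold, config.min_occurrence,
        )
        results = occurrence_analysis(
            table,
            raw.observed_profile(),
            min_reads=config.min_reads,
            threshold=config.dominance_threshold,
            min_occurrence=config.min_occurrence,
            top_n=config.top_n,
        )
        entry["outputs"] = write_occurrence_outputs(out_dir, results)
        entry["removed_samples"] = int(results["n_removed_samples"])
        entry["retained_samples"] = results["filtered"].n_samples
        entry["poc_pairs"] = int(len(results["poc"]))

        if config.run_crm:
            entry = _stage("crm")
            nom = crm.run_nomination(
                replicates=config.crm_replicates,
                resource_levels=config.crm_resource_levels,
                seed=config.seed,
            )
            vote = crm.run_voting(replicates=config.crm_replicates, seed=config.seed)
            struct = crm.run_structured(
                replicates=config.crm_replicates,
                targeted=config.crm_targeted,
                seed=config.seed,
            )
            nom_path = out_dir / "crm_group_shares.tsv"
            nom.mean_group_shares.to_csv(nom_path, sep="\t")
            vote_path = out_dir / "crm_top1_tally.tsv"
            pd.DataFrame(
                {
                    "random": struct.random.top1_counts,
                    "structured": struct.structured.top1_counts,
                }
            ).fillna(0).astype(int).to_csv(vote_path, sep="\t")
            entry["outputs"] = [str(nom_path), str(vote_path)]
            entry["voting_distinct_top1"] = int((vote.top1_counts > 0).sum())
            entry["structured_tv"] = struct.tv_distance

        manifest["completed"] = True
    finally:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
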