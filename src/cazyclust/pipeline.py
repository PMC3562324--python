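"""End-to-end orchestration: inputs -> telomeres -> clusters -> context ->
adjacency -> stats, with one result bundle and a parameter log.

The bundle is deterministic: identical config and inputs produce
byte-identical files (the log carries no timestamps for this reason).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import adjacency as adj
from . import context as ctx
from . import enrichment as enr
from . import genomeio as gio
from . import stats as gstats
from . import telomeres as tel

log = logging.getLogger("cazyclust")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    gff3: str
    categories: str
    fasta: Optional[str] = None
    proteins: Optional[str] = None
    paralog_groups: Optional[str] = None
    outdir: str = "cazyclust_out"
    enrichment: enr.EnrichmentParams = field(default_factory=enr.EnrichmentParams)
    telomere: tel.TelomereParams = field(default_factory=tel.TelomereParams)
    paralogy: adj.ParalogyParams = field(default_factory=adj.ParalogyParams)
    subtelomeric_cutoff_bp: int = ctx.DEFAULT_SUBTELOMERIC_CUTOFF_BP
    adjacency_label: str = "pcwde"
    min_protein_len_aa: int = 60
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("gff3", "categories", "fasta", "proteins", "paralog_groups"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"input {name!r} not found: {path}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - re-tagged with the stage name
                raise PipelineError(name, e) from e

        return wrapper

    return deco


@_stage("read_inputs")
def _read_inputs(config: RunConfig):
    genome = gio.read_annotation(config.gff3, config.categories)
    if config.fasta and os.path.getsize(config.fasta) > 0:
        gio.attach_sequences(genome, gio.read_fasta(config.fasta))
    proteins = gio.read_protein_fasta(config.proteins) if config.proteins else {}
    groups = None
    if config.paralog_groups:
        df = pd.read_csv(config.paralog_groups, sep="\t", dtype=str)
        groups = dict(zip(df["gene_id"], df["group"]))
    return genome, proteins, groups


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle to ``config.outdir``.

    Returns the summary dict (also written as summary.json). Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)

    handler = logging.FileHandler(out("run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cazyclust")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        log.info("parameters: %s", json.dumps(_config_dict(config), sort_keys=True))
        genome, proteins, groups = _read_inputs(config)
        log.info(
            "genome: %d scaffolds, %d genes, %d CAZyme, %d PCWDE",
            len(genome.scaffolds), genome.n_genes, genome.k_cazyme, genome.k_pcwde,
        )

        # telomeres / putative chromosomes
        calls = _telomere_stage(genome, config)
        tel_df = pd.DataFrame(
            [
                {
                    "scaffold_id": c.scaffold_id,
                    "five_prime_copies": c.five_prime.copies if c.five_prime else 0,
                    "three_prime_copies": c.three_prime.copies if c.three_prime else 0,
                    "is_putative_chromosome": c.is_putative_chromosome,
                }
                for c in calls
            ]
        )
        tel_df.to_csv(out("telomeres.tsv"), sep="\t", index=False)

        # cluster enrichment
        candidates, significant, regions, summary_stats = _cluster_stage(genome, config)
        enr.candidates_table(candidates).to_csv(out("candidates.tsv"), sep="\t", index=False)
        enr.regions_table(regions).to_csv(out("regions.tsv"), sep="\t", index=False)
        gio.write_regions_bed(regions, out("regions.bed"))

        # genomic context
        subtel = _context_stage(regions, genome, config)
        pd.DataFrame(
            [
                {
                    "region_id": c.region_id,
                    "scaffold_id": c.scaffold_id,
                    "distance_to_nearest_end": c.distance_to_nearest_end,
                    "is_subtelomeric": c.is_subtelomeric,
                    "note": c.note or "",
                }
                for c in subtel
            ]
        ).to_csv(out("subtelomeric.tsv"), sep="\t", index=False)

        # adjacency
        runs = _adjacency_stage(genome, proteins, groups, config)
        pd.DataFrame(
            [
                {
                    "scaffold_id": r.scaffold_id,
                    "first_ordinal": r.ordinals[0],
                    "run_length": r.run_length,
                    "gene_ids": ",".join(r.gene_ids),
                    "contains_paralog_pair": (
                        "" if r.contains_paralog_pair is None else r.contains_paralog_pair
                    ),
                }
                for r in runs
            ]
        ).to_csv(out("adjacent_runs.tsv"), sep="\t", index=False)

        # annotation stats
        stats = _stats_stage(genome, config)
        with open(out("genome_stats.json"), "w") as fh:
            json.dump(stats.presentation(), fh, indent=2, sort_keys=True)
            fh.write("\n")

        gio.write_gene_table(genome, out("gene_table.tsv"))

        summary = {
            "n_scaffolds": len(genome.scaffolds),
            "n_genes": genome.n_genes,
            "k_cazyme": genome.k_cazyme,
            "k_pcwde": genome.k_pcwde,
            "n_putative_chromosomes": sum(
                1 for c in calls if c.is_putative_chromosome
            ),
            "n_candidate_clusters": len(candidates),
            "n_significant_clusters": len(significant),
            "n_regions": len(regions),
            "regions_total_length_bp": summary_stats.total_length_bp,
            "regions_genome_fraction_pct": summary_stats.genome_fraction_pct,
            "label_genes_in_regions": summary_stats.label_genes_in_regions,
            "label_gene_fraction_pct": summary_stats.label_gene_fraction_pct,
            "n_subtelomeric_regions": sum(c.is_subtelomeric for c in subtel),
            "n_adjacent_runs": len(runs),
            "n_pairs": sum(1 for r in runs if r.run_length == 2),
            "n_triplets": sum(1 for r in runs if r.run_length == 3),
            "n_paralog_flagged_runs": sum(
                1 for r in runs if r.contains_paralog_pair
            ),
            "parameters": _config_dict(config),
        }
        with open(out("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("pipeline complete")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


@_stage("telomeres")
def _telomere_stage(genome, config: RunConfig):
    return tel.classify_chromosomes(genome.scaffolds, config.telomere)


@_stage("clusters")
def _cluster_stage(genome, config: RunConfig):
    candidates = enr.enumerate_candidates(genome, config.enrichment)
    significant = enr.significant_clusters(candidates, config.enrichment)
    regions = enr.merge_regions(significant, genome, config.enrichment)
    summary = enr.summarize_regions(regions, genome, config.enrichment.label)
    return candidates, significant, regions, summary


@_stage("context")
def _context_stage(regions, genome, config: RunConfig):
    return ctx.classify_regions(
        regions, genome.scaffolds, config.subtelomeric_cutoff_bp
    )


@_stage("adjacency")
def _adjacency_stage(genome, proteins, groups, config: RunConfig):
    runs = adj.find_adjacent_runs(genome, config.adjacency_label)
    if proteins or groups:
        adj.flag_paralogous_runs(runs, proteins, config.paralogy, groups)
    return runs


@_stage("stats")
def _stats_stage(genome, config: RunConfig):
    return gstats.compute_stats(genome, min_protein_len_aa=config.min_protein_len_aa)


def _config_dict(config: RunConfig) -> dict:
    """Parameters echoed into the bundle; outdir is omitted so that the same
    analysis written to two directories yields byte-identical bundles."""
    d = dataclasses.asdict(config)
    d.pop("outdir")
    return d
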