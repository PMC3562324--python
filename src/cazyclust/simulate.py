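"""Synthetic genome generator with ground truth for every downstream stage.

Emulates, at desk scale, a multi-scaffold fungal genome annotation: genes
with exon/intron structure laid out without overlap, CAZyme labels scattered
uniformly in the background, optional planted high-density label clusters,
telomeric repeat arrays written verbatim at scaffold termini (reverse
complement at the 5' end), and near-identical protein copies standing in for
paralogs. Everything is driven by one seeded NumPy generator, so a spec with
a fixed seed yields byte-identical output files.

Gene and protein sequences are random (uniform ACGT / uniform amino acids):
no downstream stage reads codon structure, so none is simulated.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
from Bio.Seq import Seq

from .models import (
    PCWDE_CATEGORIES,
    GeneRecord,
    GenomeModel,
    Scaffold,
    Transcript,
)

_CAZY_FAMILY_POOL = (
    "GH1", "GH3", "GH5", "GH6", "GH7", "GH10", "GH11", "GH28", "GH61",
    "CE1", "CE5", "PL1", "CBM1", "GT2",
)
_AA_POOL = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT_POOL = np.array(list("ACGT"))

#: Background CAZyme density mimicking a 371-of-10,013 gene census.
DEFAULT_BACKGROUND_RATE = 371 / 10_013
#: Fraction of labelled genes that are also plant-cell-wall degraders
#: (114 of 371 at genome scale).
DEFAULT_PCWDE_FRACTION = 114 / 371


@dataclass
class PlantedCluster:
    """A high-density label window: ``label_genes`` of ``window_genes``."""

    scaffold_index: int
    start_ordinal: int
    window_genes: int
    label_genes: int

    def __post_init__(self) -> None:
        if not 2 <= self.label_genes <= self.window_genes:
            raise ValueError("label_genes must be in [2, window_genes]")


@dataclass
class TelomereArraySpec:
    """Tandem arrays to write at a scaffold's termini (0 copies = none)."""

    scaffold_index: int
    five_prime_copies: int = 0
    three_prime_copies: int = 0
    motif: str = "TTAGGGG"


@dataclass
class ParalogInjection:
    """Make the target gene's protein a mutated copy of the source gene's."""

    scaffold_index: int
    source_ordinal: int
    target_ordinal: int
    mutation_rate: float = 0.02


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the simulated genome (see module docstring)."""

    n_scaffolds: int = 9
    genes_per_scaffold: Union[int, Sequence[int]] = 60
    gene_len_bp: tuple[int, int] = (500, 3000)
    intergenic_bp: tuple[int, int] = (100, 2000)
    max_exons_per_gene: int = 4
    background_label_rate: float = DEFAULT_BACKGROUND_RATE
    background_label_count: Optional[int] = None  # exact count, overrides rate
    pcwde_fraction: float = DEFAULT_PCWDE_FRACTION
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    telomere_arrays: list[TelomereArraySpec] = field(default_factory=list)
    paralog_injections: list[ParalogInjection] = field(default_factory=list)
    with_sequences: bool = True
    seed: int = 0

    def gene_counts(self) -> list[int]:
        if isinstance(self.genes_per_scaffold, int):
            return [self.genes_per_scaffold] * self.n_scaffolds
        counts = list(self.genes_per_scaffold)
        if len(counts) != self.n_scaffolds:
            raise ValueError("genes_per_scaffold list length != n_scaffolds")
        return counts

    def validate(self) -> None:
        counts = self.gene_counts()
        if not 0.0 <= self.background_label_rate <= 1.0:
            raise ValueError("background_label_rate must be in [0,1]")
        for pc in self.planted_clusters:
            if pc.scaffold_index >= self.n_scaffolds:
                raise ValueError(f"planted cluster on missing scaffold {pc.scaffold_index}")
            if pc.start_ordinal + pc.window_genes > counts[pc.scaffold_index]:
                raise ValueError(
                    f"planted cluster {pc} does not fit in scaffold "
                    f"{pc.scaffold_index} ({counts[pc.scaffold_index]} genes)"
                )
        for inj in self.paralog_injections:
            n = counts[inj.scaffold_index]
            if not (0 <= inj.source_ordinal < n and 0 <= inj.target_ordinal < n):
                raise ValueError(f"paralog injection {inj} outside scaffold")


class GeneratedPaths(NamedTuple):
    gff3: str
    fasta: str
    categories: str
    proteins: str
    truth: str


def _scaffold_id(i: int) -> str:
    return f"scaffold_{i + 1}"


def _gene_id(scaffold_index: int, ordinal: int) -> str:
    return f"SYN_{scaffold_index + 1:02d}_{ordinal:04d}"


def _make_exons(rng: np.random.Generator, start: int, end: int, max_exons: int) -> list[tuple[int, int]]:
    """Split [start, end) into exon/intron alternation with >=20 bp pieces."""
    length = end - start
    n_exons = int(rng.integers(1, max_exons + 1))
    n_parts = 2 * n_exons - 1
    if length < 20 * n_parts:
        return [(start, end)]
    # n_parts segment lengths >= 20 summing to length
    extra = rng.multinomial(length - 20 * n_parts, np.ones(n_parts) / n_parts)
    sizes = extra + 20
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_parts, 2)]


def simulate_genome_model(
    spec: SyntheticGenomeSpec,
) -> tuple[GenomeModel, dict[str, str], dict]:
    """Build the in-memory genome, its proteins and the ground-truth record.

    Returns (genome, proteins, truth). ``generate`` serialises these to the
    standard formats; tests that need no files use this directly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = spec.gene_counts()

    planted_by_scaffold: dict[int, list[PlantedCluster]] = {}
    for pc in spec.planted_clusters:
        planted_by_scaffold.setdefault(pc.scaffold_index, []).append(pc)

    scaffolds: list[Scaffold] = []
    truth: dict = {
        "seed": spec.seed,
        "scaffolds": [],
        "label_gene_ids": [],
        "planted_clusters": [],
        "telomere_arrays": [],
        "paralog_pairs": [],
    }
    all_genes: list[GeneRecord] = []

    for si in range(spec.n_scaffolds):
        n = counts[si]
        sid = _scaffold_id(si)
        # coordinates
        genes: list[GeneRecord] = []
        pos = int(rng.integers(spec.intergenic_bp[0], spec.intergenic_bp[1] + 1))
        for oi in range(n):
            glen = int(rng.integers(spec.gene_len_bp[0], spec.gene_len_bp[1] + 1))
            start, end = pos, pos + glen
            exons = _make_exons(rng, start, end, spec.max_exons_per_gene)
            gid = _gene_id(si, oi)
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    scaffold_id=sid,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    ordinal=oi,
                    transcripts=[Transcript(f"{gid}.t1", exons)],
                )
            )
            pos = end + int(
                rng.integers(spec.intergenic_bp[0], spec.intergenic_bp[1] + 1)
            )
        length = pos

        # labels: planted windows first, then background outside them
        in_planted = np.zeros(n, dtype=bool)
        labelled = np.zeros(n, dtype=bool)
        for pc in planted_by_scaffold.get(si, []):
            lo, hi = pc.start_ordinal, pc.start_ordinal + pc.window_genes  # [lo, hi)
            if in_planted[lo:hi].any():
                raise ValueError(f"overlapping planted clusters on scaffold {si}")
            in_planted[lo:hi] = True
            interior = np.arange(lo + 1, hi - 1)
            chosen = {lo, hi - 1}
            if pc.label_genes > 2:
                chosen.update(
                    int(x)
                    for x in rng.choice(
                        interior, size=pc.label_genes - 2, replace=False
                    )
                )
            ords = sorted(chosen)
            labelled[ords] = True
            truth["planted_clusters"].append(
                {
                    "scaffold_id": sid,
                    "start_ordinal": pc.start_ordinal,
                    "window_genes": pc.window_genes,
                    "label_ordinals": ords,
                }
            )
        background = np.flatnonzero(~in_planted)
        if spec.background_label_count is not None:
            take = min(spec.background_label_count, background.size)
            labelled[rng.choice(background, size=take, replace=False)] = True
        elif spec.background_label_rate > 0:
            labelled[background[rng.random(background.size) < spec.background_label_rate]] = True

        for oi in np.flatnonzero(labelled):
            g = genes[oi]
            g.is_cazyme = True
            nfam = int(rng.integers(1, 3))
            g.cazy_families = sorted(
                rng.choice(_CAZY_FAMILY_POOL, size=nfam, replace=False).tolist()
            )
            if rng.random() < spec.pcwde_fraction:
                g.is_pcwde = True
                g.pcwde_category = str(rng.choice(PCWDE_CATEGORIES))
            truth["label_gene_ids"].append(g.gene_id)

        scaffolds.append(Scaffold(scaffold_id=sid, length=length, genes=genes))
        truth["scaffolds"].append({"scaffold_id": sid, "length": length, "n_genes": n})
        all_genes.extend(genes)

    # sequences + telomere arrays
    if spec.with_sequences:
        arrays_by_scaffold: dict[int, TelomereArraySpec] = {
            t.scaffold_index: t for t in spec.telomere_arrays
        }
        for si, scaffold in enumerate(scaffolds):
            seq = rng.choice(_NT_POOL, size=scaffold.length)
            tspec = arrays_by_scaffold.get(si)
            if tspec is not None:
                motif = tspec.motif.upper()
                if tspec.five_prime_copies > 0:
                    arr = str(Seq(motif).reverse_complement()) * tspec.five_prime_copies
                    seq[: len(arr)] = list(arr)
                    truth["telomere_arrays"].append(
                        {
                            "scaffold_id": scaffold.scaffold_id,
                            "terminus": "five_prime",
                            "motif": motif,
                            "copies": tspec.five_prime_copies,
                        }
                    )
                if tspec.three_prime_copies > 0:
                    arr = motif * tspec.three_prime_copies
                    seq[-len(arr):] = list(arr)
                    truth["telomere_arrays"].append(
                        {
                            "scaffold_id": scaffold.scaffold_id,
                            "terminus": "three_prime",
                            "motif": motif,
                            "copies": tspec.three_prime_copies,
                        }
                    )
            scaffold.sequence = "".join(seq)

    # proteins: length from exonic bp; paralog targets are mutated copies
    proteins: dict[str, str] = {}
    for g in all_genes:
        rep = g.representative_transcript
        plen = max(50, rep.exonic_length // 3 if rep else 100)
        proteins[g.gene_id] = "".join(rng.choice(_AA_POOL, size=plen))
    for inj in spec.paralog_injections:
        src = scaffolds[inj.scaffold_index].genes[inj.source_ordinal]
        tgt = scaffolds[inj.scaffold_index].genes[inj.target_ordinal]
        base = np.array(list(proteins[src.gene_id]))
        mutate = rng.random(base.size) < inj.mutation_rate
        for idx in np.flatnonzero(mutate):
            choices = _AA_POOL[_AA_POOL != base[idx]]
            base[idx] = rng.choice(choices)
        proteins[tgt.gene_id] = "".join(base)
        truth["paralog_pairs"].append([src.gene_id, tgt.gene_id])

    genome = GenomeModel(scaffolds=scaffolds)
    genome.validate()
    return genome, proteins, truth


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def generate(spec: SyntheticGenomeSpec, outdir: str) -> GeneratedPaths:
    """Write GFF3, FASTA, category TSV, protein FASTA and truth JSON."""
    genome, proteins, truth = simulate_genome_model(spec)
    os.makedirs(outdir, exist_ok=True)
    paths = GeneratedPaths(
        gff3=os.path.join(outdir, "genome.gff3"),
        fasta=os.path.join(outdir, "genome.fasta"),
        categories=os.path.join(outdir, "categories.tsv"),
        proteins=os.path.join(outdir, "proteins.fasta"),
        truth=os.path.join(outdir, "truth.json"),
    )

    with open(paths.gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in genome.scaffolds:
            fh.write(f"##sequence-region {s.scaffold_id} 1 {s.length}\n")
        for s in genome.scaffolds:
            for g in s.genes:
                fh.write(
                    f"{s.scaffold_id}\tcazyclust-sim\tgene\t{g.start + 1}\t{g.end}"
                    f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
                for t in g.transcripts:
                    fh.write(
                        f"{s.scaffold_id}\tcazyclust-sim\tmRNA\t{g.start + 1}\t{g.end}"
                        f"\t.\t{g.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                    )
                    for ei, (es, ee) in enumerate(t.exons, start=1):
                        fh.write(
                            f"{s.scaffold_id}\tcazyclust-sim\texon\t{es + 1}\t{ee}"
                            f"\t.\t{g.strand}\t.\tID={t.transcript_id}.exon{ei};"
                            f"Parent={t.transcript_id}\n"
                        )

    if spec.with_sequences:
        with open(paths.fasta, "w") as fh:
            for s in genome.scaffolds:
                fh.write(f">{s.scaffold_id}\n{_wrap(s.sequence)}\n")
    else:
        open(paths.fasta, "w").close()

    with open(paths.categories, "w") as fh:
        fh.write("gene_id\tis_cazyme\tcazy_families\tpcwde_category\n")
        for g in genome.genes:
            if not (g.is_cazyme or g.is_pcwde):
                continue
            fh.write(
                f"{g.gene_id}\t{int(g.is_cazyme)}\t{','.join(g.cazy_families)}"
                f"\t{g.pcwde_category or ''}\n"
            )

    with open(paths.proteins, "w") as fh:
        for gid in sorted(proteins):
            fh.write(f">{gid}\n{_wrap(proteins[gid])}\n")

    with open(paths.truth, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return paths


def permute_labels(genome: GenomeModel, seed: int) -> GenomeModel:
    """Uniformly permute the label bundles across all gene positions.

    The CAZyme flag, family list and PCWDE flag/category of each gene travel
    together; counts are conserved. Returns a deep copy; the input is
    untouched. This is the permutation null for calibration tests.
    """
    out = copy.deepcopy(genome)
    genes = out.genes
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    bundles = [
        (g.is_cazyme, list(g.cazy_families), g.is_pcwde, g.pcwde_category)
        for g in genes
    ]
    for g, src in zip(genes, perm):
        g.is_cazyme, g.cazy_families, g.is_pcwde, g.pcwde_category = (
            bundles[src][0],
            list(bundles[src][1]),
            bundles[src][2],
            bundles[src][3],
        )
    return out
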