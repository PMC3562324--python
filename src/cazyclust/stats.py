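"""Genome-summary statistics from annotations and sequences.

Reproduces the usual "general features" table of a fungal genome report:
assembly size, GC content, gene counts, average gene/exon/intron lengths and
introns per gene. Introns are the gaps between consecutive exons of one
mRNA; for multi-isoform genes the longest mRNA (by exonic length) represents
the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .models import GenomeModel


@dataclass
class GenomeStats:
    """Unrounded summary statistics plus rounded presentation values."""

    assembled_size_bp: int
    gc_pct: Optional[float]
    n_genes: int
    n_genes_ge_min_len: int
    min_protein_len_aa: int
    coding_gc_pct: Optional[float]
    avg_gene_length_bp: float
    avg_exonic_length_bp: float
    avg_introns_per_gene: float
    n_genes_with_intron: int
    avg_intron_bp: float
    avg_exon_bp: float

    def presentation(self) -> dict:
        """Rounded values for reporting: lengths to integer, ratios to 2 dp."""
        rnd = lambda v, d=0: (None if v is None else round(v, d) if d else int(round(v)))
        return {
            "assembled_size_bp": self.assembled_size_bp,
            "gc_pct": rnd(self.gc_pct, 1),
            "n_genes": self.n_genes,
            f"n_genes_ge_{self.min_protein_len_aa}aa": self.n_genes_ge_min_len,
            "coding_gc_pct": rnd(self.coding_gc_pct, 1),
            "avg_gene_length_bp": rnd(self.avg_gene_length_bp),
            "avg_exonic_length_bp": rnd(self.avg_exonic_length_bp),
            "avg_introns_per_gene": rnd(self.avg_introns_per_gene, 2),
            "n_genes_with_intron": self.n_genes_with_intron,
            "avg_intron_bp": rnd(self.avg_intron_bp),
            "avg_exon_bp": rnd(self.avg_exon_bp),
        }


def _gc(seq: str) -> tuple[int, int]:
    """(GC count, ACGT count); N and other ambiguity codes excluded."""
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc, acgt


def compute_stats(
    genome: GenomeModel,
    sequences: Optional[dict[str, str]] = None,
    min_protein_len_aa: int = 60,
) -> GenomeStats:
    """Compute the genome-feature summary.

    Gene length is the gene-feature span (UTRs included when annotated);
    the exonic-length average is reported alongside since conventions vary.
    The ">= min_protein_len_aa" count uses the representative mRNA's summed
    exon length >= 3 * min_protein_len_aa bp as the coding-length proxy (no
    CDS features are consumed). GC is computed over A/C/G/T only. Without
    sequences the GC fields are None. Overlapping exons within one mRNA are
    fatal.
    """
    sequences = sequences or {
        s.scaffold_id: s.sequence for s in genome.scaffolds if s.sequence
    }

    gene_lengths: list[int] = []
    exonic_lengths: list[int] = []
    intron_counts: list[int] = []
    intron_lengths: list[int] = []
    exon_lengths: list[int] = []
    n_with_intron = 0
    n_ge_min = 0
    coding_gc = coding_acgt = 0

    for scaffold in genome.scaffolds:
        seq = sequences.get(scaffold.scaffold_id)
        for gene in scaffold.genes:
            gene_lengths.append(gene.end - gene.start)
            rep = gene.representative_transcript
            if rep is None:
                exonic_lengths.append(gene.end - gene.start)
                intron_counts.append(0)
                continue
            prev_end = None
            for s, e in rep.exons:
                if prev_end is not None and s < prev_end:
                    raise ValueError(
                        f"mRNA {rep.transcript_id}: overlapping exons at {s}"
                    )
                prev_end = e
                exon_lengths.append(e - s)
                if seq is not None:
                    g, a = _gc(seq[s:e])
                    coding_gc += g
                    coding_acgt += a
            introns = rep.introns()
            intron_counts.append(len(introns))
            intron_lengths.extend(e - s for s, e in introns)
            if introns:
                n_with_intron += 1
            exonic = rep.exonic_length
            exonic_lengths.append(exonic)
            if exonic >= 3 * min_protein_len_aa:
                n_ge_min += 1

    total_gc = total_acgt = 0
    for s in genome.scaffolds:
        seq = sequences.get(s.scaffold_id)
        if seq:
            g, a = _gc(seq)
            total_gc += g
            total_acgt += a

    mean = lambda xs: (sum(xs) / len(xs)) if xs else 0.0
    return GenomeStats(
        assembled_size_bp=genome.total_length_bp,
        gc_pct=(100.0 * total_gc / total_acgt) if total_acgt else None,
        n_genes=genome.n_genes,
        n_genes_ge_min_len=n_ge_min,
        min_protein_len_aa=min_protein_len_aa,
        coding_gc_pct=(100.0 * coding_gc / coding_acgt) if coding_acgt else None,
        avg_gene_length_bp=mean(gene_lengths),
        avg_exonic_length_bp=mean(exonic_lengths),
        avg_introns_per_gene=mean(intron_counts),
        n_genes_with_intron=n_with_intron,
        avg_intron_bp=mean(intron_lengths),
        avg_exon_bp=mean(exon_lengths),
    )
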