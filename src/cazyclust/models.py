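"""In-memory genome model: genes, scaffolds and genome-wide label census.

Coordinates are 0-based, half-open throughout the package; GFF3 (1-based,
closed) and BED (0-based, half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: PCWDE categories counted inside the CAZy universe.
PCWDE_CATEGORIES = (
    "cellulase",
    "hemicellulase",
    "beta-glucosidase",
    "pectinase",
    "expansin-like",
    "tannase",
    "cellobiose-dehydrogenase",
)

#: PCWDE categories that fall outside CAZy family assignment (a gene may be
#: PCWDE without being a CAZyme only in these categories).
NON_CAZY_PCWDE_CATEGORIES = frozenset(
    {"tannase", "cellobiose-dehydrogenase", "expansin-like"}
)


@dataclass
class Transcript:
    """One mRNA with its exons (0-based half-open intervals, sorted)."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1, s2))
        return out


@dataclass
class GeneRecord:
    """A single gene with its position, rank and enzyme-category flags."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    ordinal: int = 0
    is_cazyme: bool = False
    cazy_families: list[str] = field(default_factory=list)
    is_pcwde: bool = False
    pcwde_category: Optional[str] = None
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.is_pcwde and self.pcwde_category is None:
            raise ValueError(f"gene {self.gene_id}: PCWDE flag without category")

    def has_label(self, label: str) -> bool:
        """Whether the gene carries the given label ('cazyme' or 'pcwde')."""
        if label == "cazyme":
            return self.is_cazyme
        if label == "pcwde":
            return self.is_pcwde
        raise ValueError(f"unknown label {label!r} (expected 'cazyme' or 'pcwde')")

    @property
    def representative_transcript(self) -> Optional[Transcript]:
        """Longest mRNA by exonic length (ties: lexicographic ID)."""
        if not self.transcripts:
            return None
        return max(self.transcripts, key=lambda t: (t.exonic_length, t.transcript_id))


@dataclass
class Scaffold:
    """A scaffold with its ordered genes and optional sequence."""

    scaffold_id: str
    length: int
    sequence: Optional[str] = None
    genes: list[GeneRecord] = field(default_factory=list)
    is_putative_chromosome: Optional[bool] = None

    def validate(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"scaffold {self.scaffold_id}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id} ends at {g.end}, beyond scaffold "
                    f"{self.scaffold_id} length {self.length}"
                )
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"scaffold {self.scaffold_id}: genes not sorted by start")
        ordinals = sorted(g.ordinal for g in self.genes)
        if ordinals != list(range(len(self.genes))):
            raise ValueError(
                f"scaffold {self.scaffold_id}: ordinals are not 0..n-1"
            )


@dataclass
class GenomeModel:
    """All scaffolds plus genome-wide totals used as the enrichment background."""

    scaffolds: list[Scaffold] = field(default_factory=list)

    @property
    def genes(self) -> list[GeneRecord]:
        return [g for s in self.scaffolds for g in s.genes]

    @property
    def n_genes(self) -> int:
        return sum(len(s.genes) for s in self.scaffolds)

    @property
    def k_cazyme(self) -> int:
        return sum(g.is_cazyme for g in self.genes)

    @property
    def k_pcwde(self) -> int:
        return sum(g.is_pcwde for g in self.genes)

    @property
    def total_length_bp(self) -> int:
        return sum(s.length for s in self.scaffolds)

    def k_label(self, label: str) -> int:
        return sum(g.has_label(label) for g in self.genes)

    def scaffold(self, scaffold_id: str) -> Scaffold:
        for s in self.scaffolds:
            if s.scaffold_id == scaffold_id:
                return s
        raise KeyError(scaffold_id)

    def validate(self) -> None:
        for s in self.scaffolds:
            s.validate()
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene ID {g.gene_id}")
            seen.add(g.gene_id)
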