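"""Reading and writing the standard formats the pipeline touches.

GFF3 gene/mRNA/exon annotations are parsed with gffutils into the in-memory
genome model; scaffold sequences come from FASTA via Biopython; gene category
flags (CAZyme / plant-cell-wall-degrading enzyme) come from a TSV table.
Enriched regions go out as BED and the gene table round-trips through TSV.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from typing import TYPE_CHECKING, Optional

import gffutils
import pandas as pd
from Bio import SeqIO

from .models import GeneRecord, GenomeModel, Scaffold, Transcript

if TYPE_CHECKING:  # pragma: no cover
    from .enrichment import EnrichedRegion

log = logging.getLogger(__name__)

_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n", ""}

#: BED score cap for -10*log10(P).
BED_SCORE_CAP = 1000


class AnnotationError(ValueError):
    """Fatal problem in an annotation or category file."""


def _parse_bool(token: str, context: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS or t == "nan":
        return False
    raise AnnotationError(f"{context}: cannot interpret {token!r} as a boolean")


def _prevalidate_gff3(path: str) -> None:
    """Check coordinates line by line so errors can cite a line number.

    gffutils reports parse failures without positions; this pass exists only
    for error reporting and does not replace the parser.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >=8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[3]!r}..{fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed interval {start}..{end} "
                    "(GFF3 requires 1 <= start <= end)"
                )


def read_category_table(path: str) -> pd.DataFrame:
    """Read the gene-category TSV (gene_id, is_cazyme, cazy_families, pcwde_category)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "is_cazyme", "cazy_families", "pcwde_category"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(
            f"{path}: category table missing column(s) {sorted(missing)}"
        )
    return df


def read_annotation(gff3_path: str, category_table_path: Optional[str] = None) -> GenomeModel:
    """Build a :class:`GenomeModel` from a GFF3 file and a category TSV.

    GFF3 1-based closed coordinates become 0-based half-open. Ordinals are
    assigned per scaffold by (start, end, gene_id). Genes absent from the
    category table get all-false flags; table rows naming unknown genes are
    ignored with a warning. Scaffold lengths come from ``##sequence-region``
    directives when present, else from the furthest gene end.
    """
    _prevalidate_gff3(gff3_path)
    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )

    # scaffold lengths from ##sequence-region directives
    declared_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            declared_lengths[parts[1]] = int(parts[3])

    categories: dict[str, dict] = {}
    if category_table_path is not None:
        cat_df = read_category_table(category_table_path)
        for _, row in cat_df.iterrows():
            gid = row["gene_id"]
            if gid in categories:
                raise AnnotationError(
                    f"{category_table_path}: duplicate gene_id {gid!r}"
                )
            fams = [f for f in str(row["cazy_families"]).split(",") if f.strip()]
            pcwde_cat = str(row["pcwde_category"]).strip() or None
            categories[gid] = {
                "is_cazyme": _parse_bool(row["is_cazyme"], f"gene {gid}"),
                "cazy_families": fams,
                "is_pcwde": pcwde_cat is not None,
                "pcwde_category": pcwde_cat,
            }

    genes_by_scaffold: dict[str, list[GeneRecord]] = {}
    seen_ids: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.id
        if gid in seen_ids:
            raise AnnotationError(f"duplicate gene ID {gid!r} in {gff3_path}")
        seen_ids.add(gid)
        flags = categories.pop(gid, None) or {}
        transcripts = []
        for mrna in db.children(feat, featuretype="mRNA", order_by="start"):
            exons = [
                (e.start - 1, e.end)
                for e in db.children(mrna, featuretype="exon", order_by="start")
            ]
            transcripts.append(Transcript(transcript_id=mrna.id, exons=exons))
        rec = GeneRecord(
            gene_id=gid,
            scaffold_id=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            is_cazyme=flags.get("is_cazyme", False),
            cazy_families=flags.get("cazy_families", []),
            is_pcwde=flags.get("is_pcwde", False),
            pcwde_category=flags.get("pcwde_category"),
            transcripts=transcripts,
        )
        genes_by_scaffold.setdefault(feat.seqid, []).append(rec)

    for leftover in categories:
        warnings.warn(
            f"category table row for {leftover!r} has no matching gene in "
            f"{gff3_path}; ignored",
            stacklevel=2,
        )

    scaffolds = []
    for sid in sorted(genes_by_scaffold):
        genes = sorted(
            genes_by_scaffold[sid], key=lambda g: (g.start, g.end, g.gene_id)
        )
        for i, g in enumerate(genes):
            g.ordinal = i
        length = declared_lengths.get(sid, max(g.end for g in genes))
        scaffolds.append(Scaffold(scaffold_id=sid, length=length, genes=genes))
    # scaffolds declared but without genes still take part in genome length
    for sid, length in sorted(declared_lengths.items()):
        if sid not in genes_by_scaffold:
            scaffolds.append(Scaffold(scaffold_id=sid, length=length))
    scaffolds.sort(key=lambda s: s.scaffold_id)

    genome = GenomeModel(scaffolds=scaffolds)
    genome.validate()
    return genome


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into ``{scaffold_id: uppercased sequence}``.

    IDs are the first whitespace-delimited token of the header; duplicate IDs
    and empty files are fatal.
    """
    if os.path.getsize(path) == 0:
        raise AnnotationError(f"{path}: empty FASTA file")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in sequences:
            raise AnnotationError(f"{path}: duplicate FASTA ID {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise AnnotationError(f"{path}: no FASTA records found")
    return sequences


def read_protein_fasta(path: str) -> dict[str, str]:
    """Protein FASTA reader; identical contract to :func:`read_fasta`."""
    return read_fasta(path)


def attach_sequences(genome: GenomeModel, sequences: dict[str, str]) -> GenomeModel:
    """Attach FASTA sequences to scaffolds in place (and return the model).

    A sequence longer than the annotation-implied scaffold length extends the
    scaffold; a shorter one is fatal.
    """
    for s in genome.scaffolds:
        seq = sequences.get(s.scaffold_id)
        if seq is None:
            continue
        if len(seq) < s.length:
            raise AnnotationError(
                f"scaffold {s.scaffold_id}: sequence length {len(seq)} shorter "
                f"than annotation extent {s.length}"
            )
        s.length = len(seq)
        s.sequence = seq
    genome.validate()
    return genome


def write_regions_bed(regions: list["EnrichedRegion"], path: str) -> None:
    """Write enriched regions as BED (0-based half-open).

    Score column is ``-10*log10(min cluster P)`` capped at 1000.
    """
    with open(path, "w") as fh:
        for r in regions:
            score = BED_SCORE_CAP
            if r.min_p > 0:
                score = min(BED_SCORE_CAP, int(round(-10.0 * math.log10(r.min_p))))
            fh.write(f"{r.scaffold_id}\t{r.start}\t{r.end}\t{r.region_id}\t{score}\n")


_GENE_TABLE_COLUMNS = [
    "gene_id",
    "scaffold_id",
    "start",
    "end",
    "strand",
    "ordinal",
    "is_cazyme",
    "cazy_families",
    "is_pcwde",
    "pcwde_category",
]


def write_gene_table(genome: GenomeModel, path: str) -> None:
    """Write all gene records (coordinates, ordinals, flags) to a TSV."""
    rows = []
    for g in genome.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "scaffold_id": g.scaffold_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "ordinal": g.ordinal,
                "is_cazyme": int(g.is_cazyme),
                "cazy_families": ",".join(g.cazy_families),
                "is_pcwde": int(g.is_pcwde),
                "pcwde_category": g.pcwde_category or "",
            }
        )
    pd.DataFrame(rows, columns=_GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str) -> list[GeneRecord]:
    """Read a gene table written by :func:`write_gene_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        pcwde_cat = row["pcwde_category"] or None
        records.append(
            GeneRecord(
                gene_id=row["gene_id"],
                scaffold_id=row["scaffold_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                ordinal=int(row["ordinal"]),
                is_cazyme=_parse_bool(row["is_cazyme"], f"gene {row['gene_id']}"),
                cazy_families=[
                    f for f in row["cazy_families"].split(",") if f.strip()
                ],
                is_pcwde=_parse_bool(row["is_pcwde"], f"gene {row['gene_id']}"),
                pcwde_category=pcwde_cat,
            )
        )
    return records
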