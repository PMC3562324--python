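"""Shared fixtures: tiny hand-built genomes and annotation files.

All fixtures are generated programmatically; nothing is stored on disk.
"""

from __future__ import annotations

import textwrap

import pytest

from cazyclust import GeneRecord, GenomeModel, Scaffold


def build_genome(
    label_patterns: dict[str, str],
    gene_len: int = 1000,
    gap: int = 500,
    label: str = "cazyme",
    scaffold_pad: int = 0,
) -> GenomeModel:
    """Build a genome from per-scaffold label strings like ``"PPNPPP"``.

    ``P`` marks a label-positive gene, any other character a negative one.
    Genes are laid head to tail with a fixed gap; scaffold length is the
    last gene end plus one gap plus ``scaffold_pad``.
    """
    scaffolds = []
    for sid, pattern in label_patterns.items():
        genes = []
        pos = gap
        for i, ch in enumerate(pattern):
            positive = ch == "P"
            genes.append(
                GeneRecord(
                    gene_id=f"{sid}_g{i}",
                    scaffold_id=sid,
                    start=pos,
                    end=pos + gene_len,
                    ordinal=i,
                    is_cazyme=positive if label == "cazyme" else False,
                    is_pcwde=positive if label == "pcwde" else False,
                    pcwde_category="cellulase" if (positive and label == "pcwde") else None,
                )
            )
            pos += gene_len + gap
        scaffolds.append(
            Scaffold(scaffold_id=sid, length=pos + scaffold_pad, genes=genes)
        )
    genome = GenomeModel(scaffolds=scaffolds)
    genome.validate()
    return genome


@pytest.fixture
def toy_gff3(tmp_path):
    """Three genes on one scaffold, one with a two-exon mRNA."""
    text = textwrap.dedent(
        """\
        ##gff-version 3
        ##sequence-region s1 1 10000
        s1\ttest\tgene\t1\t300\t.\t+\t.\tID=gA
        s1\ttest\tmRNA\t1\t300\t.\t+\t.\tID=gA.t1;Parent=gA
        s1\ttest\texon\t1\t100\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1
        s1\ttest\texon\t201\t300\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1
        s1\ttest\tgene\t1000\t1500\t.\t-\t.\tID=gB
        s1\ttest\tmRNA\t1000\t1500\t.\t-\t.\tID=gB.t1;Parent=gB
        s1\ttest\texon\t1000\t1500\t.\t-\t.\tID=gB.t1.e1;Parent=gB.t1
        s1\ttest\tgene\t2000\t2600\t.\t+\t.\tID=gC
        s1\ttest\tmRNA\t2000\t2600\t.\t+\t.\tID=gC.t1;Parent=gC
        s1\ttest\texon\t2000\t2600\t.\t+\t.\tID=gC.t1.e1;Parent=gC.t1
        """
    )
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return str(path)


@pytest.fixture
def toy_categories(tmp_path):
    """Category table flagging gA and gC as CAZymes, gC also PCWDE."""
    text = (
        "gene_id\tis_cazyme\tcazy_families\tpcwde_category\n"
        "gA\t1\tGH5,CBM1\t\n"
        "gC\t1\tGH7\tcellulase\n"
    )
    path = tmp_path / "toy_categories.tsv"
    path.write_text(text)
    return str(path)


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">s1 scaffold one\n" + "ACGT" * 2500 + "\n")
    return str(path)
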