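"""Cross-species category comparison helpers.

Per-category gene counts across species are displayed as percent of the
per-category maximum (the row maximum is set to 100%), which makes gene
family expansions comparable across categories with very different absolute
counts.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import pandas as pd

from .genomeio import read_category_table
from .models import PCWDE_CATEGORIES


class CategoryCounts(NamedTuple):
    """Gene counts and distinct CAZy-family counts per (category, species)."""

    gene_counts: pd.DataFrame
    family_counts: pd.DataFrame


def percent_of_max(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to percent of its maximum; all-zero rows stay 0.

    Ties at the row maximum all map to 100. Negative counts are fatal.
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix must have at least one column")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    row_max = matrix.max(axis=1)
    scaled = matrix.div(row_max.where(row_max > 0, 1), axis=0) * 100.0
    return scaled


def tabulate_categories(gene_tables: dict[str, str]) -> CategoryCounts:
    """Count labelled genes and distinct CAZy families per category/species.

    ``gene_tables`` maps species name -> category TSV path. Rows whose
    pcwde_category is not in the shared vocabulary are bucketed as "other"
    with a warning. Columns follow the input mapping order.
    """
    known = set(PCWDE_CATEGORIES)
    gene_counts: dict[str, dict[str, int]] = {}
    family_sets: dict[str, dict[str, set]] = {}
    for species, path in gene_tables.items():
        df = read_category_table(path)
        counts: dict[str, int] = {}
        fams: dict[str, set] = {}
        for _, row in df.iterrows():
            cat = str(row["pcwde_category"]).strip()
            if not cat:
                continue
            if cat not in known:
                warnings.warn(
                    f"{species}: unknown category {cat!r}; bucketed as 'other'",
                    stacklevel=2,
                )
                cat = "other"
            counts[cat] = counts.get(cat, 0) + 1
            fams.setdefault(cat, set()).update(
                f for f in str(row["cazy_families"]).split(",") if f.strip()
            )
        gene_counts[species] = counts
        family_sets[species] = fams

    categories = [c for c in PCWDE_CATEGORIES] + (
        ["other"]
        if any("other" in c for c in gene_counts.values())
        else []
    )
    species_names = list(gene_tables)
    gc = pd.DataFrame(
        {
            sp: [gene_counts[sp].get(cat, 0) for cat in categories]
            for sp in species_names
        },
        index=categories,
    )
    fc = pd.DataFrame(
        {
            sp: [len(family_sets[sp].get(cat, set())) for cat in categories]
            for sp in species_names
        },
        index=categories,
    )
    return CategoryCounts(gene_counts=gc, family_counts=fc)
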