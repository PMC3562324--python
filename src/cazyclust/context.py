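"""Sub-telomeric classification of enzyme-dense regions.

A region is sub-telomeric when its nearest edge lies within a fixed distance
(default 200 kb) of a putative chromosome end. Regions on scaffolds not
classified as putative chromosomes are reported non-sub-telomeric with a
note, since "chromosome end" is undefined for an unanchored scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .enrichment import EnrichedRegion
from .models import Scaffold

#: Default distance cutoff from a chromosome end, bp (inclusive).
DEFAULT_SUBTELOMERIC_CUTOFF_BP = 200_000


@dataclass
class SubtelomericCall:
    region_id: str
    scaffold_id: str
    distance_to_nearest_end: int
    is_subtelomeric: bool
    cutoff_bp: int = DEFAULT_SUBTELOMERIC_CUTOFF_BP
    note: Optional[str] = None


def subtelomeric_classify(
    region: EnrichedRegion,
    scaffold: Scaffold,
    cutoff_bp: int = DEFAULT_SUBTELOMERIC_CUTOFF_BP,
) -> SubtelomericCall:
    """Classify one region by distance from its nearest scaffold end.

    Distance is measured from the region edge closest to a terminus
    (min(start, length - end)), so any overlap with the terminal window
    counts; the cutoff is inclusive.
    """
    if region.scaffold_id != scaffold.scaffold_id:
        raise ValueError(
            f"region {region.region_id} is on {region.scaffold_id}, "
            f"not {scaffold.scaffold_id}"
        )
    if region.start < 0 or region.end > scaffold.length:
        raise ValueError(
            f"region {region.region_id} ({region.start}-{region.end}) outside "
            f"scaffold {scaffold.scaffold_id} bounds (0-{scaffold.length})"
        )
    distance = min(region.start, scaffold.length - region.end)
    if scaffold.is_putative_chromosome:
        return SubtelomericCall(
            region_id=region.region_id,
            scaffold_id=region.scaffold_id,
            distance_to_nearest_end=distance,
            is_subtelomeric=distance <= cutoff_bp,
            cutoff_bp=cutoff_bp,
        )
    return SubtelomericCall(
        region_id=region.region_id,
        scaffold_id=region.scaffold_id,
        distance_to_nearest_end=distance,
        is_subtelomeric=False,
        cutoff_bp=cutoff_bp,
        note="scaffold not classified as a putative chromosome",
    )


def classify_regions(
    regions: list[EnrichedRegion],
    scaffolds: list[Scaffold],
    cutoff_bp: int = DEFAULT_SUBTELOMERIC_CUTOFF_BP,
) -> list[SubtelomericCall]:
    """Classify every region against its scaffold."""
    by_id = {s.scaffold_id: s for s in scaffolds}
    return [
        subtelomeric_classify(r, by_id[r.scaffold_id], cutoff_bp) for r in regions
    ]
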