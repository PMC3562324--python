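"""CAZyme-bounded cluster enumeration and hypergeometric enrichment scoring.

A candidate cluster is a window of consecutive genes (by scaffold ordinal)
whose first and last genes carry the label of interest. Each window of n
genes containing k labelled genes is scored against the genome-wide census
(N genes, K labelled) with the upper hypergeometric tail P(X >= k); windows
at or below the significance threshold are merged into enzyme-dense regions.

The tail probability is computed in log space from log-factorials
(scipy.special.gammaln), which keeps clusters with astronomically small
P-values finite and comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .models import GenomeModel

log = logging.getLogger(__name__)


@dataclass
class EnrichmentParams:
    """Tunable knobs of the cluster search.

    alpha: raw P-value threshold (inclusive), default 0.001.
    max_window_genes: cap on window size in genes, default 50.
    min_hits: minimum labelled genes per window; >=2 because both window
        endpoints must be labelled.
    label: which census to test, 'cazyme' (all CAZymes) or 'pcwde'.
    bonferroni: optionally divide alpha by the number of candidates tested.
    top_regions: optionally keep only the m merged regions with smallest
        minimum P (None keeps all).
    """

    alpha: float = 0.001
    max_window_genes: int = 50
    min_hits: int = 2
    label: str = "cazyme"
    bonferroni: bool = False
    top_regions: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_hits < 2:
            raise ValueError(f"min_hits must be >= 2, got {self.min_hits}")
        if self.max_window_genes < 2:
            raise ValueError(
                f"max_window_genes must be >= 2, got {self.max_window_genes}"
            )
        if self.label not in ("cazyme", "pcwde"):
            raise ValueError(f"label must be 'cazyme' or 'pcwde', got {self.label!r}")


@dataclass
class CandidateCluster:
    """A labelled-gene-bounded window with its enrichment P-value."""

    scaffold_id: str
    first_ordinal: int
    last_ordinal: int
    n_window: int
    k_hits: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n_window != self.last_ordinal - self.first_ordinal + 1:
            raise ValueError("n_window inconsistent with ordinal bounds")
        if not 0 < self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside (0,1]")


@dataclass
class EnrichedRegion:
    """Union of transitively overlapping significant clusters on one scaffold."""

    region_id: str
    scaffold_id: str
    start: int
    end: int
    first_ordinal: int
    last_ordinal: int
    member_clusters: list[CandidateCluster] = field(default_factory=list)
    n_label_genes: int = 0
    min_p: float = 1.0

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class RegionSummary:
    """Genome-level summary of enzyme-dense regions."""

    n_regions: int
    total_length_bp: int
    genome_fraction_pct: float
    label_genes_in_regions: int
    label_gene_fraction_pct: float


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Population of N genes, K of them labelled, a window of n genes drawn
    without replacement, k observed labelled genes. Computed by summing
    log-space terms log C(K,i) + log C(N-K,n-i) - log C(N,n) over
    i = k .. min(n, K). Returns 1.0 for k <= 0.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"invalid hypergeometric arguments N={N}, K={K}, n={n}, k={k} "
            "(need 0 <= k <= n <= N and k <= K <= N)"
        )
    if k <= 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    if i.size == 0:
        # unreachable given the argument checks, kept for safety
        return 0.0

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_terms = logC(K, i) + logC(N - K, n - i) - logC(N, n)
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def enumerate_candidates(
    genome: GenomeModel, params: EnrichmentParams | None = None
) -> list[CandidateCluster]:
    """Enumerate every labelled-gene-bounded window up to the size cap.

    For each scaffold, every ordinal interval [i, j] (i < j) whose endpoint
    genes are both label-positive and whose size j-i+1 is at most
    ``max_window_genes`` is emitted with its window size, hit count and
    hypergeometric tail P-value against the genome-wide background.
    Emission order: scaffold, then first ordinal, then last ordinal.
    """
    params = params or EnrichmentParams()
    N = genome.n_genes
    K = genome.k_label(params.label)
    candidates: list[CandidateCluster] = []
    for scaffold in genome.scaffolds:
        flags = np.array(
            [g.has_label(params.label) for g in scaffold.genes], dtype=int
        )
        label_ordinals = np.flatnonzero(flags)
        if label_ordinals.size < 2:
            continue
        cum = np.concatenate([[0], np.cumsum(flags)])  # hits in [0, i)
        for a_idx, i in enumerate(label_ordinals[:-1]):
            for j in label_ordinals[a_idx + 1 :]:
                n_window = int(j - i + 1)
                if n_window > params.max_window_genes:
                    break
                k_hits = int(cum[j + 1] - cum[i])
                if k_hits < params.min_hits:
                    continue
                candidates.append(
                    CandidateCluster(
                        scaffold_id=scaffold.scaffold_id,
                        first_ordinal=int(i),
                        last_ordinal=int(j),
                        n_window=n_window,
                        k_hits=k_hits,
                        p_value=hypergeom_tail(N, K, n_window, k_hits),
                    )
                )
    return candidates


def significant_clusters(
    candidates: list[CandidateCluster], params: EnrichmentParams | None = None
) -> list[CandidateCluster]:
    """Keep candidates with P <= alpha (inclusive), preserving order.

    No multiple-testing adjustment by default; with ``bonferroni`` the
    threshold becomes alpha / number of candidates tested.
    """
    params = params or EnrichmentParams()
    alpha = params.alpha
    if params.bonferroni and candidates:
        alpha = params.alpha / len(candidates)
    return [c for c in candidates if c.p_value <= alpha]


def merge_regions(
    significant: list[CandidateCluster],
    genome: GenomeModel,
    params: EnrichmentParams | None = None,
) -> list[EnrichedRegion]:
    """Union overlapping/touching significant clusters into maximal regions.

    Clusters on one scaffold whose ordinal intervals overlap or touch
    (adjacent ranks) are merged transitively. Region bp bounds span from the
    first member gene's start to the last member gene's end; the labelled
    gene count is over distinct genes in the union. Regions are sorted by
    scaffold then start and given sequential IDs C1, C2, ...
    """
    params = params or EnrichmentParams()
    regions: list[EnrichedRegion] = []
    by_scaffold: dict[str, list[CandidateCluster]] = {}
    for c in significant:
        by_scaffold.setdefault(c.scaffold_id, []).append(c)

    for sid in sorted(by_scaffold):
        clusters = sorted(
            by_scaffold[sid], key=lambda c: (c.first_ordinal, c.last_ordinal)
        )
        scaffold = genome.scaffold(sid)
        group: list[CandidateCluster] = []
        lo = hi = -1
        for c in clusters + [None]:  # sentinel flushes the last group
            if c is not None and (not group or c.first_ordinal <= hi + 1):
                group.append(c)
                lo = min(lo, c.first_ordinal) if group[1:] else c.first_ordinal
                hi = max(hi, c.last_ordinal)
                continue
            if group:
                member_genes = scaffold.genes[lo : hi + 1]
                regions.append(
                    EnrichedRegion(
                        region_id="",
                        scaffold_id=sid,
                        start=member_genes[0].start,
                        end=member_genes[-1].end,
                        first_ordinal=lo,
                        last_ordinal=hi,
                        member_clusters=group,
                        n_label_genes=sum(
                            g.has_label(params.label) for g in member_genes
                        ),
                        min_p=min(m.p_value for m in group),
                    )
                )
            if c is not None:
                group = [c]
                lo, hi = c.first_ordinal, c.last_ordinal

    regions.sort(key=lambda r: (r.scaffold_id, r.start))
    if params.top_regions is not None:
        keep = set(
            id(r)
            for r in sorted(regions, key=lambda r: (r.min_p, r.scaffold_id, r.start))[
                : params.top_regions
            ]
        )
        regions = [r for r in regions if id(r) in keep]
    for i, r in enumerate(regions, start=1):
        r.region_id = f"C{i}"
    return regions


def summarize_regions(
    regions: list[EnrichedRegion], genome: GenomeModel, label: str = "cazyme"
) -> RegionSummary:
    """Total region length and the genome / labelled-gene fractions.

    Percentages are rounded to one decimal for reporting, the usual
    convention of genome report summaries (e.g. 0.72 Mb of a 30.19 Mb
    genome -> 2.4%).
    """
    genome_bp = genome.total_length_bp
    if genome_bp <= 0:
        raise ValueError("genome has zero total length")
    total_bp = sum(r.length_bp for r in regions)
    n_label = sum(r.n_label_genes for r in regions)
    K = genome.k_label(label)
    return RegionSummary(
        n_regions=len(regions),
        total_length_bp=total_bp,
        genome_fraction_pct=round(100.0 * total_bp / genome_bp, 1),
        label_genes_in_regions=n_label,
        label_gene_fraction_pct=round(100.0 * n_label / K, 1) if K else 0.0,
    )


def candidates_table(candidates: list[CandidateCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold_id": c.scaffold_id,
                "first_ordinal": c.first_ordinal,
                "last_ordinal": c.last_ordinal,
                "n_window": c.n_window,
                "k_hits": c.k_hits,
                "p_value": c.p_value,
            }
            for c in candidates
        ],
        columns=[
            "scaffold_id",
            "first_ordinal",
            "last_ordinal",
            "n_window",
            "k_hits",
            "p_value",
        ],
    )


def regions_table(regions: list[EnrichedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "scaffold_id": r.scaffold_id,
                "start": r.start,
                "end": r.end,
                "length_bp": r.length_bp,
                "first_ordinal": r.first_ordinal,
                "last_ordinal": r.last_ordinal,
                "n_clusters": len(r.member_clusters),
                "n_label_genes": r.n_label_genes,
                "min_p": r.min_p,
            }
            for r in regions
        ],
        columns=[
            "region_id",
            "scaffold_id",
            "start",
            "end",
            "length_bp",
            "first_ordinal",
            "last_ordinal",
            "n_clusters",
            "n_label_genes",
            "min_p",
        ],
    )
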