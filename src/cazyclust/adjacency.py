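"""Adjacent enzyme-gene runs and paralogy exclusion.

Tandem pairs/triplets of plant-cell-wall-degrading-enzyme genes can arise
either by local gene duplication or by relocation of unrelated genes into
one neighbourhood. This module finds maximal runs of consecutive labelled
genes in the scaffold gene order and flags runs containing a protein pair
that passes a global-alignment identity/coverage screen — the runs NOT
flagged are the ones duplication cannot explain.

Alignment is plain Needleman-Wunsch with linear gap costs; the scoring and
traceback tie-break (diagonal, then up, then left) are fixed so identity
percentages are reproducible to the digit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np

from .models import GenomeModel

log = logging.getLogger(__name__)

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class ParalogyParams:
    """Thresholds and alignment scores of the paralogy screen.

    A pair is called paralogous when identity_pct >= min_identity_pct AND
    coverage_pct >= min_coverage_pct. Scores: match +1, mismatch -1, linear
    gap -2 per residue.
    """

    min_identity_pct: float = 30.0
    min_coverage_pct: float = 50.0
    match_score: int = 1
    mismatch_score: int = -1
    gap_penalty: int = -2

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity_pct <= 100.0:
            raise ValueError("min_identity_pct must be in (0, 100]")
        if not 0.0 < self.min_coverage_pct <= 100.0:
            raise ValueError("min_coverage_pct must be in (0, 100]")


@dataclass
class AdjacentRun:
    """A maximal run of >= 2 consecutive labelled genes on one scaffold."""

    scaffold_id: str
    ordinals: list[int]
    gene_ids: list[str]
    contains_paralog_pair: Optional[bool] = None  # None = not yet screened / unknown
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def run_length(self) -> int:
        return len(self.ordinals)


def find_adjacent_runs(genome: GenomeModel, label: str = "pcwde") -> list[AdjacentRun]:
    """Maximal runs of consecutive label-positive ordinals, length >= 2.

    A length-L run is reported once (a triplet is not also two pairs).
    Output sorted by scaffold, then run start.
    """
    runs: list[AdjacentRun] = []
    for scaffold in sorted(genome.scaffolds, key=lambda s: s.scaffold_id):
        current: list = []
        for gene in scaffold.genes + [None]:  # sentinel flushes the last run
            if gene is not None and gene.has_label(label):
                current.append(gene)
                continue
            if len(current) >= 2:
                runs.append(
                    AdjacentRun(
                        scaffold_id=scaffold.scaffold_id,
                        ordinals=[g.ordinal for g in current],
                        gene_ids=[g.gene_id for g in current],
                    )
                )
            current = []
    return runs


def _needleman_wunsch(a: str, b: str, params: ParalogyParams) -> tuple[str, str, int]:
    """Global alignment of a vs b; returns (aligned_a, aligned_b, score).

    Traceback prefers diagonal, then up (gap in b), then left (gap in a).
    """
    la, lb = len(a), len(b)
    gap = params.gap_penalty
    score = np.zeros((la + 1, lb + 1), dtype=np.int64)
    score[:, 0] = np.arange(la + 1) * gap
    score[0, :] = np.arange(lb + 1) * gap
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(
        a_arr[:, None] == b_arr[None, :], params.match_score, params.mismatch_score
    )
    for i in range(1, la + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + gap
        row = score[i]
        prev = row[0]
        best = np.maximum(diag, up)
        for j in range(1, lb + 1):
            prev = max(best[j - 1], prev + gap)
            row[j] = prev

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score[la, lb])


def global_identity(
    seq_a: str, seq_b: str, params: ParalogyParams | None = None
) -> tuple[float, float]:
    """Percent identity and coverage from a global protein alignment.

    identity_pct: 100 * identical columns / alignment length (gap columns
    in the denominator). coverage_pct: 100 * columns where both sequences
    have residues / length of the shorter sequence.
    """
    params = params or ParalogyParams()
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise ValueError(f"{name} is empty")
        bad = set(s.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters {sorted(bad)}")
    a, b = seq_a.upper(), seq_b.upper()
    aln_a, aln_b, _ = _needleman_wunsch(a, b, params)
    ncols = len(aln_a)
    matches = sum(x == y and x != "-" for x, y in zip(aln_a, aln_b))
    both = sum(x != "-" and y != "-" for x, y in zip(aln_a, aln_b))
    identity_pct = 100.0 * matches / ncols
    coverage_pct = 100.0 * both / min(len(a), len(b))
    return identity_pct, coverage_pct


def alignment_score(seq_a: str, seq_b: str, params: ParalogyParams | None = None) -> int:
    """Optimal global alignment score under the configured linear-gap scheme."""
    params = params or ParalogyParams()
    return _needleman_wunsch(seq_a.upper(), seq_b.upper(), params)[2]


def is_paralog_pair(
    seq_a: str, seq_b: str, params: ParalogyParams | None = None
) -> bool:
    params = params or ParalogyParams()
    ident, cov = global_identity(seq_a, seq_b, params)
    return ident >= params.min_identity_pct and cov >= params.min_coverage_pct


def flag_paralogous_runs(
    runs: list[AdjacentRun],
    proteins: dict[str, str],
    params: ParalogyParams | None = None,
    paralog_groups: Optional[dict[str, str]] = None,
) -> list[AdjacentRun]:
    """Set ``contains_paralog_pair`` on every run (modified in place).

    True iff any within-run gene pair meets both the identity and coverage
    thresholds. A precomputed paralog-group table (gene_id -> group label)
    overrides alignment for pairs where both genes have a group. Runs with
    genes lacking protein sequences stay unknown (None) and are logged.
    """
    params = params or ParalogyParams()
    for run in runs:
        missing = [g for g in run.gene_ids if g not in proteins]
        if missing and paralog_groups is None:
            log.warning(
                "run %s:%s has no protein for %s; paralogy unknown",
                run.scaffold_id,
                run.ordinals,
                missing,
            )
            run.contains_paralog_pair = None
            continue
        flagged = False
        pairs = []
        for ga, gb in combinations(run.gene_ids, 2):
            if (
                paralog_groups is not None
                and ga in paralog_groups
                and gb in paralog_groups
            ):
                same = paralog_groups[ga] == paralog_groups[gb]
            elif ga in proteins and gb in proteins:
                same = is_paralog_pair(proteins[ga], proteins[gb], params)
            else:
                run.contains_paralog_pair = None
                log.warning(
                    "run %s:%s pair (%s, %s) lacks both sequences and groups",
                    run.scaffold_id,
                    run.ordinals,
                    ga,
                    gb,
                )
                break
            if same:
                flagged = True
                pairs.append((ga, gb))
        else:
            run.contains_paralog_pair = flagged
            run.paralog_pairs = pairs
    return runs
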