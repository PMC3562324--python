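"""Terminal telomeric tandem-repeat detection and chromosome classification.

Fungal telomeres carry short tandem repeats — here 5'-TTAGGGG-3' — at
chromosome termini. On the forward strand of an assembled scaffold the
forward motif accumulates at the 3' end and its reverse complement at the
5' end; a scaffold with arrays at BOTH ends is a putative full chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

from Bio.Seq import Seq

from .models import Scaffold

log = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_VALID_SEQ_CHARS = frozenset("ACGTN")


@dataclass
class TelomereParams:
    """Motif and calling thresholds for the terminal repeat scan.

    motif: forward-strand telomeric repeat unit (default TTAGGGG).
    window_bp: terminal window searched at each scaffold end (default 500).
    min_copies: minimum head-to-tail copies to call an array (default 3).
    max_mismatch_per_copy: mismatches tolerated within each copy (default 0,
        i.e. exact matching; N never matches).
    """

    motif: str = "TTAGGGG"
    window_bp: int = 500
    min_copies: int = 3
    max_mismatch_per_copy: int = 0

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be non-empty over ACGT, got {self.motif!r}")
        if self.window_bp < len(self.motif) * self.min_copies:
            raise ValueError(
                "window_bp must be at least motif length * min_copies "
                f"({len(self.motif) * self.min_copies}), got {self.window_bp}"
            )


@dataclass
class TelomereHit:
    """A tandem motif array found at one scaffold terminus."""

    scaffold_id: str
    terminus: str  # FIVE_PRIME or THREE_PRIME
    motif: str
    copies: int
    span_start: int  # 0-based half-open, scaffold coordinates
    span_end: int


class ChromosomeCall(NamedTuple):
    scaffold_id: str
    five_prime: Optional[TelomereHit]
    three_prime: Optional[TelomereHit]
    is_putative_chromosome: Optional[bool]  # None when no sequence available


def _copies_match(seq: str, motif: str, max_mismatch: int) -> bool:
    if len(seq) != len(motif):
        return False
    mm = 0
    for a, b in zip(seq, motif):
        if a == "N" or a != b:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def _longest_run(window: str, motif: str, max_mismatch: int) -> tuple[int, int]:
    """Longest head-to-tail run of motif copies in ``window``.

    Returns (best_copies, best_start); ties go to the earliest start.
    Naive quadratic scan — terminal windows are a few hundred bp.
    """
    m = len(motif)
    best_copies, best_start = 0, 0
    run_at: dict[int, int] = {}  # start -> copies, filled right-to-left
    for start in range(len(window) - m, -1, -1):
        if _copies_match(window[start : start + m], motif, max_mismatch):
            run_at[start] = 1 + run_at.get(start + m, 0)
    for start in sorted(run_at):
        if run_at[start] > best_copies:
            best_copies, best_start = run_at[start], start
    return best_copies, best_start


def scan_terminus(
    sequence: str,
    terminus: str,
    params: TelomereParams | None = None,
    scaffold_id: str = "",
) -> Optional[TelomereHit]:
    """Scan one terminal window for a tandem telomeric array.

    The forward motif is sought near the 3' end and its reverse complement
    near the 5' end. Returns a hit iff the longest head-to-tail run has at
    least ``min_copies`` copies, else None. Sequences shorter than the
    window are scanned over their whole length.
    """
    params = params or TelomereParams()
    sequence = sequence.upper()
    bad = set(sequence) - _VALID_SEQ_CHARS
    if bad:
        raise ValueError(
            f"sequence contains non-ACGTN character(s): {sorted(bad)}"
        )
    if terminus not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"terminus must be five_prime or three_prime, got {terminus!r}")

    w = min(params.window_bp, len(sequence))
    if terminus == FIVE_PRIME:
        window = sequence[:w]
        offset = 0
        motif = str(Seq(params.motif).reverse_complement())
    else:
        window = sequence[-w:]
        offset = len(sequence) - w
        motif = params.motif

    copies, start = _longest_run(window, motif, params.max_mismatch_per_copy)
    if copies < params.min_copies:
        return None
    span_start = offset + start
    return TelomereHit(
        scaffold_id=scaffold_id,
        terminus=terminus,
        motif=motif,
        copies=copies,
        span_start=span_start,
        span_end=span_start + copies * len(motif),
    )


def classify_chromosomes(
    scaffolds: list[Scaffold], params: TelomereParams | None = None
) -> list[ChromosomeCall]:
    """Call putative chromosomes: telomeric arrays at both termini.

    Scaffolds without sequence are classified unknown (None). Each
    scaffold's ``is_putative_chromosome`` flag is updated in place.
    """
    params = params or TelomereParams()
    calls = []
    for s in scaffolds:
        if s.sequence is None:
            s.is_putative_chromosome = None
            calls.append(ChromosomeCall(s.scaffold_id, None, None, None))
            continue
        five = scan_terminus(s.sequence, FIVE_PRIME, params, s.scaffold_id)
        three = scan_terminus(s.sequence, THREE_PRIME, params, s.scaffold_id)
        is_chrom = five is not None and three is not None
        s.is_putative_chromosome = is_chrom
        calls.append(ChromosomeCall(s.scaffold_id, five, three, is_chrom))
    return calls
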