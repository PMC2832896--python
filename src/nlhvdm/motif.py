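"""Consensus-motif counting on upstream promoter windows.

Counts perfect matches of a degenerate IUPAC pattern — by default the 10 bp
p53 consensus half-site pair RRRCWWGYYY (R = A/G, W = A/T, Y = C/T) — on the
5 kb and 10 kb windows directly upstream of the transcription start site, and
bins genes by match count (0 / 1 / 2 / >2).

Scanning is stride-1 (overlapping matches counted) and forward-strand only:
this pattern equals its own reverse complement as a degenerate motif, so
forward counting already covers both strands.  ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InvalidInputError, InvalidPatternError

__all__ = [
    "P53_CONSENSUS",
    "MotifReport",
    "count_consensus",
    "categorize",
    "scan_fasta",
    "reverse_complement",
]

P53_CONSENSUS = "RRRCWWGYYY"
CATEGORIES = ("0", "1", "2", ">2")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class MotifReport:
    """Per-gene consensus-site count on one upstream window."""

    gene_id: str
    window: int
    count: int
    category: str
    truncated: bool = False  # available sequence shorter than the window


def count_consensus(sequence: str, pattern: str = P53_CONSENSUS) -> int:
    """Number of stride-1 window positions matching the IUPAC pattern.

    Ambiguity codes in the *pattern* expand to their base sets; any sequence
    character outside a position's allowed set (including N) fails the match.
    """
    pattern = pattern.upper()
    if not pattern:
        raise InvalidPatternError("empty pattern")
    for ch in pattern:
        if ch not in IUPAC:
            raise InvalidPatternError(f"invalid IUPAC code '{ch}' in pattern")
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    L, W = seq.size, len(pattern)
    if L < W:
        return 0
    ok = np.ones(L - W + 1, dtype=bool)
    for offset, ch in enumerate(pattern):
        allowed = np.zeros(256, dtype=bool)
        for base in IUPAC[ch]:
            allowed[ord(base)] = True
        ok &= allowed[seq[offset : offset + L - W + 1]]
    return int(ok.sum())


def categorize(count: int) -> str:
    """Bin a match count as 0 / 1 / 2 / >2."""
    if count < 0:
        raise InvalidInputError("count must be >= 0")
    return str(count) if count <= 2 else ">2"


def scan_fasta(fasta, windows: Sequence[int] = (5000, 10000),
               pattern: str = P53_CONSENSUS):
    """Scan upstream sequences and tabulate the per-window count distribution.

    ``fasta`` is a path or an iterable of ``(gene_id, sequence)`` pairs.  Each
    sequence runs 5'->3' and ends at the TSS, so a window of length L is the
    last L bases (the 5 kb window is the TSS-proximal half of a 10 kb
    sequence).  Shorter sequences are scanned as-is and flagged truncated.

    Returns ``(reports, table)`` where ``table`` is a DataFrame of per-window
    category fractions (rows = categories 0/1/2/>2, columns = window sizes).
    """
    if hasattr(fasta, "read") or isinstance(fasta, (str, Path)):
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fasta, "fasta")]
    else:
        records = [(gid, str(seq)) for gid, seq in fasta]

    reports: list[MotifReport] = []
    for gid, seq in records:
        for L in windows:
            sub = seq[-int(L):] if len(seq) > int(L) else seq
            count = count_consensus(sub, pattern)
            reports.append(MotifReport(
                gene_id=gid, window=int(L), count=count,
                category=categorize(count), truncated=len(seq) < int(L),
            ))

    table = pd.DataFrame(0.0, index=list(CATEGORIES), columns=[int(w) for w in windows])
    if records:
        for L in windows:
            cats = [r.category for r in reports if r.window == int(L)]
            for cat in CATEGORIES:
                table.loc[cat, int(L)] = cats.count(cat) / len(cats)
    return reports, table
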