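"""k-mer-seeded Smith-Waterman local alignment of short reads.

A read is aligned only against transcripts sharing at least one exact
``seed_k``-mer with it (both orientations when ``strand_mode="both"``).
Each candidate is scored by full local dynamic programming with match /
mismatch / linear-gap scores, and the single best alignment is reported
if it clears ``min_score_fraction`` of the read's maximum attainable
score; otherwise the read is unmapped.  Ties are broken by fewer edits,
then by transcript order in the reference.

The DP matrix fill is numba-compiled; the traceback (linear in the
alignment length) runs in Python.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .io_formats import Read, ReferenceSet, encode_phred

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and seeding parameters.

    seed_k: exact k-mer length for candidate selection (>= 4).
    match / mismatch / gap: per-base scores (gap is linear, per base).
    min_score_fraction: fraction of ``match * read_length`` required to
        call a read mapped.
    strand_mode: "forward_only" (directional small-RNA libraries) or
        "both".
    """

    seed_k: int = 10
    match: int = 2
    mismatch: int = -2
    gap: int = -4
    min_score_fraction: float = 0.8
    strand_mode: str = "forward_only"

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("require match > 0, mismatch < 0, gap < 0")
        if not 0 < self.min_score_fraction <= 1:
            raise ValueError("min_score_fraction must be in (0, 1]")
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")
        if self.strand_mode not in ("forward_only", "both"):
            raise ValueError("strand_mode must be 'forward_only' or 'both'")


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-transcript local alignment.

    ``cigar`` covers the aligned read interval [read_start, read_end);
    ``sam_cigar`` adds soft clips for the unaligned read ends.  ``edits``
    counts mismatches plus gap bases.
    """

    read_id: str
    transcript_id: str
    ref_start: int  # 0-based
    cigar: str
    score: int
    strand: str = "+"
    edits: int = 0
    read_start: int = 0
    read_end: int = 0
    seq: Optional[str] = None
    qual: Optional[tuple[int, ...]] = None

    def sam_cigar(self) -> str:
        if self.seq is None:
            return self.cigar
        left = self.read_start
        right = len(self.seq) - self.read_end
        parts = []
        if left:
            parts.append(f"{left}S")
        parts.append(self.cigar)
        if right:
            parts.append(f"{right}S")
        return "".join(parts)


UNMAPPED = None  # sentinel: align_read returns None for unmapped reads


def encode_seq(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _sw_fill(read: np.ndarray, ref: np.ndarray, match: int, mismatch: int,
             gap: int):  # pragma: no cover - exercised via smith_waterman
    n, m = len(read), len(ref)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, m + 1):
            # N (ASCII 78) never matches, not even another N
            if ri == ref[j - 1] and ri != 78:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] + mismatch
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            score = diag
            p = 1
            if up > score:
                score = up
                p = 2
            if left > score:
                score = left
                p = 3
            if score <= 0:
                score = 0
                p = 0
            H[i, j] = score
            ptr[i, j] = p
            if score > best:
                best = score
                bi = i
                bj = j
    return H, ptr, best, bi, bj


def smith_waterman(read_seq: str, ref_seq: str, params: AlignParams
                   ) -> tuple[int, int, int, int, str, int]:
    """Full local alignment of read vs reference.

    Returns (score, ref_start, read_start, read_end, cigar, edits) for
    the best-scoring local alignment; score 0 means no positive-scoring
    alignment exists.  The first maximum in row-major matrix order wins,
    and the traceback prefers diagonal moves, making the result
    deterministic.
    """
    H, ptr, best, bi, bj = _sw_fill(
        encode_seq(read_seq), encode_seq(ref_seq),
        params.match, params.mismatch, params.gap,
    )
    if best <= 0:
        return 0, 0, 0, 0, "", 0
    ops: list[str] = []
    edits = 0
    i, j = bi, bj
    while ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            ops.append("M")
            if not (read_seq[i - 1] == ref_seq[j - 1] and read_seq[i - 1] != "N"):
                edits += 1
            i -= 1
            j -= 1
        elif p == 2:  # gap in reference: insertion relative to ref
            ops.append("I")
            edits += 1
            i -= 1
        else:  # gap in read: deletion relative to ref
            ops.append("D")
            edits += 1
            j -= 1
    ops.reverse()
    cigar = _run_length(ops)
    return int(best), j, i, bi, cigar, edits


def _run_length(ops: list[str]) -> str:
    parts = []
    prev = None
    run = 0
    for op in ops:
        if op == prev:
            run += 1
        else:
            if prev is not None:
                parts.append(f"{run}{prev}")
            prev = op
            run = 1
    if prev is not None:
        parts.append(f"{run}{prev}")
    return "".join(parts)


@dataclass
class SeedIndex:
    """Exact k-mer -> (transcript order, offset) positions, plus the
    transcripts too short to hold a full k-mer (always candidates)."""

    seed_k: int
    kmers: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    short_transcripts: list[int] = field(default_factory=list)
    n_positions: int = 0


def build_index(reference_set: ReferenceSet, seed_k: int = 10) -> SeedIndex:
    """Index every k-mer position of every transcript."""
    index = SeedIndex(seed_k=seed_k)
    for order, t in enumerate(reference_set):
        seq = t.seq
        if len(seq) < seed_k:
            index.short_transcripts.append(order)
            continue
        for off in range(len(seq) - seed_k + 1):
            index.kmers.setdefault(seq[off:off + seed_k], []).append((order, off))
            index.n_positions += 1
    return index


def _candidates(seq: str, index: SeedIndex) -> set[int]:
    k = index.seed_k
    hits: set[int] = set(index.short_transcripts)
    for off in range(len(seq) - k + 1):
        for order, _ in index.kmers.get(seq[off:off + k], ()):
            hits.add(order)
    return hits


def align_read(read: Read, index: SeedIndex, reference_set: ReferenceSet,
               params: AlignParams) -> Optional[AlignmentRecord]:
    """Align one read; returns the best AlignmentRecord or None (unmapped)."""
    min_score = params.min_score_fraction * params.match * len(read)
    orientations = [("+", read.seq)]
    if params.strand_mode == "both":
        orientations.append(("-", reverse_complement(read.seq)))
    best: Optional[AlignmentRecord] = None
    best_key: Optional[tuple[int, int, int]] = None
    for strand, seq in orientations:
        for order in sorted(_candidates(seq, index)):
            t = reference_set.transcripts[order]
            score, ref_start, r_start, r_end, cigar, edits = smith_waterman(
                seq, t.seq, params)
            if score < min_score or score <= 0:
                continue
            # maximize score, then minimize edits, then transcript order
            key = (-score, edits, order)
            if best_key is None or key < best_key:
                best_key = key
                qual = read.qual if strand == "+" else read.qual[::-1]
                best = AlignmentRecord(
                    read_id=read.read_id, transcript_id=t.transcript_id,
                    ref_start=ref_start, cigar=cigar, score=score,
                    strand=strand, edits=edits, read_start=r_start,
                    read_end=r_end, seq=seq, qual=qual,
                )
    return best
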