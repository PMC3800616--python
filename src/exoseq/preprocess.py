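"""3' read cleanup: quality trimming at Q17, a 17-nt length floor, and
3' adapter trimming.

The order is fixed: quality trim, length check, adapter trim, length
check.  Reads whose length falls below the floor at either checkpoint
are dropped (returned as None) and tallied by reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import edlib

from .io_formats import Read

QUALITY_STEP = "quality_trim"
ADAPTER_STEP = "adapter_trim"


@dataclass(frozen=True)
class PreprocessParams:
    """Cleanup thresholds.

    quality_threshold: trailing bases with PHRED quality below this are
        removed from the 3' end (default 17, about a 2% error rate).
    min_length: reads shorter than this after either trim are dropped
        (default 17 nt, limiting ambiguous mappings of very short reads).
    adapter_seq: the platform's 3' adapter; empty string disables
        adapter trimming.
    max_error_rate: edits tolerated per matched adapter base.
    min_overlap: shortest adapter prefix accepted as a match.
    """

    quality_threshold: int = 17
    min_length: int = 17
    adapter_seq: str = ""
    max_error_rate: float = 0.1
    min_overlap: int = 3

    def __post_init__(self) -> None:
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class DropLog:
    """Per-reason drop counts; kept + dropped reconciles with input."""

    input_reads: int = 0
    kept: int = 0
    dropped_quality_length: int = 0
    dropped_adapter_length: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_quality_length + self.dropped_adapter_length


def quality_trim(read: Read, params: PreprocessParams) -> Optional[Read]:
    """Remove trailing 3' bases with quality below the threshold.

    Stops at the first base from the 3' end with quality >= threshold.
    Returns None (dropped) if the trimmed read is shorter than
    ``params.min_length``.
    """
    keep = len(read)
    while keep > 0 and read.qual[keep - 1] < params.quality_threshold:
        keep -= 1
    if keep == len(read):
        return read
    trimmed = read.trimmed(keep, QUALITY_STEP)
    if len(trimmed) < params.min_length:
        return None
    return trimmed


def find_adapter(seq: str, adapter: str, max_error_rate: float,
                 min_overlap: int) -> Optional[int]:
    """Locate the best 3' adapter match; return its start index or None.

    At each candidate start ``s`` a prefix of the adapter is compared
    against ``seq[s:]`` under unit-cost edit distance; the match is
    accepted when edits <= floor(max_error_rate * matched adapter length)
    and the matched length >= min_overlap.  The best match maximizes the
    number of matching bases (matched length minus edits); ties are
    broken by longest matched length, then leftmost start.  N never
    matches a base.
    """
    if not adapter:
        return None
    best: Optional[tuple[int, int, int]] = None  # (matches, matched_len, -start)
    best_start: Optional[int] = None
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        matched_len = min(len(adapter), n - start)
        if matched_len < min_overlap:
            break
        fragment = seq[start:start + matched_len]
        prefix = adapter[:matched_len]
        allowed = int(max_error_rate * matched_len)
        if allowed == 0:
            edits = 0 if fragment == prefix else allowed + 1
        else:
            edits = edlib.align(fragment, prefix, mode="NW", k=allowed)["editDistance"]
            if edits < 0:  # edlib reports -1 beyond k
                edits = allowed + 1
        if edits <= allowed:
            key = (matched_len - edits, matched_len, -start)
            if best is None or key > best:
                best = key
                best_start = start
    return best_start


def trim_adapter(read: Read, params: PreprocessParams) -> Optional[Read]:
    """Remove a 3' adapter match (and everything after it) from the read.

    If no qualifying match exists the read is returned unchanged; if the
    trimmed read is shorter than ``params.min_length`` it is dropped.
    """
    if not params.adapter_seq:
        return read
    start = find_adapter(read.seq, params.adapter_seq,
                         params.max_error_rate, params.min_overlap)
    if start is None:
        return read
    trimmed = read.trimmed(start, ADAPTER_STEP)
    if len(trimmed) < params.min_length:
        return None
    return trimmed


def preprocess_read(read: Read, params: PreprocessParams
                    ) -> tuple[Optional[Read], Optional[str]]:
    """Apply quality trim then adapter trim; returns (read, drop_reason).

    The length floor is checked after each step whether or not trimming
    fired, so undersized inputs are dropped too.
    """
    trimmed = quality_trim(read, params)
    if trimmed is None or len(trimmed) < params.min_length:
        return None, "quality_length"
    trimmed = trim_adapter(trimmed, params)
    if trimmed is None or len(trimmed) < params.min_length:
        return None, "adapter_length"
    return trimmed, None


def preprocess_stream(reads: Iterable[Read], params: PreprocessParams
                      ) -> tuple[list[Read], DropLog]:
    """Clean a stream of reads; returns kept reads and a drop log."""
    log = DropLog()
    kept: list[Read] = []
    for read in reads:
        log.input_reads += 1
        out, reason = preprocess_read(read, params)
        if out is None:
            if reason == "quality_length":
                log.dropped_quality_length += 1
            else:
                log.dropped_adapter_length += 1
        else:
            kept.append(out)
            log.kept += 1
    return kept, log
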