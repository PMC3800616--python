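"""Readers and writers for the pipeline's on-disk formats.

FASTQ (4-line, PHRED+33 by default), FASTA references with RNA-class
annotations, minimal SAM v1.x output, and tab-separated per-transcript
count tables.  Internal coordinates are 0-based half-open; SAM POS is
1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO

RNA_CLASSES = frozenset({"miRNA", "tRNA", "rRNA", "mRNA", "ncRNA", "other"})

DEFAULT_PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Malformed FASTQ input; message carries the offending line number."""


class ReferenceError_(ValueError):
    """Malformed or inconsistent reference input."""


@dataclass(frozen=True)
class Read:
    """One sequencing read with per-base qualities and trim provenance.

    ``provenance`` is an ordered tuple of ``(step_name, bases_removed)``
    entries; the original read length is the current length plus the sum
    of all ``bases_removed``.
    """

    read_id: str
    seq: str
    qual: tuple[int, ...]
    provenance: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id!r}: seq length {len(self.seq)} != "
                f"qual length {len(self.qual)}"
            )
        if any(q < 0 for q in self.qual):
            raise ValueError(f"read {self.read_id!r}: negative quality score")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def original_length(self) -> int:
        return len(self.seq) + sum(n for _, n in self.provenance)

    def trimmed(self, new_length: int, step: str) -> "Read":
        """Return a copy keeping the first ``new_length`` bases, recording
        the step in provenance (recorded even when nothing was removed)."""
        removed = len(self.seq) - new_length
        if removed < 0:
            raise ValueError("cannot grow a read by trimming")
        return replace(
            self,
            seq=self.seq[:new_length],
            qual=self.qual[:new_length],
            provenance=self.provenance + ((step, removed),),
        )


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    seq: str
    rna_class: str
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.transcript_id!r} has empty sequence")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(
                f"transcript {self.transcript_id!r}: unknown RNA class "
                f"{self.rna_class!r}"
            )


@dataclass
class ReferenceSet:
    """Class-annotated transcripts forming one cascade stage's target."""

    stage_label: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.transcripts:
            if t.transcript_id in seen:
                raise ReferenceError_(
                    f"duplicate transcript id {t.transcript_id!r} in "
                    f"reference {self.stage_label!r}"
                )
            seen.add(t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def get(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    @property
    def by_id(self) -> dict[str, Transcript]:
        return {t.transcript_id: t for t in self.transcripts}


@dataclass
class CountTable:
    """Per-transcript mapped-read tallies for one sample/stage.

    ``rows`` preserves insertion order: transcript_id -> (accession,
    rna_class, count).  Counts are non-negative; fractional values are
    allowed for mean-count tables.
    """

    sample_id: str
    stage_label: str
    rows: dict[str, tuple[Optional[str], str, float]] = field(default_factory=dict)

    def total(self) -> float:
        return sum(count for _, _, count in self.rows.values())

    def count(self, transcript_id: str) -> float:
        return self.rows[transcript_id][2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": tid,
                    "accession": acc if acc is not None else "",
                    "rna_class": cls,
                    "count": count,
                }
                for tid, (acc, cls, count) in self.rows.items()
            ],
            columns=["transcript_id", "accession", "rna_class", "count"],
        )


# ---------------------------------------------------------------------------
# PHRED
# ---------------------------------------------------------------------------

def decode_phred(qual_string: str, offset: int = DEFAULT_PHRED_OFFSET,
                 read_id: str = "?") -> tuple[int, ...]:
    """Decode an ASCII quality string into integer PHRED scores."""
    scores = []
    for ch in qual_string:
        score = ord(ch) - offset
        if score < 0:
            raise FastqParseError(
                f"read {read_id!r}: quality character {ch!r} below "
                f"offset {offset}"
            )
        scores.append(score)
    return tuple(scores)


def encode_phred(scores: Iterable[int], offset: int = DEFAULT_PHRED_OFFSET) -> str:
    return "".join(chr(q + offset) for q in scores)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path, offset: int = DEFAULT_PHRED_OFFSET) -> Iterator[Read]:
    """Yield Reads from a 4-line-record FASTQ file, in file order.

    Raises FastqParseError (with the line number) on truncated records or
    seq/qual length mismatches.
    """
    with open(path) as handle:
        yield from parse_fastq(handle, offset=offset)


def parse_fastq(handle: io.TextIOBase, offset: int = DEFAULT_PHRED_OFFSET) -> Iterator[Read]:
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        if not header.startswith("@"):
            raise FastqParseError(f"line {lineno}: expected '@' header, got {header.strip()!r}")
        read_id = header[1:].strip().split()[0] if header[1:].strip() else ""
        if not read_id:
            raise FastqParseError(f"line {lineno}: empty read id")
        lines = [handle.readline() for _ in range(3)]
        if any(not ln for ln in lines):
            raise FastqParseError(f"line {lineno}: truncated record for read {read_id!r}")
        seq, plus, qual = (ln.rstrip("\n") for ln in lines)
        lineno += 3
        if not plus.startswith("+"):
            raise FastqParseError(f"line {lineno - 1}: expected '+' separator")
        if len(seq) != len(qual):
            raise FastqParseError(
                f"line {lineno}: read {read_id!r} seq length {len(seq)} != "
                f"qual length {len(qual)}"
            )
        yield Read(read_id=read_id, seq=seq.upper(),
                   qual=decode_phred(qual, offset, read_id=read_id))


def write_fastq(reads: Iterable[Read], path: str | Path,
                offset: int = DEFAULT_PHRED_OFFSET) -> int:
    """Write reads as 4-line FASTQ records; returns number written."""
    n = 0
    with open(path, "w") as out:
        for read in reads:
            out.write(f"@{read.read_id}\n{read.seq}\n+\n"
                      f"{encode_phred(read.qual, offset)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA references
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, class_map: Optional[dict[str, str]] = None,
               default_class: Optional[str] = None,
               accession_map: Optional[dict[str, str]] = None,
               stage_label: str = "reference") -> ReferenceSet:
    """Load a FASTA reference; sequences are uppercased and U is converted
    to T so RNA-space references align against DNA-space reads."""
    class_map = class_map or {}
    accession_map = accession_map or {}
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        tid = record.id
        if tid in seen:
            raise ReferenceError_(f"duplicate FASTA id {tid!r} in {path}")
        seen.add(tid)
        if tid in class_map:
            cls = class_map[tid]
        elif default_class is not None:
            cls = default_class
        else:
            raise ReferenceError_(
                f"transcript {tid!r} has no RNA class and no default was given"
            )
        seq = str(record.seq).upper().replace("U", "T")
        transcripts.append(Transcript(tid, seq, cls, accession_map.get(tid)))
    return ReferenceSet(stage_label=stage_label, transcripts=transcripts)


def write_fasta(reference: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as out:
        for t in reference:
            out.write(f">{t.transcript_id}\n{t.seq}\n")


def read_class_table(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a transcript metadata TSV (transcript_id, rna_class, accession)
    into (class_map, accession_map)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "transcript_id" not in df.columns or "rna_class" not in df.columns:
        raise ReferenceError_(f"{path}: expected transcript_id and rna_class columns")
    class_map = dict(zip(df["transcript_id"], df["rna_class"]))
    acc_map = {
        tid: acc
        for tid, acc in zip(df["transcript_id"], df.get("accession", ""))
        if acc
    }
    return class_map, acc_map


def write_class_table(reference: ReferenceSet, path: str | Path) -> None:
    rows = [
        {"transcript_id": t.transcript_id, "rna_class": t.rna_class,
         "accession": t.accession or ""}
        for t in reference
    ]
    pd.DataFrame(rows, columns=["transcript_id", "rna_class", "accession"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def write_sam(alignments, reference_set: ReferenceSet, path: str | Path) -> None:
    """Write mapped alignments as minimal SAM v1.6.

    Header: @HD plus one @SQ per reference transcript.  Each record carries
    POS (1-based), a CIGAR with soft clips for unaligned read ends, and the
    alignment score (AS) and edit count (NM) as numeric tags.  Unmapped
    reads are not written; the cascade routes them onward as FASTQ.
    """
    by_id = reference_set.by_id
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for t in reference_set:
            out.write(f"@SQ\tSN:{t.transcript_id}\tLN:{len(t.seq)}\n")
        for aln in alignments:
            if aln.transcript_id not in by_id:
                raise ReferenceError_(
                    f"alignment of {aln.read_id!r} to unknown transcript "
                    f"{aln.transcript_id!r}"
                )
            flag = 16 if aln.strand == "-" else 0
            cigar = aln.sam_cigar()
            qual = encode_phred(aln.qual) if aln.qual is not None else "*"
            out.write(
                f"{aln.read_id}\t{flag}\t{aln.transcript_id}\t{aln.ref_start + 1}"
                f"\t255\t{cigar}\t*\t0\t0\t{aln.seq or '*'}\t{qual}"
                f"\tAS:i:{aln.score}\tNM:i:{aln.edits}\n"
            )


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["transcript_id", "accession", "rna_class", "count"]


def load_count_table(path: str | Path, sample_id: str = "",
                     stage_label: str = "") -> CountTable:
    """Load a 4-column TSV count table, preserving row order.

    Counts may be fractional (mean tables).  Negative counts or missing
    columns raise ValueError.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "accession": str,
                                            "rna_class": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    table = CountTable(sample_id=sample_id or str(path), stage_label=stage_label)
    for tid, acc, cls, count in zip(df["transcript_id"], df["accession"],
                                    df["rna_class"], df["count"]):
        count = float(count)
        if count < 0:
            raise ValueError(f"{path}: negative count for {tid!r}")
        acc = acc if isinstance(acc, str) and acc else None
        table.rows[str(tid)] = (acc, str(cls), count)
    return table


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
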