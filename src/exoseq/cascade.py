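"""Iterative mapping cascade, per-transcript counting, percent-of-mapped
normalization, ranking, top-N overlap, composition, and differential
representation.

The cascade aligns reads against an ordered list of references; reads
mapped at stage *i* are counted there and only the still-unmapped reads
proceed to stage *i+1*, so the per-stage mapped read-ID sets and the
final unmapped set partition the input exactly ("one read, one count").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .aligner import AlignParams, AlignmentRecord, align_read, build_index
from .io_formats import CountTable, Read, ReferenceSet


class CascadeConfigError(ValueError):
    pass


@dataclass
class CascadeConfig:
    """Ordered mapping stages.  The default design mirrors a small-RNA
    workflow: stage 1 = miRNA hairpins + tRNA + rRNA, stage 2 = RefSeq
    transcripts (mRNA + ncRNA), stage 3 = additional ncRNA."""

    stages: list[tuple[str, ReferenceSet]]

    def __post_init__(self) -> None:
        if not self.stages:
            raise CascadeConfigError("cascade needs at least one stage")
        labels = [label for label, _ in self.stages]
        if len(set(labels)) != len(labels):
            raise CascadeConfigError("stage labels must be unique")
        for label, ref in self.stages:
            if len(ref) == 0:
                raise CascadeConfigError(f"stage {label!r} has an empty reference")


@dataclass
class StageResult:
    stage_label: str
    alignments: list[AlignmentRecord]
    counts: CountTable


@dataclass
class CascadeResult:
    sample_id: str
    stages: list[StageResult]
    unmapped: list[Read]

    @property
    def tables(self) -> list[CountTable]:
        return [s.counts for s in self.stages]

    def mapped_total(self) -> int:
        return sum(len(s.alignments) for s in self.stages)


def run_cascade(reads: Sequence[Read], config: CascadeConfig,
                align_params: AlignParams | None = None,
                sample_id: str = "sample") -> CascadeResult:
    """Map reads through the stage cascade.

    Stage i receives exactly the reads unmapped at stages < i; each read
    is mapped at most once overall.
    """
    align_params = align_params or AlignParams()
    pending = list(reads)
    stage_results: list[StageResult] = []
    for stage_label, reference in config.stages:
        index = build_index(reference, align_params.seed_k)
        alignments: list[AlignmentRecord] = []
        still_unmapped: list[Read] = []
        for read in pending:
            aln = align_read(read, index, reference, align_params)
            if aln is None:
                still_unmapped.append(read)
            else:
                alignments.append(aln)
        counts = tally_counts(alignments, reference, sample_id=sample_id,
                              stage_label=stage_label)
        stage_results.append(StageResult(stage_label, alignments, counts))
        pending = still_unmapped
    return CascadeResult(sample_id=sample_id, stages=stage_results,
                         unmapped=pending)


def tally_counts(alignments: Iterable[AlignmentRecord],
                 reference: ReferenceSet, sample_id: str = "sample",
                 stage_label: str = "stage") -> CountTable:
    """Tally one count per mapped read, keyed by transcript.

    Raises ValueError on a duplicate read id (each read may carry at
    most one alignment record per stage).
    """
    by_id = reference.by_id
    table = CountTable(sample_id=sample_id, stage_label=stage_label)
    seen_reads: set[str] = set()
    for aln in alignments:
        if aln.read_id in seen_reads:
            raise ValueError(
                f"read {aln.read_id!r} has multiple alignment records; "
                "one read, one count"
            )
        seen_reads.add(aln.read_id)
        t = by_id[aln.transcript_id]
        if aln.transcript_id in table.rows:
            acc, cls, count = table.rows[aln.transcript_id]
            table.rows[aln.transcript_id] = (acc, cls, count + 1)
        else:
            table.rows[aln.transcript_id] = (t.accession, t.rna_class, 1)
    return table


def normalize_percent(tables: Sequence[CountTable]) -> dict[str, float]:
    """Per-transcript percent of total mapped reads across all stages."""
    total = sum(table.total() for table in tables)
    if total <= 0:
        raise ValueError("cannot normalize: zero mapped reads")
    return {
        tid: 100.0 * count / total
        for table in tables
        for tid, (_, _, count) in table.rows.items()
    }


@dataclass
class CompositionProfile:
    """Percent of total mapped reads per RNA class for one sample."""

    sample_id: str
    percent_by_class: dict[str, float]


def composition_profile(tables: Sequence[CountTable],
                        sample_id: str = "sample") -> CompositionProfile:
    """Aggregate transcript counts by RNA class, as percent of mapped."""
    total = sum(table.total() for table in tables)
    if total <= 0:
        raise ValueError("cannot profile composition: zero mapped reads")
    by_class: dict[str, float] = {}
    for table in tables:
        for _, (_, cls, count) in table.rows.items():
            by_class[cls] = by_class.get(cls, 0.0) + count
    return CompositionProfile(
        sample_id=sample_id,
        percent_by_class={cls: 100.0 * c / total for cls, c in by_class.items()},
    )


def mean_counts(replicates: Sequence[CountTable],
                sample_id: str = "mean") -> CountTable:
    """Arithmetic mean of raw counts over replicate libraries.

    A transcript absent from a replicate contributes 0 to its mean.
    Means are rounded to 2 decimals.  Row order follows first
    appearance across replicates.
    """
    if not replicates:
        raise ValueError("mean_counts requires at least one replicate")
    n = len(replicates)
    out = CountTable(sample_id=sample_id, stage_label="mean")
    for table in replicates:
        for tid, (acc, cls, count) in table.rows.items():
            if tid in out.rows:
                a, c, total = out.rows[tid]
                out.rows[tid] = (a, c, total + count)
            else:
                out.rows[tid] = (acc, cls, count)
    for tid, (acc, cls, total) in out.rows.items():
        out.rows[tid] = (acc, cls, round(total / n, 2))
    return out


@dataclass
class RankedList:
    """Ordered top-N transcripts for one RNA class and sample type."""

    rna_class: str
    sample_type: str
    entries: list[tuple[str, Optional[str], float]]  # (id, accession, mean)
    short: bool = False  # fewer transcripts than requested

    def keys(self) -> list[str]:
        """Overlap keys: accession when present, else transcript id."""
        return [acc if acc else tid for tid, acc, _ in self.entries]


def top_n(table: CountTable, rna_class: str, n: int = 10,
          sample_type: str = "sample") -> RankedList:
    """The n highest-mean transcripts of a class, descending.

    Ties are broken by transcript_id lexicographic order.  If the class
    has fewer than n transcripts, all are returned and the list is
    flagged short.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows = [
        (tid, acc, count)
        for tid, (acc, cls, count) in table.rows.items()
        if cls == rna_class
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return RankedList(rna_class=rna_class, sample_type=sample_type,
                      entries=rows[:n], short=len(rows) < n)


def topn_overlap(list_a: RankedList, list_b: RankedList) -> int:
    """Number of shared entries between two ranked lists of one class.

    Entries are keyed by accession when present (so distinct transcript
    variants of one gene count separately), else by transcript id.
    """
    if list_a.rna_class != list_b.rna_class:
        raise ValueError(
            f"rank-overlap requires matching RNA classes, got "
            f"{list_a.rna_class!r} vs {list_b.rna_class!r}"
        )
    return len(set(list_a.keys()) & set(list_b.keys()))


def differential_table(group_a: Sequence[dict[str, float]],
                       group_b: Sequence[dict[str, float]],
                       label_a: str = "a", label_b: str = "b") -> pd.DataFrame:
    """Descriptive comparison of normalized percents between two groups.

    Each group is a list of per-replicate {transcript: percent} maps.
    Rows report mean and sample standard deviation (ddof=1; 0 when a
    group has one replicate) of the normalized percent per group, plus
    the ratio of group means (NaN when the denominator mean is 0).
    Transcripts absent from a replicate contribute 0.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one replicate")
    transcripts = sorted(
        {t for rep in group_a for t in rep} | {t for rep in group_b for t in rep}
    )
    rows = []
    for tid in transcripts:
        va = [rep.get(tid, 0.0) for rep in group_a]
        vb = [rep.get(tid, 0.0) for rep in group_b]
        mean_a, sd_a = _mean_sd(va)
        mean_b, sd_b = _mean_sd(vb)
        ratio = mean_a / mean_b if mean_b > 0 else math.nan
        rows.append({
            "transcript_id": tid,
            f"mean_percent_{label_a}": mean_a, f"sd_percent_{label_a}": sd_a,
            f"mean_percent_{label_b}": mean_b, f"sd_percent_{label_b}": sd_b,
            "ratio": ratio,
        })
    return pd.DataFrame(rows)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)
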