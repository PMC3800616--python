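"""Per-library quality summaries: per-cycle quality quartiles, base
composition, read-length histogram, and most-represented k-mers."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = ("A", "C", "G", "T", "N")


@dataclass
class QcReport:
    per_position_quality: list[tuple[float, float, float]] = field(default_factory=list)
    base_composition: list[dict[str, float]] = field(default_factory=list)
    length_histogram: dict[int, int] = field(default_factory=dict)
    top_kmers: list[tuple[str, int]] = field(default_factory=list)
    n_reads: int = 0
    k: int = 8


def qc_summary(reads: Iterable, k: int = 8, top: int = 20) -> QcReport:
    """Summarize a read stream.

    Quartiles (Q1/median/Q3) use linear interpolation; base-composition
    fractions at each cycle sum to 1 over cycles with at least one
    observation; k-mer counting slides over every read position
    (overlapping windows).  Empty input yields an empty report.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    quals_by_cycle: list[list[int]] = []
    bases_by_cycle: list[Counter] = []
    lengths: Counter = Counter()
    kmers: Counter = Counter()
    n_reads = 0
    for read in reads:
        n_reads += 1
        lengths[len(read.seq)] += 1
        for cycle, (base, q) in enumerate(zip(read.seq, read.qual)):
            if cycle >= len(quals_by_cycle):
                quals_by_cycle.append([])
                bases_by_cycle.append(Counter())
            quals_by_cycle[cycle].append(q)
            bases_by_cycle[cycle][base if base in BASES else "N"] += 1
        for i in range(len(read.seq) - k + 1):
            kmers[read.seq[i:i + k]] += 1
    report = QcReport(n_reads=n_reads, k=k, length_histogram=dict(sorted(lengths.items())))
    for cycle_quals in quals_by_cycle:
        q1, med, q3 = np.percentile(cycle_quals, [25, 50, 75])
        report.per_position_quality.append((float(q1), float(med), float(q3)))
    for counter in bases_by_cycle:
        total = sum(counter.values())
        report.base_composition.append(
            {b: counter.get(b, 0) / total for b in BASES}
        )
    # descending count; lexicographic k-mer order breaks ties
    report.top_kmers = sorted(kmers.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return report


def write_qc_report(report: QcReport, path: str | Path) -> None:
    """Write the report as a sectioned TSV."""
    with open(path, "w") as out:
        out.write(f"# reads\t{report.n_reads}\n")
        out.write("# section: per_position_quality\ncycle\tq1\tmedian\tq3\n")
        for i, (q1, med, q3) in enumerate(report.per_position_quality, start=1):
            out.write(f"{i}\t{q1:g}\t{med:g}\t{q3:g}\n")
        out.write("# section: base_composition\ncycle\t" + "\t".join(BASES) + "\n")
        for i, comp in enumerate(report.base_composition, start=1):
            out.write(f"{i}\t" + "\t".join(f"{comp[b]:.4f}" for b in BASES) + "\n")
        out.write("# section: length_histogram\nlength\tcount\n")
        for length, count in report.length_histogram.items():
            out.write(f"{length}\t{count}\n")
        out.write(f"# section: top_kmers (k={report.k})\nkmer\tcount\n")
        for kmer, count in report.top_kmers:
            out.write(f"{kmer}\t{count}\n")
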