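"""Deterministic synthetic data: class-labelled reference transcripts,
truth-labelled short reads with 3' adapter read-through and 3' quality
decay, and the packaged top-10 mean-count reference tables.

The generator emulates a directional small-RNA library: short inserts
(~15-40 nt) sampled from class-labelled transcripts, an optional 3'
adapter appended when the insert is shorter than the sequenced length
(read-through), per-base substitution errors, and PHRED qualities that
sit on a high plateau before declining linearly toward the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import CountTable, Read, ReferenceSet, Transcript, load_count_table

# Stage routing by RNA class: hairpin/tRNA/rRNA first, RefSeq-style
# mRNA+ncRNA second, remaining ncRNA ("other") last.
STAGE_CLASSES: dict[str, tuple[str, ...]] = {
    "stage1_mirna_trna_rrna": ("miRNA", "tRNA", "rRNA"),
    "stage2_refseq": ("mRNA", "ncRNA"),
    "stage3_noncode": ("other",),
}

# Fixed arbitrary 23-mer standing in for the platform's 3' adapter.
DEFAULT_ADAPTER = "ATCACCGACTGCCCATAGAGAGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class QualityModel:
    """High plateau, then linear per-cycle decay, floored at Q2."""

    plateau: int = 32
    decay_start: int = 30
    decay_slope: float = 0.5
    floor: int = 2

    def qualities(self, length: int, rng: np.random.Generator) -> tuple[int, ...]:
        cycles = np.arange(1, length + 1)
        q = np.full(length, float(self.plateau))
        late = cycles > self.decay_start
        q[late] -= self.decay_slope * (cycles[late] - self.decay_start)
        jitter = rng.integers(-1, 2, size=length)
        return tuple(int(x) for x in np.maximum(self.floor, np.floor(q) + jitter))


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    per_class_transcripts maps RNA class -> (number of transcripts,
    (min length, max length)); class_mixture gives read sampling
    probabilities per class and must sum to 1.
    """

    seed: int = 0
    per_class_transcripts: dict[str, tuple[int, tuple[int, int]]] = field(
        default_factory=lambda: {
            "miRNA": (20, (60, 90)),
            "tRNA": (10, (70, 90)),
            "rRNA": (3, (120, 160)),
            "mRNA": (15, (200, 400)),
            "ncRNA": (10, (100, 200)),
            "other": (10, (100, 200)),
        }
    )
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "miRNA": 0.20, "tRNA": 0.25, "rRNA": 0.20,
            "mRNA": 0.15, "ncRNA": 0.10, "other": 0.10,
        }
    )
    read_count: int = 2000
    insert_length: tuple[int, int] = (15, 40)
    adapter_seq: str = DEFAULT_ADAPTER
    adapter_fraction: float = 1.0
    error_rate: float = 0.0
    quality_model: QualityModel = field(default_factory=QualityModel)

    def __post_init__(self) -> None:
        if not self.per_class_transcripts:
            raise ValueError("per_class_transcripts must not be empty")
        if sum(n for n, _ in self.per_class_transcripts.values()) == 0:
            raise ValueError("need at least one transcript overall")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture must sum to 1, got {total}")
        if not 0 <= self.adapter_fraction <= 1:
            raise ValueError("adapter_fraction must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    transcript_id: str
    rna_class: str
    stage_label: str
    insert_length: int
    had_adapter: bool
    n_errors: int


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def stage_for_class(rna_class: str) -> str:
    for stage, classes in STAGE_CLASSES.items():
        if rna_class in classes:
            return stage
    raise ValueError(f"unknown RNA class {rna_class!r}")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_reference(config: SimConfig) -> dict[str, ReferenceSet]:
    """Generate one ReferenceSet per cascade stage, keyed by stage label.

    Transcripts have uniform base composition.  Stages are not forced to
    be seed-disjoint; use :func:`stages_share_seeds` to check.
    """
    rng = np.random.default_rng(config.seed)
    by_stage: dict[str, list[Transcript]] = {s: [] for s in STAGE_CLASSES}
    acc_counter = {"mRNA": 0, "ncRNA": 0}
    for rna_class in sorted(config.per_class_transcripts):
        count, (lo, hi) = config.per_class_transcripts[rna_class]
        stage = stage_for_class(rna_class)
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            accession: Optional[str] = None
            if rna_class in acc_counter:
                acc_counter[rna_class] += 1
                prefix = "NM" if rna_class == "mRNA" else "NR"
                accession = f"{prefix}_{900000 + acc_counter[rna_class]:06d}"
            by_stage[stage].append(Transcript(
                transcript_id=f"{rna_class}_t{i + 1}",
                seq=_random_seq(length, rng),
                rna_class=rna_class,
                accession=accession,
            ))
    return {
        stage: ReferenceSet(stage_label=stage, transcripts=ts)
        for stage, ts in by_stage.items()
        if ts
    }


def generate_reads(config: SimConfig, references: dict[str, ReferenceSet]
                   ) -> tuple[list[Read], TruthTable]:
    """Generate truth-labelled reads from the reference sets.

    Uses a generator seeded with ``config.seed + 1`` so reads are
    reproducible independently of reference generation.
    """
    if not references:
        raise ValueError("references must not be empty")
    rng = np.random.default_rng(config.seed + 1)
    by_class: dict[str, list[tuple[str, Transcript]]] = {}
    for stage, ref in references.items():
        for t in ref:
            by_class.setdefault(t.rna_class, []).append((stage, t))
    classes = [c for c in sorted(config.class_mixture) if config.class_mixture[c] > 0]
    missing = [c for c in classes if c not in by_class]
    if missing:
        raise ValueError(f"mixture classes with no transcripts: {missing}")
    probs = np.array([config.class_mixture[c] for c in classes])
    probs = probs / probs.sum()
    lo, hi = config.insert_length
    reads: list[Read] = []
    truth = TruthTable()
    for i in range(config.read_count):
        cls = classes[rng.choice(len(classes), p=probs)]
        stage, t = by_class[cls][rng.integers(len(by_class[cls]))]
        ins_len = int(rng.integers(lo, min(hi, len(t.seq)) + 1))
        start = int(rng.integers(0, len(t.seq) - ins_len + 1))
        insert = t.seq[start:start + ins_len]
        had_adapter = bool(rng.random() < config.adapter_fraction)
        seq = insert + (config.adapter_seq if had_adapter else "")
        n_errors = 0
        if config.error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < config.error_rate
            for pos in np.nonzero(hit)[0]:
                choices = _BASES[_BASES != arr[pos]]
                arr[pos] = choices[rng.integers(len(choices))]
            n_errors = int(hit.sum())
            seq = arr.tobytes().decode("ascii")
        read_id = f"sim_{i:06d}"
        reads.append(Read(
            read_id=read_id, seq=seq,
            qual=config.quality_model.qualities(len(seq), rng),
        ))
        truth.rows.append(TruthRow(
            read_id=read_id, transcript_id=t.transcript_id, rna_class=cls,
            stage_label=stage, insert_length=ins_len,
            had_adapter=had_adapter, n_errors=n_errors,
        ))
    return reads, truth


def stages_share_seeds(references: dict[str, ReferenceSet], seed_k: int = 10) -> bool:
    """True if any exact seed_k-mer occurs in more than one stage
    (cross-stage mis-routing is then possible)."""
    seen: dict[str, str] = {}
    for stage, ref in references.items():
        stage_kmers = {
            t.seq[i:i + seed_k]
            for t in ref
            for i in range(len(t.seq) - seed_k + 1)
        }
        for kmer in stage_kmers:
            if kmer in seen and seen[kmer] != stage:
                return True
            seen[kmer] = stage
    return False


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

FIXTURE_CLASSES = ("mirna", "trna", "mrna", "ncrna")
FIXTURE_SAMPLES = (
    ("hela", "cells"), ("hela", "exosomes"),
    ("serum", "parental"), ("serum", "exosomes"),
)


def fixture_path(source: str, sample_type: str, rna_class: str) -> Path:
    """Path to a bundled top-10 mean-count table.

    source: "hela" or "serum"; sample_type: "cells"/"parental"/
    "exosomes"; rna_class: "mirna", "trna", "mrna", or "ncrna".
    """
    name = f"{source}_{sample_type}_{rna_class.lower()}.tsv"
    with resources.as_file(resources.files("exoseq.data") / name) as p:
        if not p.exists():
            raise FileNotFoundError(name)
        return p


def packaged_fixtures() -> dict[tuple[str, str, str], CountTable]:
    """Load all bundled top-10 mean-count tables.

    These are curated mean raw-count rankings observed in HeLa
    cell/exosome libraries (means over 3 replicate libraries) and human
    serum/serum-exosome libraries (means over 2 donors), keyed by
    (source, sample_type, rna_class).
    """
    out: dict[tuple[str, str, str], CountTable] = {}
    for source, sample_type in FIXTURE_SAMPLES:
        for cls in FIXTURE_CLASSES:
            path = fixture_path(source, sample_type, cls)
            out[(source, sample_type, cls)] = load_count_table(
                path, sample_id=f"{source}_{sample_type}", stage_label="mean")
    return out
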