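# Methods

`exoseq` quantifies the RNA cargo of small-RNA sequencing libraries — in
particular libraries prepared from exosomes and their parental samples
(cultured cells, whole serum) — by cleaning reads, mapping them through an
ordered cascade of class-annotated references, and reporting per-transcript
counts, percent-of-mapped abundances, top-N rankings and their overlaps, and
RNA-class composition.

## Read model and preprocessing

A read is a nucleotide string over {A,C,G,T,N} with per-base PHRED scores
(decoded at offset +33, the Sanger/Ion convention; the offset is a flag for
other encodings) and a provenance trail of trimming steps, from which the
original length is always recoverable.

Cleanup applies, in fixed order: 3' quality trimming, a length floor, 3'
adapter trimming, and the length floor again.

- **Quality trimming** removes the trailing run of bases with quality below
  `quality_threshold` (default Q17, ≈2% per-base error), stopping at the
  first 3' base at or above the threshold. Interior low-quality bases are
  kept; only the 3' tail is removed.
- **Length floor** (`min_length`, default 17 nt): reads shorter than this
  after either step are dropped, because very short reads map ambiguously.
  The floor is enforced whether or not trimming fired, so undersized input
  reads are also removed. Drops are tallied by reason (quality vs adapter).
- **Adapter trimming** scans every candidate start position and compares a
  prefix of the 3' adapter against the read from that position under
  unit-cost edit distance (edlib computes the distances). A match is
  accepted when edits ≤ floor(`max_error_rate` × matched adapter length)
  (default rate 0.1) and the matched length ≥ `min_overlap` (default 3).
  The best match maximizes the number of matching bases (matched length
  minus edits); ties go to the longest match, then the leftmost start.
  Everything from the match start to the read end is removed. N matches
  nothing. The adapter sequence is a required user input.

A note on idempotence: like any greedy 3' trimmer, a second pass can trim
further when a read's genuine 3' end happens to equal a short adapter
prefix (≥ `min_overlap` bases). The property suite asserts idempotence on
reads whose cleaned ends do not mimic the adapter; the exceptional case is
inherent to the matching rule, not an implementation accident.

The maximize-matches criterion matters: ranking candidate matches by length
alone would let a one-base-shifted match (paid for out of the edit budget)
tie the exact planted match and win on leftmost-start, systematically
clipping 1–2 insert bases. With maximize-matches, error-free read-through
reads are restored to their exact insert.

## QC summaries

Per-library summaries cover per-cycle quality quartiles (Q1/median/Q3,
linear interpolation), per-cycle base composition (fractions sum to 1 at
every observed cycle), the read-length histogram (counts sum to the number
of reads), and the most-represented k-mers over all overlapping windows
(default k = 8; descending count, lexicographic tie-break). No automated
pass/fail is attached; the report is for inspection.

## Seeded local alignment

Each read is aligned only against transcripts that share at least one exact
`seed_k`-mer with it (default k = 10; transcripts shorter than k are always
candidates). Candidates are scored by full Smith–Waterman local dynamic
programming with match +2, mismatch −2, and a linear gap penalty of −4 per
gap base — short reads (≤ ~40 nt) rarely need affine gap structure, and the
linear model keeps the exhaustive-DP oracle in the test suite simple. The
matrix fill is numba-compiled; traceback prefers diagonal moves and the
first maximum in row-major order, so results are deterministic.

A read is called mapped when its best score reaches `min_score_fraction`
(default 0.8) of its maximum attainable score (match × read length). Ties
between candidates break by fewer edits, then reference order. One read
yields at most one alignment record ("one read, one count"), so count-table
sums always equal mapped-read totals. Strand handling defaults to
forward-only, matching directional ligation protocols; `--both-strands`
reverse-complements the read for the minus strand.

Known sensitivity limit: a read whose errors disrupt every `seed_k`-mer it
shares with its source is reported unmapped even though exhaustive DP might
clear the threshold. With substitution rates around 1% and 18–40-nt reads
this is rare; the oracle-equivalence test quantifies the seeded/exhaustive
agreement whenever a seed is shared.

## Cascade quantification

`run_cascade` maps reads through ordered stages; stage *i* receives exactly
the reads unmapped at stages < *i*. The default stage design is: (1) miRNA
hairpins + tRNA + rRNA, (2) RefSeq-style transcripts (mRNA with NM_
accessions, ncRNA with NR_), (3) other/annotation-gap ncRNA. The per-stage
mapped read-ID sets and the final unmapped set partition the input exactly
— the invariant every downstream report relies on.

Downstream operations:

- **Counting**: one count per mapped read, per transcript; duplicate read
  IDs in a stage are an error.
- **Normalization**: a transcript's percent is 100 × count / total mapped
  across *all* stages of the sample; percentages sum to 100 (±1e-9).
- **Composition**: class-level aggregation of the same normalization.
- **Mean counts**: arithmetic mean of raw counts over replicate libraries
  (absent transcript = 0), reported to 2 decimals — matching the convention
  of published mean-count tables.
- **Top-N ranking**: the N highest-mean transcripts of one class,
  descending, ties broken lexicographically; short lists are flagged.
- **Rank overlap**: intersection size of two same-class top-N lists, keyed
  by accession when present, else transcript ID. Accession keying is what
  lets distinct transcript variants of one gene (e.g. several SIRPG
  accessions) count separately.
- **Differential table**: descriptive mean ± sample SD (ddof = 1; SD 0 for
  n = 1) of normalized percents per group and the ratio of group means. No
  statistical test is attached; with 2–3 replicates per group the report is
  intentionally descriptive.

## Bundled reference tables

The package ships 16 small TSV tables: top-10 mean raw counts per RNA class
(miRNA, tRNA, mRNA, ncRNA) for HeLa cells and HeLa-exosome libraries (means
over 3 replicate libraries) and for human serum and serum-exosome libraries
(means over 2 donors). They are transcribed as printed, including gene-name
idiosyncrasies and the original (not always sorted) row order; `top_n`
re-ranks on load, so overlaps are unaffected. Duplicate gene symbols with
distinct accessions carry a numeric ID suffix to keep transcript IDs unique;
overlaps for mRNA/ncRNA are accession-keyed and unaffected.

## Synthetic data generator

The generator emulates the preprocessed-data regime of a directional
exosome small-RNA library; its defaults are the package's fixed study
conditions:

- **References**: random uniform-composition transcripts per class — 20
  miRNA hairpins (60–90 nt), 10 tRNA (70–90), 3 rRNA (120–160), 15 mRNA
  (200–400), 10 RefSeq-style ncRNA and 10 other ncRNA (100–200) — routed to
  cascade stages by class. Stages are not forced seed-disjoint; the
  `stages_share_seeds` check reports whether cross-stage k-mer sharing is
  possible, and the truth comparison measures (rather than prevents) any
  cross-mapping.
- **Reads**: class sampled from a mixture (defaults 0.20 miRNA / 0.25 tRNA
  / 0.20 rRNA / 0.15 mRNA / 0.10 ncRNA / 0.10 other — rRNA-rich with
  substantial tRNA and miRNA, as exosome libraries are), transcript uniform
  within class, insert substring uniform with length 15–40 nt. A fraction
  of reads (default 1.0) carries 3' adapter read-through: the full fixed
  23-mer adapter is appended. Substitution errors at `error_rate` (default
  0; an option for aligner stress tests). Every read gets a truth row
  (source transcript, class, stage, insert length, adapter flag, error
  count); generation is fully deterministic under the seed.
- **Qualities**: plateau Q32 for the first 30 cycles, then linear decay of
  0.5/cycle with ±1 jitter, floored at Q2 — a minimal stand-in for the 3'
  quality decline of semiconductor sequencing. Under these defaults insert
  bases stay above the Q17 trim threshold (decay only reaches Q17 around
  cycle 58, beyond any insert), so quality trimming eats at most a few
  trailing adapter bases and the planted insert remains exactly
  recoverable.

What the generator does not emulate: real sequence motifs or secondary
structure, indel sequencing errors (available via a flag but off by
default), PCR duplication, ligation bias, or donor-to-donor variability.
Passing tests on synthetic data therefore demonstrate the pipeline's
bookkeeping and alignment correctness under controlled conditions, not
biological fidelity of any particular abundance profile.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end pipeline at
10,000 reads against the default reference set (~68 transcripts), a scale
at which every invariant (partition, normalization mass, truth recovery)
is measured exactly in seconds. Quartiles interpolate linearly; mean counts
round half-even to 2 decimals via Python's `round`; all randomness flows
from a single integer seed (reference generation uses `seed`, read
generation `seed + 1`).

## Limitations

- The aligner indexes transcript sets, not genomes; it is not meant for
  spliced or genome-scale alignment.
- Quality-aware alignment scoring is not implemented; qualities influence
  trimming only.
- Multi-mapping reads are assigned to the single best transcript; ties are
  resolved deterministically rather than fractionally distributed.
- The rank-overlap statistic is a set intersection; it carries no
  significance measure.
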