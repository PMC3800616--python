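"""Independent brute-force oracles used by the test suite.

Deliberately simple and separate from the package implementation: a
triple-loop Smith-Waterman score, a sliding-window k-mer counter, and
helpers for constructing reads by hand.
"""

from exoseq.io_formats import Read


def sw_score(a: str, b: str, match: int = 2, mismatch: int = -2,
             gap: int = -4) -> int:
    """Exhaustive local-alignment score (no seeding, score only)."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                diag = prev[j - 1] + match
            else:
                diag = prev[j - 1] + mismatch
            cur[j] = max(0, diag, prev[j] + gap, cur[j - 1] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def count_kmers(seqs, k: int) -> dict:
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def make_read(seq: str, qual=None, read_id: str = "r1") -> Read:
    if qual is None:
        qual = (30,) * len(seq)
    elif isinstance(qual, int):
        qual = (qual,) * len(seq)
    return Read(read_id=read_id, seq=seq, qual=tuple(qual))
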