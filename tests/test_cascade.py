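import math

import numpy as np
import pytest

from exoseq.aligner import AlignParams, AlignmentRecord
from exoseq.cascade import (CascadeConfig, CascadeConfigError,
                            composition_profile, differential_table,
                            mean_counts, normalize_percent, run_cascade,
                            tally_counts, top_n, topn_overlap)
from exoseq.io_formats import CountTable, ReferenceSet, Transcript
from exoseq.synth import packaged_fixtures

from _oracles import make_read


def _table(sample, rows):
    return CountTable(sample, "stage", dict(rows))


def _aln(read_id, tid):
    return AlignmentRecord(read_id, tid, 0, "20M", 40, read_end=20)


REF = ReferenceSet("s", [Transcript("T1", "A" * 30, "miRNA"),
                         Transcript("T2", "C" * 30, "tRNA")])


class TestTallyCounts:
    def test_counts_per_transcript(self):
        table = tally_counts([_aln("r1", "T1"), _aln("r2", "T1"),
                              _aln("r3", "T1"), _aln("r4", "T2")], REF)
        assert table.rows["T1"][2] == 3 and table.rows["T2"][2] == 1
        assert table.total() == 4

    def test_empty(self):
        assert tally_counts([], REF).rows == {}

    def test_duplicate_read_is_error(self):
        with pytest.raises(ValueError, match="one read, one count"):
            tally_counts([_aln("r1", "T1"), _aln("r1", "T2")], REF)

    def test_uniform_reads(self):
        ref = ReferenceSet("s", [Transcript(f"T{i}", "ACGT" * 8, "miRNA")
                                 for i in range(10)])
        alns = [_aln(f"r{i}", f"T{i}") for i in range(10)]
        table = tally_counts(alns, ref)
        assert all(row[2] == 1 for row in table.rows.values())


class TestNormalizePercent:
    def test_simple_split(self):
        percents = normalize_percent([_table("s", {"A": (None, "miRNA", 3),
                                                   "B": (None, "miRNA", 1)})])
        assert percents == {"A": 75.0, "B": 25.0}

    def test_single_transcript(self):
        assert normalize_percent([_table("s", {"A": (None, "miRNA", 5)})]) == \
            {"A": 100.0}

    def test_cross_stage_total(self):
        t1 = _table("s", {"A": (None, "miRNA", 2)})
        t2 = _table("s", {"B": (None, "mRNA", 2)})
        assert normalize_percent([t1, t2]) == {"A": 50.0, "B": 50.0}

    def test_zero_mapped_is_error(self):
        with pytest.raises(ValueError, match="zero mapped"):
            normalize_percent([_table("s", {})])

    def test_sums_to_100(self):
        rng = np.random.default_rng(0)
        tables = [
            _table("s", {f"T{s}_{i}": (None, "miRNA", int(rng.integers(1, 50)))
                         for i in range(20)})
            for s in range(3)
        ]
        assert math.isclose(sum(normalize_percent(tables).values()), 100.0,
                            abs_tol=1e-9)


class TestComposition:
    def test_all_one_class(self):
        profile = composition_profile([_table("s", {"A": (None, "miRNA", 7)})])
        assert profile.percent_by_class == {"miRNA": 100.0}

    def test_two_classes(self):
        profile = composition_profile([_table("s", {
            "A": (None, "rRNA", 40), "B": (None, "other", 60)})])
        assert profile.percent_by_class == {"rRNA": 40.0, "other": 60.0}


class TestMeanCounts:
    def test_simple_mean(self):
        reps = [_table(f"s{i}", {"A": (None, "miRNA", c)})
                for i, c in enumerate((1, 2, 3))]
        assert mean_counts(reps).rows["A"][2] == 2.00

    def test_absent_contributes_zero(self):
        reps = [_table("s1", {"A": (None, "miRNA", 4)}), _table("s2", {})]
        assert mean_counts(reps).rows["A"][2] == 2.00

    def test_thirds_rounding(self):
        """Means over 3 replicates are reported to 2 decimals."""
        reps = [_table(f"s{i}", {"A": (None, "miRNA", c)})
                for i, c in enumerate((2015, 2015, 2016))]
        assert mean_counts(reps).rows["A"][2] == 2015.33

    def test_zero_replicates_error(self):
        with pytest.raises(ValueError):
            mean_counts([])


class TestTopN:
    def test_fixture_ranking(self):
        tables = packaged_fixtures()
        ranked = top_n(tables[("hela", "exosomes", "mirna")], "miRNA")
        assert ranked.entries[0][0] == "hsa-mir-21"
        assert ranked.entries[1][0] == "hsa-mir-3160-1"
        means = [e[2] for e in ranked.entries]
        assert means == sorted(means, reverse=True)

    def test_short_list_flagged(self):
        table = _table("s", {f"T{i}": (None, "miRNA", i + 1) for i in range(3)})
        ranked = top_n(table, "miRNA", n=10)
        assert len(ranked.entries) == 3 and ranked.short

    def test_tie_lexicographic(self):
        table = _table("s", {"B": (None, "miRNA", 5), "A": (None, "miRNA", 5)})
        ranked = top_n(table, "miRNA", n=2)
        assert [e[0] for e in ranked.entries] == ["A", "B"]

    def test_class_filtering(self):
        table = _table("s", {"A": (None, "miRNA", 5), "B": (None, "tRNA", 9)})
        assert [e[0] for e in top_n(table, "tRNA", n=5).entries] == ["B"]


class TestTopnOverlap:
    @pytest.mark.parametrize("source,parental,cls,expected", [
        ("hela", "cells", "mirna", 4),
        ("hela", "cells", "trna", 7),
        ("hela", "cells", "mrna", 2),
        ("hela", "cells", "ncrna", 2),
        ("serum", "parental", "mirna", 6),
        ("serum", "parental", "trna", 7),
        ("serum", "parental", "mrna", 7),
        ("serum", "parental", "ncrna", 4),
    ])
    def test_fixture_overlaps(self, source, parental, cls, expected):
        """Top-10 overlap between exosomes and their parental sample."""
        tables = packaged_fixtures()
        rna_class = {"mirna": "miRNA", "trna": "tRNA",
                     "mrna": "mRNA", "ncrna": "ncRNA"}[cls]
        a = top_n(tables[(source, parental, cls)], rna_class)
        b = top_n(tables[(source, "exosomes", cls)], rna_class)
        assert topn_overlap(a, b) == expected
        assert topn_overlap(b, a) == expected  # symmetric

    def test_identical_and_disjoint(self):
        t = _table("s", {f"T{i}": (None, "miRNA", 10 - i) for i in range(10)})
        u = _table("s", {f"U{i}": (None, "miRNA", 10 - i) for i in range(10)})
        a = top_n(t, "miRNA")
        assert topn_overlap(a, top_n(t, "miRNA")) == 10
        assert topn_overlap(a, top_n(u, "miRNA")) == 0

    def test_class_mismatch_error(self):
        t = _table("s", {"A": (None, "miRNA", 1), "B": (None, "tRNA", 1)})
        with pytest.raises(ValueError, match="class"):
            topn_overlap(top_n(t, "miRNA"), top_n(t, "tRNA"))

    def test_accession_keyed(self):
        """Distinct accessions of one gene symbol count separately."""
        a = _table("s", {"G.1": ("NM_1", "mRNA", 5), "G.2": ("NM_2", "mRNA", 4)})
        b = _table("s", {"G.x": ("NM_1", "mRNA", 9), "G.y": ("NM_3", "mRNA", 1)})
        assert topn_overlap(top_n(a, "mRNA"), top_n(b, "mRNA")) == 1


class TestDifferentialTable:
    def test_identical_replicates_sd_zero(self):
        reps = [{"A": 60.0, "B": 40.0}] * 3
        df = differential_table(reps, reps, "x", "y")
        assert (df["sd_percent_x"] == 0).all()
        assert (df["mean_percent_x"] == df["mean_percent_y"]).all()

    def test_absent_in_group_b_means_zero(self):
        df = differential_table([{"A": 100.0}], [{"B": 100.0}], "a", "b")
        row = df.set_index("transcript_id").loc["A"]
        assert row["mean_percent_b"] == 0.0 and math.isnan(row["ratio"])

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(1)
        group_a = [{"A": 40.0 + rng.normal(0, 1), "B": 60.0}
                   for _ in range(3)]
        group_b = [{"A": 10.0 + rng.normal(0, 1), "B": 90.0}
                   for _ in range(3)]
        df = differential_table(group_a, group_b, "exo", "cell")
        row = df.set_index("transcript_id").loc["A"]
        assert row["ratio"] == pytest.approx(4.0, rel=0.25)
        assert row["sd_percent_exo"] > 0


class TestRunCascade:
    def test_config_validation(self):
        with pytest.raises(CascadeConfigError):
            CascadeConfig(stages=[])
        with pytest.raises(CascadeConfigError):
            CascadeConfig(stages=[("a", REF), ("a", REF)])
        with pytest.raises(CascadeConfigError):
            CascadeConfig(stages=[("a", ReferenceSet("a", []))])

    def test_empty_read_set(self):
        result = run_cascade([], CascadeConfig(stages=[("s1", REF)]))
        assert result.mapped_total() == 0 and result.unmapped == []

    def test_stage1_reads_never_reach_stage2(self):
        rng = np.random.default_rng(2)
        mk = lambda cls: "".join(rng.choice(list("ACGT"), 60))
        ref1 = ReferenceSet("s1", [Transcript("A1", mk("miRNA"), "miRNA")])
        ref2 = ReferenceSet("s2", [Transcript("B1", mk("mRNA"), "mRNA")])
        reads = [make_read(ref1.transcripts[0].seq[5:30], read_id=f"r{i}")
                 for i in range(10)]
        result = run_cascade(reads, CascadeConfig(stages=[("s1", ref1),
                                                          ("s2", ref2)]))
        assert len(result.stages[0].alignments) == 10
        assert len(result.stages[1].alignments) == 0
        assert result.unmapped == []

    def test_partition_and_routing(self, sim_small):
        """Per-stage mapped sets plus unmapped exactly partition input."""
        config, references, reads, truth = sim_small
        from exoseq.preprocess import PreprocessParams, preprocess_stream
        kept, _ = preprocess_stream(
            reads, PreprocessParams(adapter_seq=config.adapter_seq))
        result = run_cascade(kept, CascadeConfig(stages=list(references.items())))
        id_sets = [{a.read_id for a in s.alignments} for s in result.stages]
        id_sets.append({r.read_id for r in result.unmapped})
        union = set().union(*id_sets)
        assert union == {r.read_id for r in kept}
        assert sum(len(s) for s in id_sets) == len(kept)  # pairwise disjoint
        for stage in result.stages:
            assert stage.counts.total() == len(stage.alignments)
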