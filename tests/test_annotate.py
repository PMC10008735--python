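"""Annotation engine: collapsing, priority, tie-splitting, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from serumrna.annotate import (
    CountMatrix,
    KmerIndex,
    LibraryAnnotation,
    ReadRecord,
    annotate_library,
    assign_category,
    collapse_reads,
    compute_class_proportions,
    length_distribution,
    rpm_normalize,
)
from serumrna.reference import DEFAULT_PRIORITY, ParentRNA, ReferenceSet


class TestCollapse:
    def test_counts_multiplicities(self):
        reads = ["ACGTACGTACGTACGTACGT"] * 3 + ["TTGCATGCATGCATGCA"]
        recs = collapse_reads(reads)
        assert sorted(r.count for r in recs) == [1, 3]

    def test_empty_input(self):
        assert collapse_reads([]) == []

    def test_tally_conserves_total(self):
        rng = np.random.default_rng(0)
        pool = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(50)]
        reads = [pool[i] for i in rng.integers(0, 50, size=10_000)]
        recs = collapse_reads(reads)
        assert len(recs) == 50
        assert sum(r.count for r in recs) == 10_000

    def test_length_filter_and_non_acgt_dropped(self):
        recs = collapse_reads(["ACGT" * 3,            # 12 nt: too short
                               "A" * 50,              # too long
                               "ACGTNACGTACGTACGT",   # ambiguous base
                               "ACGTACGTACGTACGTA"])
        assert len(recs) == 1 and recs[0].count == 1


def _toy_reference():
    """A miRNA deliberately embedded inside an rRNA-like parent."""
    mirna = "ACGTGCATTGACCGTAGCATCA"  # 22 nt
    rng = np.random.default_rng(1)
    flank = "".join(rng.choice(list("ACGT"), 60))
    rrna = flank[:30] + mirna + flank[30:]
    trna_core = "TGCACCGGTTAACCGGTCAT"  # shared 5' arm of two tRNAs
    t1 = trna_core + "GATCGGATTTACGATCCGGATCCGGAATTGGCCAATTGGCCAAGGTTCCAAGG"
    t2 = trna_core + "CATGCCTAAGGCCTTAATCCGGATAAGGCCTTAAGGCCTTAACCGGTTAACCG"
    parents = {
        "mir-x": ParentRNA("mir-x", "miRNA", "mir-x", mirna),
        "rRNA-y": ParentRNA("rRNA-y", "rRNA", "y", rrna),
        "tRNA-A": ParentRNA("tRNA-A", "tRNA", "Xaa-AAA", t1),
        "tRNA-B": ParentRNA("tRNA-B", "tRNA", "Xaa-BBB", t2),
    }
    return ReferenceSet(parents=parents)


class TestPriorityAndTies:
    def test_mirna_wins_over_embedding_rrna(self):
        toy = _toy_reference()
        index = KmerIndex(toy)
        read = ReadRecord("r1", toy["mir-x"].sequence, 1)
        rec = assign_category(read, index, DEFAULT_PRIORITY)
        assert rec.category == "miRNA"
        # reversing the priority hands the same read to the rRNA class
        rec2 = assign_category(read, index, ("rRNA", "miRNA", "YRNA", "tRNA",
                                             "mt_tRNA", "piRNA", "other_ncRNA",
                                             "spike_in"))
        assert rec2.category == "rsRNA"

    def test_tie_between_trnas_splits_count_equally(self):
        toy = _toy_reference()
        index = KmerIndex(toy)
        read = ReadRecord("r1", toy["tRNA-A"].sequence[:20], 4)
        rec = assign_category(read, index, DEFAULT_PRIORITY)
        assert rec.category == "tsRNA"
        assert {p for p, _, _ in rec.hits} == {"tRNA-A", "tRNA-B"}
        assert rec.weight == 0.5
        assert rec.hit_weights == (2.0, 2.0)

    def test_no_hit_is_unannotated(self):
        toy = _toy_reference()
        index = KmerIndex(toy)
        read = ReadRecord("r1", "A" * 30, 1)
        assert assign_category(read, index, DEFAULT_PRIORITY) is None

    def test_one_mismatch_mode_recovers_mutated_read(self):
        toy = _toy_reference()
        index = KmerIndex(toy)
        seq = toy["rRNA-y"].sequence[10:50]
        mutated = seq[:5] + ("A" if seq[5] != "A" else "C") + seq[6:]
        assert assign_category(ReadRecord("r", mutated, 1), index,
                               DEFAULT_PRIORITY, max_mismatch=0) is None
        rec = assign_category(ReadRecord("r", mutated, 1), index,
                              DEFAULT_PRIORITY, max_mismatch=1)
        assert rec is not None and rec.mismatches == 1


class TestTruthRecovery:
    def test_category_totals_match_generator_truth(self, truth20k, library20k):
        truth_tallies = truth20k["category"].value_counts()
        recovered = library20k.category_counts()
        for cat, n in truth_tallies.items():
            assert recovered[cat] == pytest.approx(n, abs=1e-9)
        assert library20k.unannotated == 0

    def test_non_positional_features_match_exactly(self, truth20k, library20k):
        """miRNA/tsRNA/ysRNA/piRNA feature counts equal the truth tallies
        (rsRNA background reads may legitimately fall into peak bins)."""
        truth_tallies = truth20k["feature_id"].value_counts()
        for fid, n in truth_tallies.items():
            if fid.startswith("rsRNA-18S") or fid.startswith("rsRNA-28S"):
                continue
            assert library20k.feature_counts[fid] == pytest.approx(n, abs=1e-9)

    def test_conservation(self, truth20k, library20k):
        total = library20k.feature_counts.sum() + library20k.unannotated
        assert total == pytest.approx(len(truth20k), abs=1e-6)

    def test_reference_order_does_not_change_assignments(self, ref, truth20k):
        reordered = ReferenceSet(
            parents=dict(reversed(list(ref.parents.items()))),
            nested=ref.nested)
        reads = collapse_reads(truth20k["sequence"].iloc[:2000])
        a = annotate_library(reads, ref)
        b = annotate_library(reads, reordered)
        pd.testing.assert_series_equal(a.feature_counts, b.feature_counts)

    def test_annotation_agrees_with_brute_force(self, ref, kindex, truth20k):
        """Oracle: exhaustive substring scan over every (CCA-appended) parent."""
        rng = np.random.default_rng(2)
        reads = list(truth20k["sequence"].iloc[:200])
        reads += ["".join(rng.choice(list("ACGT"), 25)) for _ in range(100)]
        seqs = kindex.seqs
        for seq in reads:
            hits = {pid for pid, s in seqs.items() if seq in s}
            rec = assign_category(ReadRecord("r", seq, 1), kindex,
                                  DEFAULT_PRIORITY)
            if not hits:
                assert rec is None
                continue
            best = next(c for c in DEFAULT_PRIORITY
                        if any(ref[p].category == c for p in hits))
            cat_hits = {p for p in hits if ref[p].category == best}
            got = {p for p, _, _ in rec.hits}
            if best == "rRNA":
                assert got <= cat_hits
            else:
                assert got == cat_hits
            for pid, s, e in rec.hits:
                assert seqs[pid][s - 1 : e] == seq


class TestSummaries:
    def test_worked_class_proportions(self):
        counts = {"rsRNA-x": 6286.0, "ysRNA-x": 1497.0, "tsRNA-x": 422.0,
                  "mir-x": 309.0, "other-x": 1486.0}
        cats = {"rsRNA-x": "rsRNA", "ysRNA-x": "ysRNA", "tsRNA-x": "tsRNA",
                "mir-x": "miRNA", "other-x": "other_ncRNA"}
        lib = LibraryAnnotation(records=[], unannotated=0,
                                feature_counts=pd.Series(counts),
                                feature_categories=pd.Series(cats))
        props = compute_class_proportions(lib)
        assert props["rsRNA"] == pytest.approx(0.6286)
        assert props["ysRNA"] == pytest.approx(0.1497)
        assert props["tsRNA"] == pytest.approx(0.0422)
        assert props["miRNA"] == pytest.approx(0.0309)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_proportions_error_when_nothing_annotated(self):
        lib = LibraryAnnotation([], 10, pd.Series(dtype=float),
                                pd.Series(dtype=object))
        with pytest.raises(ValueError):
            compute_class_proportions(lib)

    @pytest.mark.parametrize("count,total,expected",
                             [(10, 1_000_000, 10.0), (0, 5, 0.0),
                              (37, 250_000, 148.0)])
    def test_rpm_values(self, count, total, expected):
        assert rpm_normalize([count], total)[0] == pytest.approx(expected)

    def test_rpm_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            rpm_normalize([1], 0)

    def test_rpm_sums_to_one_million(self, library20k):
        mat = CountMatrix.from_libraries(
            {"s1": library20k},
            pd.DataFrame({"group": ["control"]}, index=["s1"]))
        assert mat.rpm()["s1"].sum() == pytest.approx(1e6, abs=0.5)

    def test_length_distribution_shapes(self, library20k):
        hist = length_distribution(library20k.records, "ysRNA",
                                   library20k.mapped_total)
        assert hist.shape == (31,)
        assert 15 + int(np.argmax(hist)) == 30  # ysRNAs peak at ~30 nt
        empty = length_distribution([], "miRNA", 1000)
        assert (empty == 0).all()
        with pytest.raises(ValueError):
            length_distribution([], "nonsense", 1000)

    def test_single_length_occupies_one_bin(self, kindex, ref):
        seq = ref["RNY4"].sequence[:30]
        rec = assign_category(ReadRecord("r", seq, 7), kindex, DEFAULT_PRIORITY)
        hist = length_distribution([rec], "ysRNA", 7)
        assert hist[30 - 15] == pytest.approx(1e6)
        assert hist.sum() == pytest.approx(1e6)
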