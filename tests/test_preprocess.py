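from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovamir import preprocess
from ovamir.io import FastqRead, write_fastq
from ovamir.preprocess import (
    FilterReport,
    REMOVAL_CATEGORIES,
    clean_reads,
    collapse_tags,
    classify_insert,
    filter_inserts,
    find_adapter3,
    has_adapter5_prefix,
    length_distribution,
    mean_quality,
)

A3 = "TGGAATTCTCGGGTGCCAAGG"
A5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def _read(seq: str, qual_char: str = "I", name: str = "r") -> FastqRead:
    return FastqRead(name, seq, qual_char * len(seq))


class TestFilterReport:
    def test_table_accounting_multiple_library(self):
        # printed accounting: high-quality total minus the five removal rows
        rep = FilterReport.from_counts(5_965_487, [973, 354, 9_183, 6_119, 21])
        assert rep.clean_reads == 5_948_837
        assert rep.percentages()["clean_reads"] == 99.72

    def test_table_accounting_uniparous_library(self):
        rep = FilterReport.from_counts(5_963_795, [1_066, 665, 10_495, 6_375, 49])
        assert rep.clean_reads == 5_945_145
        assert rep.percentages()["clean_reads"] == 99.69

    def test_identity_check(self):
        rep = FilterReport.from_counts(100, [1, 2, 3, 4, 5])
        rep.check()
        rep.clean_reads += 1
        with pytest.raises(AssertionError):
            rep.check()

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            FilterReport(total_reads=-1)

    @given(st.lists(st.integers(0, 1000), min_size=5, max_size=5), st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_accounting_identity_fuzz(self, removals, clean):
        rep = FilterReport.from_counts(sum(removals) + clean, removals)
        rep.check()
        assert rep.clean_reads == clean


class TestAdapterFinding:
    def test_exact_adapter(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        assert find_adapter3(insert + A3, A3) == len(insert)

    def test_suffix_overlap(self):
        read = "ACGTACGTACGTACGTACGTAC" + A3[:6]
        assert find_adapter3(read, A3) == 22

    def test_short_overlap_rejected(self):
        read = "ACGTACGTACGTACGTACGTAC" + A3[:5]
        assert find_adapter3(read, A3) is None

    def test_one_mismatch_per_10nt(self):
        adapter_mut = "A" + A3[1:12]  # 1 mismatch in a 12 nt overlap
        read = "CCGTCCGTCCGTCCGTCCGTCC" + adapter_mut
        assert find_adapter3(read, A3) == 22

    def test_no_adapter(self):
        assert find_adapter3("ACGCCGTACGTTGACCATCGGACATCAGCATCAGCA", A3) is None

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            find_adapter3("ACGT", "")

    def test_adapter5_prefix(self):
        assert has_adapter5_prefix(A5[:12] + "ACGTACGTAC", A5)
        assert has_adapter5_prefix("T" + A5[1:12] + "ACGTACGTAC", A5)  # 1 mismatch
        assert not has_adapter5_prefix("CCCCCCCCCCCCCCCCCCCC", A5)


class TestCleanReads:
    def test_polya_insert_removed(self, tmp_path):
        fq = tmp_path / "a.fastq"
        write_fastq(fq, [_read("A" * 20 + A3[:16])])
        tags, rep = clean_reads(fq, A3, A5)
        assert rep.polyA == 1 and rep.clean_reads == 0 and tags == []

    def test_fixed_filter_order(self, tmp_path):
        # one read per category, in a single file
        reads = [
            _read("ACGTACGTACGTACGTACGTAC" + A3[:14], qual_char="#"),   # low quality
            _read("ACGCCGTACGTTGACCATCGGACATCAGCATCAGCA"),              # no 3' adapter
            _read((A3 * 2)[:36]),                                       # empty insert
            _read(A5[:12] + "ACGTACGTAC" + A3[:14]),                    # 5' contaminant
            _read("ACGTACGTACGT" + A3[:24]),                            # < 18 nt
            _read("A" * 20 + A3[:16]),                                  # polyA
            _read("ACGTACGTACGTACGTACGTAC" + A3[:14]),                  # clean
        ]
        fq = tmp_path / "mix.fastq"
        write_fastq(fq, reads)
        tags, rep = clean_reads(fq, A3, A5)
        assert rep.total_reads == 7
        assert rep.high_quality == 6
        assert [getattr(rep, c) for c in REMOVAL_CATEGORIES] == [1, 1, 1, 1, 1]
        assert rep.clean_reads == 1
        assert tags == ["ACGTACGTACGTACGTACGTAC"]

    def test_empty_file_zeroed_report(self, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        tags, rep = clean_reads(fq, A3, A5)
        assert tags == [] and rep.total_reads == 0 and rep.clean_reads == 0

    def test_truncated_record_names_index(self, tmp_path):
        fq = tmp_path / "trunc.fastq"
        fq.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n")
        with pytest.raises(ValueError, match="index 1"):
            clean_reads(fq, A3, A5)

    def test_noise_free_simulation_all_clean(self, noise_free_study):
        rep = noise_free_study.report1
        assert rep.clean_reads == 10_000
        assert all(getattr(rep, c) == 0 for c in REMOVAL_CATEGORIES)

    def test_noise_free_recovers_inserts_verbatim(self, noise_free_study):
        matures = set(noise_free_study.refs.bundle.mature.values())
        recovered = sum(1 for t in noise_free_study.tags1 if t in matures)
        assert recovered >= 0.99 * len(noise_free_study.tags1)

    def test_report_matches_truth_categories(self, small_study):
        truth = small_study.truth.category_counts[0]
        rep = small_study.report1
        assert rep.polyA == truth["polyA"]
        assert rep.insert_null == truth["insert_null"]
        assert rep.adapter3_null == truth["adapter3_null"]
        assert rep.adapter5_contaminants == truth["adapter5"]
        assert rep.shorter_than_18nt == truth["short"]
        assert rep.total_reads - rep.high_quality == truth["low_quality"]

    def test_cleaning_idempotent(self, small_study):
        kept, removed = filter_inserts(small_study.tags1, small_study.config.adapter5)
        assert kept == small_study.tags1
        assert not removed


class TestLengthDistribution:
    def test_single_length(self):
        dist = length_distribution(["A" * 22] * 5)
        assert dist == {22: (5, 1.0)}

    def test_empty(self):
        assert length_distribution([]) == {}

    def test_fractions_recompute(self, small_study):
        dist = length_distribution(small_study.tags1)
        total = sum(c for c, _ in dist.values())
        assert total == small_study.report1.clean_reads
        for length, (count, frac) in dist.items():
            assert frac == pytest.approx(count / total)
        assert sum(f for _, f in dist.values()) == pytest.approx(1.0)

    def test_simulated_profile_mode(self, noise_free_study):
        # configured profile peaks at 22; depth 10k must reproduce the mode
        dist = length_distribution(noise_free_study.tags1)
        mode = max(dist, key=lambda k: dist[k][0])
        assert mode == 22
        profile = noise_free_study.config.length_profile
        for length, (_, frac) in dist.items():
            assert frac == pytest.approx(profile[length], abs=0.15)


class TestCollapseTags:
    def test_basic_counts(self):
        t = collapse_tags(["ACGT" * 5] * 3 + ["TTTTACGTACGTACGTACGTA"],
                          [])
        assert t.loc[0, "tag"] == "ACGT" * 5
        assert t.loc[0, "count_lib1"] == 3
        assert t.loc[1, "count_lib1"] == 1
        assert (t["count_lib2"] == 0).all()

    def test_lib2_only_tag(self):
        t = collapse_tags([], ["ACGTACGTACGTACGTAC"])
        assert t.loc[0, "count_lib1"] == 0
        assert t.loc[0, "count_lib2"] == 1

    def test_length_bounds_applied(self):
        t = collapse_tags(["A" * 17, "C" * 31, "ACGTACGTACGTACGTAC"], [])
        assert list(t["tag"]) == ["ACGTACGTACGTACGTAC"]

    def test_conservation_on_simulation(self, small_study):
        t = small_study.tag_table
        assert t["count_lib1"].sum() == small_study.report1.clean_reads
        assert t["count_lib2"].sum() == small_study.report2.clean_reads
        assert t["tag"].is_unique

    def test_deterministic_order(self, small_study):
        t = small_study.tag_table
        keys = list(zip(-(t["count_lib1"] + t["count_lib2"]), t["tag"]))
        assert keys == sorted(keys)

    def test_noise_free_counts_match_truth(self, noise_free_study):
        truth = noise_free_study.truth.mirna_table
        t = noise_free_study.tag_table.set_index("tag")
        for _, row in truth.iterrows():
            assert t.loc[row["sequence"], "count_lib1"] == row["realized_lib1"]
            assert t.loc[row["sequence"], "count_lib2"] == row["realized_lib2"]


@given(st.lists(
    st.text(alphabet="ACGT", min_size=18, max_size=30), min_size=0, max_size=30))
@settings(max_examples=30, deadline=None)
def test_filter_report_conservation_fuzz(tmp_path_factory, inserts):
    rng = np.random.default_rng(0)
    fq = tmp_path_factory.mktemp("fuzz") / "reads.fastq"
    reads = []
    for i, ins in enumerate(inserts):
        qual = "I" if rng.random() < 0.9 else "#"
        reads.append(FastqRead(f"r{i}", (ins + A3 * 3)[:36], qual * 36))
    write_fastq(fq, reads)
    tags, rep = clean_reads(fq, A3, A5)
    rep.check()
    assert rep.clean_reads == len(tags)
    assert rep.total_reads == len(inserts)


def test_mean_quality():
    assert mean_quality("II") == 40.0
    assert mean_quality("#") == 2.0
    assert mean_quality("") == 0.0


def test_classify_insert_order():
    assert classify_insert("", A5) == "insert_null"
    assert classify_insert(A5[:12] + "AAAAAAAAAA", A5) == "adapter5_contaminants"
    assert classify_insert("ACGTACGTACGT", A5) == "shorter_than_18nt"
    assert classify_insert("A" * 19 + "C", A5) == "polyA"  # 95% A
    assert classify_insert("ACGTACGTACGTACGTACGTAC", A5) is None
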