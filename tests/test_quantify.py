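"""Size classes, rRNA removal, family counting, normalization, fold change."""

import numpy as np
import pandas as pd
import pytest

from pirnasig import (
    Alignment,
    ConsensusRecord,
    FamilyGroup,
    LibraryMeta,
    RefCategory,
    SmallRead,
    classify_by_size,
    count_families,
    fold_change,
    low_count_filter,
    mirna_total,
    normalize_counts,
    remove_rrna,
)

from conftest import random_record


def read_of_len(n, rid="r"):
    return SmallRead(rid, "A" * n)


class TestClassifyBySize:
    @pytest.mark.parametrize(
        "length,bucket",
        [(23, "piRNA"), (30, "piRNA"), (18, "miRNA"), (22, "miRNA"),
         (17, "other"), (31, "other")],
    )
    def test_inclusive_boundaries(self, length, bucket):
        out = classify_by_size([read_of_len(length)])
        assert len(out[bucket]) == 1
        assert sum(len(v) for v in out.values()) == 1


class TestRemoveRrna:
    def test_contaminant_removed_clean_kept(self, rng):
        rrna = random_record(rng, "rRNA1", 300, RefCategory.RRNA)
        contaminant = SmallRead("bad", rrna.seq[50:75])
        clean = SmallRead("good", "".join(rng.choice(list("ACGT"), size=25)))
        kept = remove_rrna([contaminant, clean], [rrna], max_mm=2)
        assert [r.read_id for r in kept] == ["good"]

    def test_empty_reference_is_identity(self):
        reads = [read_of_len(25)]
        assert remove_rrna(reads, []) == reads


class TestMirnaTotal:
    def test_counts_matching_reads_once(self, rng):
        mir = random_record(rng, "mir1", 22, RefCategory.MIRNA)
        # a second identical miRNA entry: multi-mapping still counts once
        mir2 = ConsensusRecord("mir2", mir.seq, RefCategory.MIRNA)
        matching = [SmallRead(f"m{i}", mir.seq) for i in range(8)]
        nonmatching = [SmallRead(f"x{i}", "ACGT" * 5) for i in range(2)]
        assert mirna_total(matching + nonmatching, [mir, mir2], max_mm=0) == 8

    def test_zero_matches_error(self, rng):
        mir = random_record(rng, "mir1", 20, RefCategory.MIRNA)
        with pytest.raises(ValueError, match="normalization"):
            mirna_total([SmallRead("x", "A" * 20)], [mir], max_mm=0)


def _groups():
    return [
        FamilyGroup("g1", {"g1", "g1b"}),
        FamilyGroup("g2", {"g2"}),
    ]


def aln(read_id, family, strand="plus", weight=1.0, start=10):
    return Alignment(read_id, family, strand, start, start + 24, 0, weight)


class TestCountFamilies:
    def test_redundant_members_count_once(self):
        alns = {"r1": [aln("r1", "g1", weight=0.5), aln("r1", "g1b", weight=0.5)]}
        table, stats = count_families(alns, _groups())
        assert table["raw"].sum() == 1.0
        assert table.iloc[0]["group_id"] == "g1"
        assert stats == {"counted": 1, "cross_group_discarded": 0, "unaligned": 0}

    def test_cross_group_read_discarded(self):
        alns = {"r1": [aln("r1", "g1", weight=0.5), aln("r1", "g2", weight=0.5)]}
        table, stats = count_families(alns, _groups())
        assert table.empty
        assert stats["cross_group_discarded"] == 1

    def test_minus_strand_is_antisense(self):
        alns = {"r1": [aln("r1", "g2", strand="minus")]}
        table, _ = count_families(alns, _groups())
        assert table.iloc[0]["strand"] == "antisense"
        assert table.iloc[0]["raw"] == 1.0

    def test_strand_tie_splits_half_half(self):
        alns = {
            "r1": [
                aln("r1", "g1", "plus", 0.5),
                aln("r1", "g1b", "minus", 0.5),
            ]
        }
        table, _ = count_families(alns, _groups())
        by_strand = table.set_index("strand")["raw"]
        assert by_strand["sense"] == 0.5 and by_strand["antisense"] == 0.5

    def test_weighted_mode_sums_apportioned_weights(self):
        alns = {"r1": [aln("r1", "g1", weight=0.5), aln("r1", "g1b", weight=0.5)]}
        table, _ = count_families(alns, _groups(), weighted=True)
        assert table["raw"].sum() == pytest.approx(1.0)

    def test_order_invariance_and_conservation(self, rng):
        reads = {}
        for i in range(50):
            rid = f"r{i}"
            kind = i % 4
            if kind == 0:
                reads[rid] = [aln(rid, "g1")]
            elif kind == 1:
                reads[rid] = [aln(rid, "g1"), aln(rid, "g2")]
            elif kind == 2:
                reads[rid] = []
            else:
                reads[rid] = [aln(rid, "g2", "minus")]
        table, stats = count_families(reads, _groups())
        shuffled = dict(reversed(list(reads.items())))
        table2, stats2 = count_families(shuffled, _groups())
        pd.testing.assert_frame_equal(table, table2)
        assert stats == stats2
        # conservation: counted + discarded + unaligned == input reads
        assert table["raw"].sum() + stats["cross_group_discarded"] + stats["unaligned"] == len(reads)


class TestNormalizeAndFilter:
    def make_table(self):
        rows = []
        for lib, count in [("m_r1", 10), ("m_r2", 14), ("a_r1", 60), ("a_r2", 80)]:
            rows.append({"group_id": "g1", "library_id": lib, "strand": "sense", "raw": count})
        return pd.DataFrame(rows)

    def test_normalization_scales_inversely_with_mirna_total(self):
        table = self.make_table()
        one = normalize_counts(table, {lib: 1000 for lib in table["library_id"]})
        two = normalize_counts(table, {lib: 2000 for lib in table["library_id"]})
        assert np.allclose(one["normalized"], 2 * two["normalized"])
        assert one["normalized"].iloc[0] == pytest.approx(10 / 1000 * 1e6)

    def test_missing_library_total_errors(self):
        with pytest.raises(KeyError):
            normalize_counts(self.make_table(), {"m_r1": 1000})

    @pytest.mark.parametrize(
        "means,kept",
        [({"mut": 10, "mel": 12, "sim": 8}, False),
         ({"mut": 60, "mel": 5, "sim": 5}, True),
         ({"mut": 50, "mel": 50, "sim": 50}, True)],  # boundary: mean == 50 retained
    )
    def test_low_count_filter_rule(self, means, kept):
        meta = [LibraryMeta(f"{g}_r{i}", g, i) for g in means for i in (1, 2)]
        rows = [
            {"group_id": "fam", "library_id": f"{g}_r{i}", "strand": "sense", "raw": float(v)}
            for g, v in means.items()
            for i in (1, 2)
        ]
        table = pd.DataFrame(rows)
        filtered = low_count_filter(table, meta, min_avg=50)
        assert (not filtered.empty) is kept

    def test_filter_sums_sense_and_antisense(self):
        meta = [LibraryMeta("m_r1", "mut", 1)]
        rows = [
            {"group_id": "fam", "library_id": "m_r1", "strand": "sense", "raw": 30.0},
            {"group_id": "fam", "library_id": "m_r1", "strand": "antisense", "raw": 25.0},
        ]
        filtered = low_count_filter(pd.DataFrame(rows), meta, min_avg=50)
        assert not filtered.empty


class TestFoldChange:
    def make(self, norm_a, norm_b):
        meta = [LibraryMeta("a1", "A", 1), LibraryMeta("b1", "B", 1)]
        rows = [
            {"group_id": "fam", "library_id": "a1", "strand": "sense",
             "raw": 1.0, "normalized": norm_a},
            {"group_id": "fam", "library_id": "b1", "strand": "sense",
             "raw": 1.0, "normalized": norm_b},
        ]
        return pd.DataFrame(rows), meta

    def test_te_threshold_up(self):
        table, meta = self.make(100.0, 25.0)
        out = fold_change(table, meta, "A", "B", threshold=2.0)
        assert out.iloc[0]["log2FC"] == pytest.approx(2.0)
        assert out.iloc[0]["class"] == "up"

    def test_small_change_unchanged(self):
        table, meta = self.make(30.0, 25.0)
        out = fold_change(table, meta, "A", "B", threshold=2.0)
        assert out.iloc[0]["class"] == "unchanged"

    def test_gene_threshold_is_lower(self):
        table, meta = self.make(40.0, 20.0)
        assert fold_change(table, meta, "A", "B", threshold=1.5).iloc[0]["class"] == "up"
        assert fold_change(table, meta, "A", "B", threshold=2.0).iloc[0]["class"] == "unchanged"

    def test_zero_denominator_and_double_zero(self):
        table, meta = self.make(10.0, 0.0)
        out = fold_change(table, meta, "A", "B")
        assert np.isinf(out.iloc[0]["log2FC"]) and out.iloc[0]["class"] == "up"
        table, meta = self.make(0.0, 0.0)
        assert fold_change(table, meta, "A", "B").iloc[0]["class"] == "NA"

    def test_pseudocount_tames_zero(self):
        table, meta = self.make(10.0, 0.0)
        out = fold_change(table, meta, "A", "B", pseudocount=1.0)
        assert out.iloc[0]["log2FC"] == pytest.approx(np.log2(11.0))
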