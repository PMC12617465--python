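"""Alignment I/O, hotspot masking, haplotype collapsing and diversity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodemes.mito_data import (
    Alignment,
    AlignmentError,
    HaplotypeTable,
    MaskPolicy,
    SampleMetadata,
    apply_mask,
    collapse_haplotypes,
    default_mask,
    haplogroup_frequency_table,
    haplotype_diversity,
    macrohaplogroup,
    read_fasta,
    read_metadata,
    write_fasta,
    write_metadata,
)


class TestReadFasta:
    def test_parses_aligned_records(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nACGTACGTAC\n>b\nACGTACGTAT\n>c\nACGTACGAAC\n")
        aln = read_fasta(p)
        assert (aln.n, aln.L) == (3, 10)

    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nacgt\n>b\nACGT\n")
        aln = read_fasta(p)
        assert aln.sequences() == ["ACGT", "ACGT"]

    def test_unknown_symbol_becomes_n(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nACRT\n>b\nACGT\n")
        assert read_fasta(p).sequences()[0] == "ACNT"

    def test_unequal_lengths_rejected(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nACGTACGTAC\n>b\nACGTACGTA\n")
        with pytest.raises(AlignmentError):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text("")
        with pytest.raises(AlignmentError):
            read_fasta(p)

    def test_roundtrip(self, tmp_path, toy_alignment):
        p = tmp_path / "out.fasta"
        write_fasta(toy_alignment, p)
        back = read_fasta(p)
        assert back.sample_ids == toy_alignment.sample_ids
        assert np.array_equal(back.matrix, toy_alignment.matrix)


class TestDefaultMask:
    def test_hotspot_positions(self):
        policy = default_mask()
        assert 16519 in policy.excluded_positions
        assert set(range(303, 316)) <= policy.excluded_positions
        assert set(range(16182, 16195)) <= policy.excluded_positions
        assert len([p for p in policy.excluded_positions if 303 <= p <= 315]) == 13

    def test_boundaries_not_excluded(self):
        policy = default_mask()
        for p in (302, 316, 16181, 16195, 16518):
            assert p not in policy.excluded_positions

    def test_indels_excluded_by_default(self):
        assert default_mask().exclude_indels


class TestApplyMask:
    def test_hotspot_difference_removed(self):
        L = 16_569
        a = ["A"] * L
        b = ["A"] * L
        b[16519 - 1] = "T"  # only difference sits on the hotspot
        aln = Alignment.from_sequences(["x", "y"], ["".join(a), "".join(b)])
        masked = apply_mask(aln, default_mask())
        assert (masked.matrix[0] != masked.matrix[1]).sum() == 0

    def test_gap_column_dropped(self):
        aln = Alignment.from_sequences(["x", "y"], ["AC-TA", "ACGTA"])
        masked = apply_mask(aln, MaskPolicy(frozenset(), exclude_indels=True))
        assert masked.L == 4
        assert 3 not in masked.positions

    def test_empty_mask_is_identity(self, toy_alignment):
        masked = apply_mask(toy_alignment, MaskPolicy(frozenset(), exclude_indels=False))
        assert np.array_equal(masked.matrix, toy_alignment.matrix)

    def test_original_coordinates_tracked(self):
        aln = Alignment.from_sequences(["x", "y"], ["ACGTA", "ACGTA"])
        masked = apply_mask(aln, MaskPolicy(frozenset({2, 4}), exclude_indels=False))
        assert masked.positions.tolist() == [1, 3, 5]


class TestCollapseHaplotypes:
    def test_twelve_sequences_eleven_haplotypes(self):
        from mitodemes.synthetic_data import generate_toy

        tab = collapse_haplotypes(generate_toy("paleolithic_hd"))
        assert tab.k == 11
        assert sorted(tab.counts.tolist(), reverse=True) == [2] + [1] * 10

    def test_all_identical(self):
        aln = Alignment.from_sequences(["a", "b", "c"], ["ACGT"] * 3)
        assert collapse_haplotypes(aln).k == 1

    def test_all_distinct(self, toy_alignment):
        tab = collapse_haplotypes(toy_alignment)
        assert tab.k == 4  # s0 == s1 in the fixture

    def test_counts_sum_to_n(self, toy_alignment):
        tab = collapse_haplotypes(toy_alignment)
        assert tab.n == toy_alignment.n
        assert abs(tab.frequencies.sum() - 1.0) < 1e-12

    def test_masking_then_collapsing_idempotent(self, toy_alignment):
        policy = default_mask()
        once = apply_mask(toy_alignment, policy)
        twice = apply_mask(once, policy)
        t1 = collapse_haplotypes(once)
        t2 = collapse_haplotypes(twice)
        assert t1.haplotype_ids == t2.haplotype_ids
        assert np.array_equal(t1.counts, t2.counts)

    def test_n_column_dropped_alignment_wide(self):
        # the N column must not split haplotypes (complete-case columns)
        aln = Alignment.from_sequences(["a", "b", "c"], ["ANGT", "AAGT", "ACGT"])
        assert collapse_haplotypes(aln).k == 1


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, expected_2dp",
        [
            ([1] * 10 + [2], 0.98),  # 12 sequences, 11 haplotypes
            ([1] * 15 + [2], 0.99),  # 17 sequences, 16 haplotypes
            ([5], 0.0),  # single haplotype
            ([1, 1, 1, 1], 1.0),  # 4 distinct: (4/3)(1 - 4/16) = 1
        ],
    )
    def test_known_compositions(self, counts, expected_2dp):
        tab = HaplotypeTable.from_counts(counts)
        assert round(haplotype_diversity(tab), 2) == expected_2dp

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            haplotype_diversity(HaplotypeTable.from_counts([1]))

    @given(
        st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=15).filter(
            lambda c: sum(c) >= 2
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_pairwise_draw_probability(self, counts):
        """Hd equals the probability that two draws without replacement
        differ (brute-force enumeration oracle)."""
        tab = HaplotypeTable.from_counts(counts)
        n = sum(counts)
        same = sum(c * (c - 1) for c in counts) / (n * (n - 1))
        assert haplotype_diversity(tab) == pytest.approx(1.0 - same, abs=1e-12)


class TestHaplogroupTable:
    def _meta(self, triples):
        return [
            SampleMetadata(sample_id=f"s{i}", group=g, haplogroup=h, age_bp=0.0)
            for i, (g, h) in enumerate(triples)
        ]

    def test_u5_dominance(self):
        meta = self._meta([("uzzo_meso", "U5b2b")] * 7 + [("uzzo_meso", "U2'3'4")])
        table, missing = haplogroup_frequency_table(meta)
        assert table.loc["uzzo_meso", "U5"] == 7
        assert table.loc["uzzo_meso"].sum() == 8
        assert not missing

    def test_u8bk_three_of_four(self):
        meta = self._meta(
            [("buffa_neo", "K1a2"), ("buffa_neo", "U8b1b1"), ("buffa_neo", "K2"), ("buffa_neo", "H3")]
        )
        table, _ = haplogroup_frequency_table(meta)
        assert table.loc["buffa_neo", "U8b/K"] == 3
        assert table.loc["buffa_neo", "U8b/K"] / table.loc["buffa_neo"].sum() == 0.75

    def test_missing_labels_reported(self):
        meta = self._meta([("g", "U5b"), ("g", None)])
        table, missing = haplogroup_frequency_table(meta)
        assert missing == ["s1"]
        assert table.to_numpy().sum() == 1

    def test_empty_metadata(self):
        table, missing = haplogroup_frequency_table([])
        assert table.empty and not missing

    @pytest.mark.parametrize(
        "label, macro",
        [("U5b2b1", "U5"), ("K1a3", "U8b/K"), ("HV0a", "HV0-V"), ("H1c", "H1"), ("T2b", "T2")],
    )
    def test_longest_prefix_wins(self, label, macro):
        assert macrohaplogroup(label) == macro


class TestMetadataIO:
    def test_roundtrip(self, tmp_path):
        meta = [
            SampleMetadata("a1", "uzzo_mesolithic", None, 9100.0, (8500.0, 9700.0), "U5b2b"),
            SampleMetadata("m1", "modern", "trapani", 0.0, None, "H1"),
        ]
        p = tmp_path / "meta.tsv"
        write_metadata(meta, p)
        back = read_metadata(p)
        assert back[0].age_ci95 == (8500.0, 9700.0)
        assert back[1].geogroup == "trapani"
        assert back[1].haplogroup == "H1"

    def test_age_outside_ci_rejected(self):
        with pytest.raises(ValueError):
            SampleMetadata("x", "g", age_bp=100.0, age_ci95=(200.0, 300.0))
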