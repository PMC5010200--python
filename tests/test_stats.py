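"""Variable/informative site counting, percent variability, ranking."""

from __future__ import annotations

import numpy as np
import pytest

from cphotspot.align import MultipleAlignment, progressive_msa
from cphotspot.io import PlastomeError
from cphotspot.loci import HomologousLocusSet, Locus
from cphotspot.reference import load_marker_table
from cphotspot.stats import (
    LocusDivergence,
    count_parsimony_informative,
    count_variable_sites,
    divergence_of_set,
    percent_variability,
    rank_markers,
    site_counts,
    sliding_window_identity,
    summarize_partitions,
)

from oracles import site_counts_bruteforce


def msa_of(*rows):
    return MultipleAlignment(names=[f"s{i}" for i in range(len(rows))], rows=list(rows))


class TestSiteCounting:
    def test_constant_alignment(self):
        assert count_variable_sites(msa_of("AAAA", "AAAA")) == 0

    def test_single_variable_column(self):
        assert count_variable_sites(msa_of("AAAT", "AAAA", "AAAA")) == 1

    def test_gap_handling(self):
        # col1 {A,A} constant; col2 {A,G} variable (gap ignored); col3 variable
        assert count_variable_sites(msa_of("A-T", "AAT", "AGA")) == 2

    def test_gaps_never_make_a_column_variable(self):
        assert count_variable_sites(msa_of("A-", "AA", "A-")) == 0

    def test_all_gap_and_single_char_columns_excluded(self):
        counts = site_counts(msa_of("-A", "-A", "--"))
        assert counts.n_excluded == 1
        assert counts.n_constant == 1

    def test_pic_definition(self):
        assert count_parsimony_informative(msa_of("A", "A", "T", "T", "C")) == 1
        assert count_parsimony_informative(msa_of("A", "A", "A", "A", "T")) == 0

    def test_n_is_not_a_state(self):
        # col2 holds a single unambiguous char: excluded, not variable
        assert count_variable_sites(msa_of("AN", "AN", "AA")) == 0
        assert count_parsimony_informative(msa_of("N", "N", "A", "A", "T")) == 0

    def test_matches_bruteforce_on_random_alignments(self, rng):
        for _ in range(50):
            rows = [
                "".join(rng.choice(list("ACGTN-"), size=100, p=[0.2, 0.2, 0.2, 0.2, 0.05, 0.15]))
                for _ in range(5)
            ]
            msa = msa_of(*rows)
            counts = site_counts(msa)
            bf_const, bf_var, bf_pic, bf_excl = site_counts_bruteforce(rows)
            assert counts.n_variable == bf_var
            assert counts.n_pic == bf_pic
            assert counts.n_constant == bf_const
            assert counts.n_excluded == bf_excl

    def test_concatenation_consistency(self, rng):
        rows_a = ["".join(rng.choice(list("ACGT-"), size=60)) for _ in range(4)]
        rows_b = ["".join(rng.choice(list("ACGT-"), size=40)) for _ in range(4)]
        joint = [a + b for a, b in zip(rows_a, rows_b)]
        assert count_variable_sites(msa_of(*joint)) == count_variable_sites(
            msa_of(*rows_a)
        ) + count_variable_sites(msa_of(*rows_b))

    def test_adding_divergent_row_never_decreases_vc(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(4)]
        before = count_variable_sites(msa_of(*rows))
        extra = "".join(rng.choice(list("ACGT"), size=80))
        after = count_variable_sites(msa_of(*rows, extra))
        assert after >= before


class TestPercentVariability:
    @pytest.mark.parametrize(
        "ns,l,expected",
        [(30, 332, 9.04), (27, 639, 4.23), (71, 1234, 5.75), (0, 500, 0.0)],
    )
    def test_published_examples(self, ns, l, expected):
        assert percent_variability(ns, l) == expected

    def test_half_up_rounding(self):
        assert percent_variability(1, 16) == 6.25
        assert percent_variability(1, 800) == 0.13  # 0.125 rounds up

    def test_zero_length_rejected(self):
        with pytest.raises(PlastomeError):
            percent_variability(1, 0)

    def test_counts_out_of_range_rejected(self):
        with pytest.raises(PlastomeError):
            percent_variability(10, 5)


class TestReferenceMarkerTable:
    def test_recomputed_percentages_match_printed_where_consistent(self):
        df = load_marker_table()
        assert len(df) == 20
        consistent = df[df.printed_consistent]
        assert len(consistent) == 17
        assert (consistent.pct_vc == consistent.pct_vc_printed).all()
        assert (consistent.pct_pic == consistent.pct_pic_printed).all()

    def test_top_locus_and_range(self):
        df = load_marker_table()
        assert df.loc[df.pct_vc.idxmax(), "name"] == "rps18-rpl20"
        assert df.pct_vc.max() == 9.04


class TestRankMarkers:
    @staticmethod
    def rows_from_reference():
        df = load_marker_table()
        return [
            LocusDivergence(
                name=r["name"],
                category="spacer",
                length_min=r["length_min"],
                length_max=r["length_max"],
                aligned_length=r["aligned_length"],
                n_variable=r["n_vc"],
                n_pic=r["n_pic"],
            )
            for r in df.to_dict("records")
        ]

    def test_reference_table_ranks_rps18_rpl20_first(self):
        ranked = rank_markers(self.rows_from_reference(), top_n=20)
        assert ranked[0].name == "rps18-rpl20"
        assert ranked[0].pct_variable == 9.04
        assert len(ranked) == 20

    def test_all_zero_ties_break_by_name(self):
        loci = [
            LocusDivergence(n, "spacer", 100, 100, 100, 0, 0)
            for n in ("zeta", "alpha", "mid")
        ]
        ranked = rank_markers(loci, top_n=3)
        assert [d.name for d in ranked] == ["alpha", "mid", "zeta"]

    def test_category_filter(self):
        loci = [
            LocusDivergence("spc", "spacer", 100, 100, 100, 10, 2),
            LocusDivergence("cds", "coding", 100, 100, 100, 50, 10),
        ]
        assert [d.name for d in rank_markers(loci, category="noncoding")] == ["spc"]
        assert rank_markers(loci, category="coding")[0].name == "cds"


class TestDivergenceOfSet:
    def test_invariants_on_random_set(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=300))
        loci = {}
        for g in range(5):
            s = list(base)
            for pos in rng.integers(0, 300, size=8):
                s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
            loci[f"G{g}"] = Locus(
                name="a-b", category="spacer", sequence="".join(s), source_id=f"G{g}"
            )
        lset = HomologousLocusSet(name="a-b", category="spacer", loci=loci)
        div = divergence_of_set(lset)
        assert 0 <= div.n_pic <= div.n_variable <= div.aligned_length
        assert div.pct_pic <= div.pct_variable
        assert div.aligned_length >= 300


class TestSummarizePartitions:
    def test_identical_genomes_have_zero_divergence(self):
        msa = msa_of("ACGTACGTAC", "ACGTACGTAC")
        out = summarize_partitions({"LSC": msa})
        assert out[0].pct == 0.0

    def test_coding_noncoding_split(self):
        rows = ["AAAACCCC", "AAATCCCG"]
        msa = MultipleAlignment(names=["G1", "G2"], rows=rows)
        coding = {"LSC": {"G1": [(0, 4)], "G2": [(0, 4)]}}
        out = {d.partition: d for d in summarize_partitions({"LSC": msa}, coding)}
        assert out["coding"].aligned_length == 4
        assert out["coding"].n_snps == 1
        assert out["noncoding"].n_snps == 1


def test_sliding_window_identity_flags_divergent_window():
    rows = ["A" * 100 + "C" * 20, "A" * 100 + "G" * 20]
    msa = MultipleAlignment(names=["a", "b"], rows=rows)
    df = sliding_window_identity(msa, window=20, step=20)
    assert df.iloc[0].identity_pct == 100.0
    assert df.iloc[-1].identity_pct < 100.0
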