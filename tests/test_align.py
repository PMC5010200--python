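"""Pairwise and progressive alignment, anchor chaining."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cphotspot.align import (
    MultipleAlignment,
    align_partition,
    build_anchor_chain,
    pairwise_nw,
    progressive_msa,
)
from cphotspot.io import PlastomeError

from oracles import (
    best_colinear_chain_bruteforce,
    msa3_optimal_sp_score,
    msa_sp_score,
    nw_score_bruteforce,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestPairwiseNW:
    def test_identity(self):
        a, b, score = pairwise_nw("ACGT", "ACGT")
        assert (a, b, score) == ("ACGT", "ACGT", 4)

    def test_single_deletion(self):
        a, b, score = pairwise_nw("ACGT", "AGT")
        assert score == 1
        assert (a, b) == ("ACGT", "A-GT")

    def test_empty_rejected(self):
        with pytest.raises(PlastomeError):
            pairwise_nw("", "ACGT")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_score_matches_bruteforce(self, a, b):
        """DP score equals the exhaustive optimum over all alignments."""
        _, _, score = pairwise_nw(a, b)
        assert score == nw_score_bruteforce(a, b)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_alignment_degaps_to_inputs_and_scores_itself(self, a, b):
        ra, rb, score = pairwise_nw(a, b)
        assert ra.replace("-", "") == a
        assert rb.replace("-", "") == b
        assert msa_sp_score([ra, rb]) == score


class TestProgressiveMSA:
    def test_identical_sequences_align_without_gaps(self):
        msa = progressive_msa([(f"s{i}", "ACGTACGTAC") for i in range(5)])
        assert msa.aligned_length == 10
        assert all(r == "ACGTACGTAC" for r in msa.rows)

    def test_aligned_length_at_least_longest_input(self, rng):
        seqs = []
        base = "".join(rng.choice(list("ACGT"), size=326))
        for i, cut in enumerate((0, 10, 20, 30, 43)):
            seqs.append((f"s{i}", base[cut:]))
        msa = progressive_msa(seqs)
        assert msa.aligned_length >= 326

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=0, max_size=12), min_size=2, max_size=5))
    def test_rows_degap_to_inputs_bit_exactly(self, seqs):
        named = [(f"s{i}", s) for i, s in enumerate(seqs)]
        msa = progressive_msa(named)
        for i, (_, s) in enumerate(named):
            assert msa.degapped(i) == s

    @pytest.mark.parametrize(
        "seqs",
        [
            ["ACGTACGT", "ACGTACGT", "ACGTACGT"],
            ["ACGTACGT", "ACGAACGT", "ACGTACGT"],  # one SNP
            ["ACGTACGT", "ACGACGT", "ACGTACGT"],  # one deletion
            ["TTACGG", "TTCGG", "TTACG"],
        ],
    )
    def test_matches_exact_three_sequence_optimum(self, seqs):
        """On short triples the progressive result attains the exact
        sum-of-pairs optimum from the 3-D lattice DP."""
        named = [(f"s{i}", s) for i, s in enumerate(seqs)]
        msa = progressive_msa(named)
        assert msa_sp_score(msa.rows) == msa3_optimal_sp_score(seqs)

    def test_row_order_follows_input_not_guide(self):
        named = [("short", "ACG"), ("long", "ACGTACGTA")]
        msa = progressive_msa(named)
        assert msa.names == ["short", "long"]
        assert msa.degapped(0) == "ACG"


class TestAnchorChain:
    def test_identical_sequences_single_merged_anchor(self):
        seq = "ACGTTGCAAGCTTGCATGCCGCTAGGCATCG"
        chain = build_anchor_chain([seq, seq], k=5)
        assert len(chain.anchors) == 1
        assert chain.anchors[0].positions == (0, 0)
        assert chain.anchors[0].length == len(seq)

    def test_snp_splits_into_two_flanking_anchors(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=200))
        mutated = base[:100] + ("A" if base[100] != "A" else "C") + base[101:]
        chain = build_anchor_chain([base, mutated], k=21)
        assert len(chain.anchors) == 2
        first, second = chain.anchors
        assert first.positions == (0, 0)
        assert first.positions[0] + first.length <= 100
        assert second.positions[0] >= 101

    def test_transposed_block_excluded(self, rng):
        """A block moved out of order cannot join a co-linear chain; the
        selected chain weight equals the exhaustive-subset optimum."""
        a = "".join(rng.choice(list("ACGT"), size=120))
        block, rest = a[:30], a[30:]
        b = rest + block  # transposition
        chain = build_anchor_chain([a, b], k=15)
        anchors = [(x.positions, x.length) for x in chain.anchors]
        # rebuild the full candidate set at the same k to feed the oracle
        full = build_anchor_chain([a, b], k=15)
        assert sum(x.length for x in full.anchors) == best_colinear_chain_bruteforce(
            _candidate_anchors([a, b], k=15)
        )
        for x, y in zip(chain.anchors, chain.anchors[1:]):
            assert all(
                x.positions[g] + x.length <= y.positions[g] for g in range(2)
            )


def _candidate_anchors(seqs, k):
    """All merged candidate anchors (pre-chaining), via the public builder
    run pairwise on sub-slices is not possible; reimplement candidate
    generation minimally for the oracle."""
    maps = []
    for s in seqs:
        first, dup = {}, set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if km in first:
                dup.add(km)
            else:
                first[km] = i
        maps.append({km: i for km, i in first.items() if km not in dup})
    shared = set(maps[0]).intersection(*maps[1:])
    cands = sorted(tuple(m[km] for m in maps) for km in shared)
    merged = []
    for pos in cands:
        if merged:
            (lp, ll) = merged[-1]
            delta = pos[0] - lp[0]
            if 0 < delta <= ll and all(
                pos[g] - lp[g] == delta for g in range(1, len(seqs))
            ):
                merged[-1] = (lp, delta + k)
                continue
        merged.append((pos, k))
    return merged


class TestAlignPartition:
    def test_zero_divergence_gives_identical_columns(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        msa = align_partition([(f"s{i}", seq) for i in range(5)])
        assert msa.aligned_length == 3000
        assert all(r == seq for r in msa.rows)

    def test_rows_degap_to_inputs(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=2000))
        variants = []
        for i in range(4):
            s = list(base)
            for pos in rng.integers(0, len(base), size=20):
                s[pos] = "ACGT"[(("ACGT".index(s[pos])) + 1) % 4]
            variants.append((f"s{i}", "".join(s)))
        msa = align_partition(variants)
        for i, (_, s) in enumerate(variants):
            assert msa.degapped(i) == s

    def test_row_content_stable_under_input_order(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=1500))
        variants = {}
        for i in range(4):
            s = list(base)
            for pos in rng.integers(0, len(base), size=10):
                s[pos] = "ACGT"[(("ACGT".index(s[pos])) + 2) % 4]
            variants[f"s{i}"] = "".join(s)
        order1 = sorted(variants)
        order2 = list(reversed(order1))
        m1 = align_partition([(n, variants[n]) for n in order1])
        m2 = align_partition([(n, variants[n]) for n in order2])
        cols1 = {n: m1.rows[m1.names.index(n)] for n in order1}
        cols2 = {n: m2.rows[m2.names.index(n)] for n in order1}
        assert cols1 == cols2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(PlastomeError):
            MultipleAlignment(names=["a", "b"], rows=["ACGT", "ACG"])
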