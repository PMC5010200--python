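"""Locus extraction and homolog matching."""

from __future__ import annotations

import pytest

from cphotspot.io import FeatureAnnotation, PlastomeError, PlastomeRecord, revcomp
from cphotspot.loci import (
    Locus,
    extract_coding_loci,
    extract_noncoding_loci,
    match_homologs,
)


def record_with(features, length=1000, seq=None, ident="G1", rng=None):
    if seq is None:
        seq = "".join(rng.choice(list("ACGT"), size=length))
    return PlastomeRecord(identifier=ident, sequence=seq, features=features)


class TestExtractCoding:
    def test_minus_strand_exons_concatenated_then_revcomped(self, rng):
        rec = record_with(
            [
                FeatureAnnotation("gA", "gene", [(0, 400, "-")]),
                FeatureAnnotation("gA", "CDS", [(0, 150, "-"), (300, 400, "-")]),
            ],
            rng=rng,
        )
        (locus,) = extract_coding_loci(rec, min_len=200)
        assert locus.length == 250
        assert locus.sequence == revcomp(rec.sequence[0:150] + rec.sequence[300:400])
        assert locus.category == "coding"

    def test_short_gene_dropped_strictly(self, rng):
        rec = record_with(
            [
                FeatureAnnotation("gA", "gene", [(0, 180, "+")]),
                FeatureAnnotation("gA", "CDS", [(0, 180, "+")]),
                FeatureAnnotation("gB", "gene", [(300, 500, "+")]),
                FeatureAnnotation("gB", "CDS", [(300, 500, "+")]),
            ],
            rng=rng,
        )
        # strictly greater than: a 200 bp gene does not pass min_len=200
        assert extract_coding_loci(rec, min_len=200) == []
        assert len(extract_coding_loci(rec, min_len=200, strict=False)) == 1

    def test_ir_duplicates_emitted_once(self, rng):
        rec = record_with(
            [
                FeatureAnnotation("gA", "CDS", [(0, 300, "+")]),
                FeatureAnnotation("gA", "CDS", [(600, 900, "-")], copy_tag="copy2"),
            ],
            rng=rng,
        )
        loci = extract_coding_loci(rec, min_len=200)
        assert [l.name for l in loci] == ["gA"]
        assert loci[0].sequence == rec.sequence[0:300]

    def test_exon_unit_mode(self, rng):
        rec = record_with(
            [
                FeatureAnnotation("gA", "CDS", [(0, 250, "+"), (400, 650, "+")]),
            ],
            rng=rng,
        )
        loci = extract_coding_loci(rec, min_len=200, unit="exon")
        assert [l.name for l in loci] == ["gA_exon1", "gA_exon2"]


class TestExtractNoncoding:
    def test_spacer_between_consecutive_genes(self, rng):
        rec = record_with(
            [
                FeatureAnnotation("g1", "gene", [(100, 200, "+")]),
                FeatureAnnotation("g2", "gene", [(500, 600, "+")]),
            ],
            rng=rng,
        )
        spacers = [
            l for l in extract_noncoding_loci(rec, min_len=200) if l.category == "spacer"
        ]
        by_name = {l.name: l for l in spacers}
        assert by_name["g1-g2"].length == 300
        assert by_name["g1-g2"].sequence == rec.sequence[200:500]
        # wrap-around spacer g2 -> g1 through the origin: 400 + 100 bp
        assert by_name["g2-g1"].length == 500

    def test_gap_below_threshold_dropped(self, rng):
        rec = record_with(
            [
                FeatureAnnotation("g1", "gene", [(0, 200, "+")]),
                FeatureAnnotation("g2", "gene", [(350, 1000, "+")]),
            ],
            rng=rng,
        )
        spacers = [
            l for l in extract_noncoding_loci(rec, min_len=200) if l.category == "spacer"
        ]
        assert spacers == []  # 150 bp gap, and no wrap spacer (gene at both ends)

    def test_overlapping_genes_skipped(self, rng):
        rec = record_with(
            [
                FeatureAnnotation("g1", "gene", [(0, 400, "+")]),
                FeatureAnnotation("g2", "gene", [(300, 700, "+")]),
            ],
            rng=rng,
        )
        spacers = [
            l for l in extract_noncoding_loci(rec, min_len=100) if l.category == "spacer"
        ]
        assert all(l.name != "g1-g2" for l in spacers)

    def test_intron_named_in_translation_order(self, rng):
        rec = record_with(
            [
                FeatureAnnotation("gA", "gene", [(0, 900, "-")]),
                FeatureAnnotation(
                    "gA", "CDS", [(0, 200, "-"), (450, 600, "-"), (850, 900, "-")]
                ),
            ],
            rng=rng,
        )
        introns = [
            l for l in extract_noncoding_loci(rec, min_len=100) if l.category == "intron"
        ]
        # minus strand: first intron in translation order is the rightmost gap
        assert [l.name for l in introns] == ["gA_intron1", "gA_intron2"]
        assert introns[0].sequence == revcomp(rec.sequence[600:850])
        assert introns[1].sequence == revcomp(rec.sequence[200:450])


class TestMatchHomologs:
    @staticmethod
    def locus(name, gid, category="spacer", seq="A" * 250):
        return Locus(name=name, category=category, sequence=seq, source_id=gid)

    def test_complete_set(self):
        per = {g: [self.locus("a-b", g)] for g in ("G1", "G2", "G3")}
        (lset,) = match_homologs(per)
        assert lset.n_genomes == 3
        assert not lset.partial

    def test_partial_flagged_and_filterable(self):
        per = {g: [self.locus("a-b", g)] for g in ("G1", "G2", "G3", "G4")}
        per["G5"] = []
        sets = match_homologs(per)
        assert sets[0].partial
        assert match_homologs(per, require_complete=True) == []

    def test_reversed_spacer_name_matches(self):
        per = {
            "G1": [self.locus("a-b", "G1")],
            "G2": [self.locus("b-a", "G2")],
        }
        (lset,) = match_homologs(per)
        assert lset.n_genomes == 2

    def test_duplicate_locus_in_one_genome_rejected(self):
        per = {
            "G1": [self.locus("a-b", "G1"), self.locus("a-b", "G1")],
            "G2": [self.locus("a-b", "G2")],
        }
        with pytest.raises(PlastomeError):
            match_homologs(per)

    def test_single_genome_rejected(self):
        with pytest.raises(PlastomeError):
            match_homologs({"G1": []})


class TestOnSimulatedAncestor:
    def test_spacer_boundaries_equal_truth(self, small_simulation):
        """Extracted spacers reproduce the generator's intergenic intervals."""
        _, ancestor, _, truth = small_simulation
        loci = extract_noncoding_loci(ancestor, min_len=1)
        extracted = {
            l.name: (l.interval[0], l.interval[1])
            for l in loci
            if l.category == "spacer"
        }
        for name, interval in truth.spacer_intervals.items():
            if interval[1] - interval[0] >= 1 and name in extracted:
                assert extracted[name] == interval
        # every truth spacer wide enough to survive must be found
        missing = [
            n
            for n, (s, e) in truth.spacer_intervals.items()
            if e - s > 1 and n not in extracted
        ]
        assert missing == []
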