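"""Extraction of homologous coding and non-coding loci.

Divergence-hotspot screens compare, across genomes, the individual loci a
plastome is built from: protein-coding genes (spliced exons), intergenic
spacers between consecutive genes, and introns.  Loci shorter than a
length threshold (default: strictly greater than 200 bp are kept) carry
too little signal for marker development and are dropped.

Homologs are matched across genomes by name: congeneric plastomes are
syntenic with identical gene sets, so annotation-trusted name matching is
exact and deterministic.  Spacers are keyed by the unordered pair of
flanking genes so that the two IR copies (and genomes rotated differently)
collapse onto one locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import FeatureAnnotation, PlastomeError, PlastomeRecord, revcomp
from .quadripartite import QuadripartiteStructure

logger = logging.getLogger(__name__)

CODING = "coding"
SPACER = "spacer"
INTRON = "intron"


@dataclass
class Locus:
    """One locus in one genome."""

    name: str
    category: str  # coding | spacer | intron
    sequence: str
    source_id: str
    region: str = ""  # LSC | SSC | IRb | IRa | "" when no partition given
    interval: tuple[int, int] = (0, 0)  # genomic span on the source record
    spans_junction: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def match_key(self) -> tuple[str, str]:
        """Key used for homolog matching across genomes.

        Spacer names depend on which flanking gene comes first on the local
        strand/rotation, so spacers are keyed by the sorted flank pair.
        """
        if self.category == SPACER and "-" in self.name:
            a, b = self.name.split("-", 1)
            return (SPACER, "-".join(sorted((a, b))))
        return (self.category, self.name)


@dataclass
class HomologousLocusSet:
    """One named locus with a sequence per genome."""

    name: str
    category: str
    loci: dict[str, Locus] = field(default_factory=dict)
    partial: bool = False

    @property
    def n_genomes(self) -> int:
        return len(self.loci)

    def sequences(self) -> list[tuple[str, str]]:
        return [(gid, locus.sequence) for gid, locus in sorted(self.loci.items())]

    def length_range(self) -> tuple[int, int]:
        lengths = [locus.length for locus in self.loci.values()]
        return min(lengths), max(lengths)


def _keep(length: int, min_len: int, strict: bool) -> bool:
    return length > min_len if strict else length >= min_len


def _dedupe_ir_copies(feats: list[FeatureAnnotation]) -> list[FeatureAnnotation]:
    """Keep one copy per gene name: the untagged (first-seen) copy."""
    seen: set[str] = set()
    out = []
    for feat in sorted(feats, key=lambda f: (f.name, f.copy_tag)):
        if feat.name in seen:
            continue
        seen.add(feat.name)
        out.append(feat)
    return sorted(out, key=lambda f: f.start)


def _annotate_region(
    locus: Locus, structure: QuadripartiteStructure | None
) -> Locus:
    if structure is not None:
        region, spans = structure.region_of_interval(*locus.interval)
        locus.region = region
        locus.spans_junction = spans
    return locus


def extract_coding_loci(
    record: PlastomeRecord,
    min_len: int = 200,
    unit: str = "gene",
    structure: QuadripartiteStructure | None = None,
    strict: bool = True,
) -> list[Locus]:
    """Extract protein-coding loci, one per gene (or per exon).

    With ``unit="gene"`` the exons of each CDS are concatenated in
    translation order and reverse-complemented to the coding strand; with
    ``unit="exon"`` every exon becomes its own locus named ``gene_exonN``.
    IR-duplicated genes are emitted once.  Loci failing the length
    threshold are dropped.
    """
    if unit not in ("gene", "exon"):
        raise ValueError(f"unit must be 'gene' or 'exon', got {unit!r}")
    cds = [f for f in record.features if f.kind == "CDS"]
    out: list[Locus] = []
    for feat in _dedupe_ir_copies(cds):
        if unit == "gene":
            seq = record.feature_sequence(feat)
            if _keep(len(seq), min_len, strict):
                out.append(
                    _annotate_region(
                        Locus(
                            name=feat.name,
                            category=CODING,
                            sequence=seq,
                            source_id=record.identifier,
                            interval=(feat.start, feat.end),
                        ),
                        structure,
                    )
                )
        else:
            intervals = feat.intervals
            order = intervals if feat.strand == "+" else intervals[::-1]
            for i, (s, e, strand) in enumerate(order, start=1):
                seq = record.sequence[s:e]
                if strand == "-":
                    seq = revcomp(seq)
                if _keep(len(seq), min_len, strict):
                    out.append(
                        _annotate_region(
                            Locus(
                                name=f"{feat.name}_exon{i}",
                                category=CODING,
                                sequence=seq,
                                source_id=record.identifier,
                                interval=(s, e),
                            ),
                            structure,
                        )
                    )
    return out


def extract_noncoding_loci(
    record: PlastomeRecord,
    min_len: int = 200,
    structure: QuadripartiteStructure | None = None,
    strict: bool = True,
) -> list[Locus]:
    """Extract intergenic spacers and introns.

    Spacers are the maximal intervals between consecutive gene-level
    features in genome order on the canonical strand, named
    ``upstream-downstream`` (the circular wrap-around spacer between the
    last and first gene included).  Introns are the gaps between
    consecutive exons of multi-interval CDS/tRNA/rRNA features, named
    ``gene_intronN`` in translation order and oriented to the coding
    strand.  One IR copy of each duplicated locus is retained.
    """
    n = record.length
    out: list[Locus] = []

    genes = sorted(record.genes(), key=lambda f: (f.start, f.end))
    seen_spacer: dict[tuple[str, ...], bool] = {}
    for i, gene in enumerate(genes):
        nxt = genes[(i + 1) % len(genes)] if genes else None
        if nxt is None:
            break
        if nxt is gene:
            continue  # single-gene genome: no spacer
        start = gene.end
        if i + 1 < len(genes):
            end = nxt.start
            if end <= start:
                logger.debug(
                    "%s: overlapping genes %s/%s leave no spacer",
                    record.identifier,
                    gene.name,
                    nxt.name,
                )
                continue
            seq = record.sequence[start:end]
            interval = (start, end)
        else:  # wrap-around spacer: last gene -> first gene through origin
            end = genes[0].start
            gap = (end - start) % n
            if gap == 0 or start < end:
                continue
            seq = record.sequence[start:] + record.sequence[:end]
            interval = (start, start + gap)
        key = tuple(sorted((gene.name, nxt.name)))
        tagged = bool(gene.copy_tag or nxt.copy_tag)
        if key in seen_spacer and (tagged or seen_spacer[key]):
            continue  # second IR copy of the same spacer
        seen_spacer[key] = tagged
        if not _keep(len(seq), min_len, strict):
            continue
        locus = Locus(
            name=f"{gene.name}-{nxt.name}",
            category=SPACER,
            sequence=seq,
            source_id=record.identifier,
            interval=interval,
        )
        out.append(_annotate_region(locus, structure))

    multi = [
        f
        for f in record.features
        if f.kind in ("CDS", "tRNA", "rRNA") and len(f.intervals) >= 2
    ]
    for feat in _dedupe_ir_copies(multi):
        ivs = feat.intervals
        gaps = [
            (ivs[j][1], ivs[j + 1][0])
            for j in range(len(ivs) - 1)
            if ivs[j + 1][0] > ivs[j][1]
        ]
        if feat.strand == "-":
            gaps = gaps[::-1]
        for j, (s, e) in enumerate(gaps, start=1):
            seq = record.sequence[s:e]
            if feat.strand == "-":
                seq = revcomp(seq)
            if _keep(len(seq), min_len, strict):
                out.append(
                    _annotate_region(
                        Locus(
                            name=f"{feat.name}_intron{j}",
                            category=INTRON,
                            sequence=seq,
                            source_id=record.identifier,
                            interval=(s, e),
                        ),
                        structure,
                    )
                )
    return out


def match_homologs(
    per_genome_loci: dict[str, list[Locus]],
    require_complete: bool = False,
) -> list[HomologousLocusSet]:
    """Group loci across genomes into homologous sets by (name, category).

    A set missing from at least one genome is flagged ``partial`` (and
    dropped entirely when ``require_complete`` is set); marker ranking
    downstream ignores partial sets by default.
    """
    if len(per_genome_loci) < 2:
        raise PlastomeError("homolog matching needs at least two genomes")
    groups: dict[tuple[str, str], HomologousLocusSet] = {}
    for gid, loci in per_genome_loci.items():
        keys_seen: set[tuple[str, str]] = set()
        for locus in loci:
            key = locus.match_key
            if key in keys_seen:
                raise PlastomeError(
                    f"genome {gid}: duplicate locus {locus.name!r} "
                    f"({locus.category}) after deduplication"
                )
            keys_seen.add(key)
            group = groups.get(key)
            if group is None:
                group = HomologousLocusSet(name=locus.name, category=locus.category)
                groups[key] = group
            group.loci[gid] = locus
    n_genomes = len(per_genome_loci)
    out = []
    for key in sorted(groups):
        group = groups[key]
        group.partial = group.n_genomes < n_genomes
        if require_complete and group.partial:
            continue
        out.append(group)
    return out
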