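"""Reading and writing plastome records.

The in-memory model used throughout the package is :class:`PlastomeRecord`:
a circular DNA sequence plus a flat list of :class:`FeatureAnnotation`.
All internal coordinates are 0-based half-open on the forward strand;
GenBank's 1-based inclusive locations are converted at the I/O boundary and
nowhere else.  Features that span the origin of a circular molecule are
represented by two intervals and flagged ``wraps_origin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

GENE_LIKE = {"gene"}
FEATURE_KINDS = {"gene", "CDS", "tRNA", "rRNA", "intron", "exon", "misc"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class PlastomeError(ValueError):
    """Malformed record, feature or coordinate."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FeatureAnnotation:
    """One annotated feature: a name, a kind, and stranded intervals.

    ``intervals`` is an ordered list of ``(start, end, strand)`` triples in
    0-based half-open coordinates; multi-interval features arise from
    GenBank ``join()`` locations (multi-exon genes) and from origin-spanning
    features which are unwrapped into two intervals.  ``copy_tag``
    disambiguates IR-duplicated copies of the same gene ("" for the first
    occurrence, "copy2" for the second, ...).
    """

    name: str
    kind: str
    intervals: list[tuple[int, int, str]]
    copy_tag: str = ""
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if not self.intervals:
            raise PlastomeError(f"feature {self.name!r} has no intervals")
        for start, end, strand in self.intervals:
            if start >= end:
                raise PlastomeError(
                    f"feature {self.name!r}: empty interval ({start}, {end})"
                )
            if strand not in "+-":
                raise PlastomeError(f"feature {self.name!r}: bad strand {strand!r}")

    @property
    def strand(self) -> str:
        return self.intervals[0][2]

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.intervals)

    def span_length(self) -> int:
        return sum(e - s for s, e, _ in self.intervals)


@dataclass
class PlastomeRecord:
    """One genome: identifier, sequence and feature annotations."""

    identifier: str
    sequence: str
    features: list[FeatureAnnotation] = field(default_factory=list)
    is_circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise PlastomeError(f"record {self.identifier!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise PlastomeError(
                f"record {self.identifier!r}: non-ACGTN characters {sorted(bad)}"
            )
        n = len(self.sequence)
        for feat in self.features:
            if feat.end > n:
                raise PlastomeError(
                    f"feature {feat.name!r} extends to {feat.end} beyond "
                    f"sequence end {n}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: FeatureAnnotation) -> str:
        """Spliced feature sequence on its coding strand.

        Intervals are concatenated in genomic order; minus-strand features
        are reverse-complemented afterwards, so the result reads 5'->3' in
        translation order.
        """
        parts = [self.sequence[s:e] for s, e, _ in feat.intervals]
        joined = "".join(parts)
        return revcomp(joined) if feat.strand == "-" else joined

    def genes(self) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == "gene"]


class GeneCount(NamedTuple):
    total: int
    unique: int


def count_genes(record: PlastomeRecord) -> GeneCount:
    """Gene tally with IR-duplicated copies counted separately.

    ``total`` counts every gene feature (IR duplicates twice, matching the
    convention under which a plastome with 18 IR-duplicated genes among 113
    unique ones carries 131 genes); ``unique`` counts distinct gene names.
    """
    genes = record.genes()
    return GeneCount(total=len(genes), unique=len({g.name for g in genes}))


def gc_content(sequence: str) -> float:
    """GC percentage over unambiguous bases, full precision.

    N bases are excluded from both numerator and denominator.  Use
    :func:`round_half_up` when formatting for reports.
    """
    if not sequence:
        raise PlastomeError("gc_content of empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise PlastomeError("gc_content: no unambiguous bases")
    return 100.0 * gc / acgt


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as report tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# GenBank I/O


def _kind_of(feature_type: str) -> str | None:
    if feature_type in ("gene", "CDS", "tRNA", "rRNA", "intron", "exon"):
        return feature_type
    if feature_type in ("source",):
        return None
    return "misc"


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "locus_tag", "product", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    1-based inclusive locations become 0-based half-open intervals,
    ``join()`` locations become multi-interval features, ``complement()``
    sets strand '-'.  A ``join`` whose last part ends at the sequence end
    and whose first part starts at 1 is treated as origin-spanning on a
    circular molecule.
    """
    path = Path(path)
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise PlastomeError(f"cannot parse GenBank file {path}: {exc}") from exc
    sequence = str(seqrec.seq).upper()
    if not sequence:
        raise PlastomeError(f"{path}: no ORIGIN sequence")
    n = len(sequence)
    is_circular = seqrec.annotations.get("topology", "linear") == "circular"

    features: list[FeatureAnnotation] = []
    seen: dict[tuple[str, str], int] = {}
    for feat in seqrec.features:
        kind = _kind_of(feat.type)
        if kind is None:
            continue
        intervals: list[tuple[int, int, str]] = []
        for part in sorted(feat.location.parts, key=lambda p: int(p.start)):
            start, end = int(part.start), int(part.end)
            if end > n:
                raise PlastomeError(
                    f"{path}: feature {feat.type} interval ({start}, {end}) "
                    f"beyond sequence end {n}"
                )
            strand = "-" if part.strand == -1 else "+"
            intervals.append((start, end, strand))
        if not intervals:
            continue
        wraps = (
            is_circular
            and len(intervals) >= 2
            and intervals[0][0] == 0
            and intervals[-1][1] == n
            and len(feat.location.parts) >= 2
        )
        name = _feature_name(feat)
        occurrence = seen.get((name, kind), 0) + 1
        seen[(name, kind)] = occurrence
        features.append(
            FeatureAnnotation(
                name=name,
                kind=kind,
                intervals=intervals,
                copy_tag="" if occurrence == 1 else f"copy{occurrence}",
                wraps_origin=wraps,
            )
        )
    return PlastomeRecord(
        identifier=seqrec.id or path.stem,
        sequence=sequence,
        features=features,
        is_circular=is_circular,
    )


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Write a record (sequence + features) as a GenBank flat file."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.identifier,
        name=record.identifier[:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.is_circular else "linear",
        },
    )
    for feat in record.features:
        locs = [
            SimpleLocation(s, e, strand=1 if strand == "+" else -1)
            for s, e, strand in feat.intervals
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [feat.name]}
        if feat.copy_tag:
            qualifiers["note"] = [feat.copy_tag]
        seqrec.features.append(
            SeqFeature(location, type=feat.kind, qualifiers=qualifiers)
        )
    SeqIO.write([seqrec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA I/O


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(name, sequence)`` pairs as multi-FASTA, 70-column lines.

    The first whitespace-separated token of the name is the FASTA id; the
    remainder becomes the description.  Duplicate ids are rejected.
    """
    records = list(records)
    ids = [name.split()[0] for name, _ in records]
    if len(set(ids)) != len(ids):
        raise PlastomeError("duplicate FASTA ids")
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read multi-FASTA as ``(description, sequence)`` pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.description, str(rec.seq).upper()))
    return out


def rotate_record(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate a circular record so old position ``offset`` becomes 0.

    Features are lifted over; a feature interval that ends up crossing the
    new origin is split into two intervals and flagged ``wraps_origin``.
    """
    n = record.length
    offset %= n
    if offset == 0:
        return record
    if not record.is_circular:
        raise PlastomeError("cannot rotate a linear record")
    new_seq = record.sequence[offset:] + record.sequence[:offset]
    new_feats = []
    for feat in record.features:
        intervals: list[tuple[int, int, str]] = []
        wraps = False
        for s, e, strand in feat.intervals:
            ns, ne = (s - offset) % n, (e - offset) % n or n
            if ns < ne:
                intervals.append((ns, ne, strand))
            else:  # crosses the new origin
                intervals.append((ns, n, strand))
                intervals.append((0, ne, strand))
                wraps = True
        intervals.sort()
        new_feats.append(replace(feat, intervals=intervals, wraps_origin=wraps))
    return PlastomeRecord(
        identifier=record.identifier,
        sequence=new_seq,
        features=new_feats,
        is_circular=True,
    )


def reverse_complement_record(record: PlastomeRecord) -> PlastomeRecord:
    """Reverse-complement a record, flipping feature strands and coordinates."""
    n = record.length
    new_feats = []
    for feat in record.features:
        intervals = sorted(
            (n - e, n - s, "-" if strand == "+" else "+")
            for s, e, strand in feat.intervals
        )
        new_feats.append(replace(feat, intervals=intervals))
    return PlastomeRecord(
        identifier=record.identifier,
        sequence=revcomp(record.sequence),
        features=new_feats,
        is_circular=record.is_circular,
    )
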