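"""End-to-end scan: partition -> extract -> align -> statistics -> ranking.

``run_scan`` takes two or more annotated genomes and produces the report
tables of a comparative plastome survey:

* ``table1``      — per-genome summary (size, gene counts, GC, partition sizes)
* ``partitions``  — percent variability of LSC / SSC / IRa and pooled
  coding / non-coding columns
* ``loci_stats``  — per-locus divergence for every complete homologous set
* ``markers``     — the top non-coding loci ranked by percent variability
* ``repeats``     — SSR / tandem / palindrome census per genome
* ``windows``     — sliding-window identity along each partition alignment

Everything is a pure function of (inputs, config): reruns are
byte-identical.  Reports are TSV with '.' decimals and 2-decimal percents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import align as _align
from . import loci as _loci
from . import repeats as _repeats
from . import stats as _stats
from .io import PlastomeError, PlastomeRecord, count_genes, gc_content, read_genbank, round_half_up
from .quadripartite import QuadripartiteStructure, partition_genome

logger = logging.getLogger(__name__)

PARTITIONS = ("LSC", "SSC", "IRa")


@dataclass
class PipelineConfig:
    min_locus_len: int = 200
    top_n: int = 20
    ir_min_len: int = 1000
    anchor_k: int = 31
    max_gap: int = 20000
    coding_unit: str = "gene"
    ssr_minima: dict[int, int] | None = None
    window: int = 100
    step: int = 25
    with_repeats: bool = True

    def __post_init__(self) -> None:
        for name in ("min_locus_len", "top_n", "ir_min_len", "anchor_k", "max_gap"):
            if getattr(self, name) <= 0:
                raise PlastomeError(f"{name} must be positive")


@dataclass
class ScanResult:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    structures: dict[str, QuadripartiteStructure] = field(default_factory=dict)
    partition_alignments: dict[str, _align.MultipleAlignment] = field(default_factory=dict)
    locus_divergences: list[_stats.LocusDivergence] = field(default_factory=list)


def _coding_intervals_for_partition(
    structure: QuadripartiteStructure, partition: str
) -> list[tuple[int, int]]:
    """CDS exon intervals clipped to one partition, in local coordinates."""
    lo, hi = {
        "LSC": structure.lsc,
        "SSC": structure.ssc,
        "IRa": structure.ira,
        "IRb": structure.irb,
    }[partition]
    out = []
    for feat in structure.record.features:
        if feat.kind != "CDS":
            continue
        for s, e, _ in feat.intervals:
            cs, ce = max(s, lo), min(e, hi)
            if cs < ce:
                out.append((cs - lo, ce - lo))
    out.sort()
    return out


def align_partitions(
    structures: dict[str, QuadripartiteStructure], config: PipelineConfig
) -> tuple[dict[str, _align.MultipleAlignment], dict[str, dict[str, list[tuple[int, int]]]]]:
    """Anchored alignment of each partition across all genomes."""
    alignments: dict[str, _align.MultipleAlignment] = {}
    coding: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for partition in PARTITIONS:
        seqs = [
            (name, structures[name].partition_sequence(partition))
            for name in structures
        ]
        alignments[partition] = _align.align_partition(
            seqs, k=config.anchor_k, max_gap=config.max_gap
        )
        coding[partition] = {
            name: _coding_intervals_for_partition(structures[name], partition)
            for name in structures
        }
    return alignments, coding


def run_scan(
    records: list[PlastomeRecord], config: PipelineConfig | None = None
) -> ScanResult:
    """Run the full comparative scan over annotated genome records."""
    config = config or PipelineConfig()
    if len(records) < 2:
        raise PlastomeError("scan needs at least two genomes")
    result = ScanResult()

    structures = {
        rec.identifier: partition_genome(rec, min_len=config.ir_min_len)
        for rec in records
    }
    result.structures = structures

    rows = []
    for rec in records:
        st = structures[rec.identifier]
        counts = count_genes(rec)
        rows.append(
            {
                "id": rec.identifier,
                "length": rec.length,
                "n_genes_total": counts.total,
                "n_genes_unique": counts.unique,
                "gc_percent": round_half_up(gc_content(rec.sequence), 1),
                "lsc_len": st.lsc_length,
                "irb_len": st.ir_length,
                "ssc_len": st.ssc_length,
                "ira_len": st.ir_length,
                "j_lb": st.junctions["JLB"],
                "j_sb": st.junctions["JSB"],
                "j_sa": st.junctions["JSA"],
                "j_la": st.junctions["JLA"],
            }
        )
    result.tables["table1"] = pd.DataFrame(rows)

    alignments, coding = align_partitions(structures, config)
    result.partition_alignments = alignments
    part_rows = [
        {
            "partition": d.partition,
            "aligned_length": d.aligned_length,
            "n_snps": d.n_snps,
            "pct_variability": d.pct,
        }
        for d in _stats.summarize_partitions(alignments, coding)
    ]
    result.tables["partitions"] = pd.DataFrame(part_rows)

    per_genome: dict[str, list[_loci.Locus]] = {}
    for name, st in structures.items():
        rec = st.record
        per_genome[name] = _loci.extract_coding_loci(
            rec, min_len=config.min_locus_len, unit=config.coding_unit, structure=st
        ) + _loci.extract_noncoding_loci(
            rec, min_len=config.min_locus_len, structure=st
        )
    homolog_sets = _loci.match_homologs(per_genome)
    divergences = []
    locus_rows = []
    for lset in homolog_sets:
        if lset.partial:
            continue
        div = _stats.divergence_of_set(lset)
        divergences.append(div)
        lo, hi = lset.length_range()
        locus_rows.append(
            {
                "name": div.name,
                "category": div.category,
                "region": next(iter(lset.loci.values())).region,
                "length_min": lo,
                "length_max": hi,
                "aligned_length": div.aligned_length,
                "n_vc": div.n_variable,
                "pct_vc": div.pct_variable,
                "n_pic": div.n_pic,
                "pct_pic": div.pct_pic,
            }
        )
    result.locus_divergences = divergences
    loci_df = pd.DataFrame(locus_rows).sort_values(
        ["category", "name"], ignore_index=True
    ) if locus_rows else pd.DataFrame(
        columns=[
            "name", "category", "region", "length_min", "length_max",
            "aligned_length", "n_vc", "pct_vc", "n_pic", "pct_pic",
        ]
    )
    result.tables["loci_stats"] = loci_df

    ranked = _stats.rank_markers(divergences, top_n=config.top_n, category="noncoding")
    if len(ranked) < config.top_n:
        logger.warning(
            "only %d non-coding loci available for a top-%d ranking",
            len(ranked),
            config.top_n,
        )
    result.tables["markers"] = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "name": d.name,
                "category": d.category,
                "length_range": f"{d.length_min}-{d.length_max}",
                "aligned_length": d.aligned_length,
                "n_vc": d.n_variable,
                "pct_vc": d.pct_variable,
                "n_pic": d.n_pic,
                "pct_pic": d.pct_pic,
            }
            for i, d in enumerate(ranked)
        ]
    )

    if config.with_repeats:
        rep_rows = []
        for rec in records:
            seq = rec.sequence
            for hit in _repeats.find_ssrs(seq, minima=config.ssr_minima, circular=True):
                rep_rows.append(
                    {
                        "id": rec.identifier, "kind": "ssr", "start": hit.start,
                        "end": hit.end, "unit": hit.unit, "unit_count": hit.unit_count,
                        "arm_length": "", "spacer_length": "",
                    }
                )
            for hit in _repeats.find_tandem_repeats(seq, circular=True):
                rep_rows.append(
                    {
                        "id": rec.identifier, "kind": "tandem", "start": hit.start,
                        "end": hit.end, "unit": hit.unit, "unit_count": hit.unit_count,
                        "arm_length": "", "spacer_length": "",
                    }
                )
            for hit in _repeats.find_palindromes(seq, circular=True):
                rep_rows.append(
                    {
                        "id": rec.identifier, "kind": "palindrome", "start": hit.start,
                        "end": hit.end, "unit": "", "unit_count": "",
                        "arm_length": hit.arm_length, "spacer_length": hit.spacer_length,
                    }
                )
        result.tables["repeats"] = pd.DataFrame(
            rep_rows,
            columns=[
                "id", "kind", "start", "end", "unit", "unit_count",
                "arm_length", "spacer_length",
            ],
        )

    win_rows = []
    for partition, msa in alignments.items():
        df = _stats.sliding_window_identity(msa, window=config.window, step=config.step)
        df.insert(0, "partition", partition)
        win_rows.append(df)
    result.tables["windows"] = pd.concat(win_rows, ignore_index=True)
    return result


def write_report(result: ScanResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.2f")


def scan_files(paths: list[str | Path], config: PipelineConfig | None = None) -> ScanResult:
    records = []
    for path in paths:
        try:
            records.append(read_genbank(path))
        except PlastomeError as exc:
            raise PlastomeError(f"unreadable input {path}: {exc}") from exc
    return run_scan(records, config)
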