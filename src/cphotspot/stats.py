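"""Divergence statistics and marker ranking.

The central quantity is the proportion of variation of an aligned locus or
partition: ``100 * NS / L``, where NS is the number of variable alignment
columns (single-nucleotide substitutions; one column counts once however
many states it holds) and L the aligned length.  Variable columns (VCs)
hold at least two distinct unambiguous bases among their non-gap, non-N
characters; parsimony-informative columns (PICs) additionally require at
least two states each present in at least two rows.  Gaps are not a fifth
state: they never make a column variable, and columns with fewer than two
unambiguous characters are neither constant nor variable (they are tallied
separately as excluded).

Markers are ranked by raw percent variability — no model fitting and no
multiple-testing machinery, because the screen is a descriptive ranking,
not a hypothesis test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .align import MultipleAlignment, progressive_msa
from .io import PlastomeError
from .loci import HomologousLocusSet


@dataclass(frozen=True)
class SiteCounts:
    n_constant: int
    n_variable: int
    n_pic: int
    n_excluded: int


@dataclass
class LocusDivergence:
    """Per-locus divergence summary (one marker-table row)."""

    name: str
    category: str
    length_min: int
    length_max: int
    aligned_length: int
    n_variable: int
    n_pic: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_pic <= self.n_variable <= self.aligned_length:
            raise PlastomeError(
                f"{self.name}: inconsistent counts PIC {self.n_pic} <= "
                f"VC {self.n_variable} <= L {self.aligned_length} violated"
            )

    @property
    def pct_variable(self) -> float:
        return percent_variability(self.n_variable, self.aligned_length)

    @property
    def pct_pic(self) -> float:
        return percent_variability(self.n_pic, self.aligned_length)


@dataclass
class PartitionDivergence:
    partition: str
    aligned_length: int
    n_snps: int

    @property
    def pct(self) -> float:
        return percent_variability(self.n_snps, self.aligned_length)


def _base_counts(msa: MultipleAlignment) -> np.ndarray:
    """(4, L) count of A/C/G/T per column; N and gaps ignored."""
    codes = msa.codes()
    return np.stack([(codes == c).sum(axis=0) for c in range(4)])


def site_counts(msa: MultipleAlignment) -> SiteCounts:
    """Classify every column as constant, variable, or excluded; tally PICs."""
    if msa.n_rows < 2:
        raise PlastomeError("site counting needs at least two rows")
    counts = _base_counts(msa)
    usable = counts.sum(axis=0)
    distinct = (counts > 0).sum(axis=0)
    excluded = usable < 2
    variable = ~excluded & (distinct >= 2)
    constant = ~excluded & (distinct == 1)
    pic = ~excluded & ((counts >= 2).sum(axis=0) >= 2)
    return SiteCounts(
        n_constant=int(constant.sum()),
        n_variable=int(variable.sum()),
        n_pic=int(pic.sum()),
        n_excluded=int(excluded.sum()),
    )


def count_variable_sites(msa: MultipleAlignment) -> int:
    """Number of columns with >=2 distinct unambiguous bases."""
    return site_counts(msa).n_variable


def count_parsimony_informative(msa: MultipleAlignment) -> int:
    """Number of columns with >=2 bases each present in >=2 rows."""
    return site_counts(msa).n_pic


def percent_variability(ns: int, l: int) -> float:
    """``100 * ns / l`` rounded half-up to two decimals.

    This is the marker-screen statistic: substitution columns over aligned
    length, reported at table precision.
    """
    ns, l = int(ns), int(l)
    if l <= 0:
        raise PlastomeError("aligned length must be positive")
    if not 0 <= ns <= l:
        raise PlastomeError(f"need 0 <= ns <= l, got ns={ns}, l={l}")
    return float(
        (Decimal(ns) * 100 / Decimal(l)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def divergence_of_set(
    locus_set: HomologousLocusSet, msa: MultipleAlignment | None = None
) -> LocusDivergence:
    """Align one homologous locus set (progressively) and summarize it."""
    if msa is None:
        msa = progressive_msa(locus_set.sequences())
    counts = site_counts(msa)
    lo, hi = locus_set.length_range()
    return LocusDivergence(
        name=locus_set.name,
        category=locus_set.category,
        length_min=lo,
        length_max=hi,
        aligned_length=msa.aligned_length,
        n_variable=counts.n_variable,
        n_pic=counts.n_pic,
    )


def coding_column_mask(
    msa: MultipleAlignment,
    coding_intervals: dict[str, list[tuple[int, int]]],
) -> np.ndarray:
    """Columns overlapping any exon in any genome.

    ``coding_intervals`` maps genome name to exon intervals in the
    ungapped coordinates of that genome's alignment row.
    """
    mask = np.zeros(msa.aligned_length, dtype=bool)
    for row_idx, name in enumerate(msa.names):
        intervals = coding_intervals.get(name)
        if not intervals:
            continue
        colmap = msa.ungapped_to_column(row_idx)
        for start, end in intervals:
            start = max(0, start)
            end = min(len(colmap), end)
            if start < end:
                mask[colmap[start]:colmap[end - 1] + 1] = True
    return mask


def summarize_partitions(
    partition_alignments: dict[str, MultipleAlignment],
    coding_intervals: dict[str, dict[str, list[tuple[int, int]]]] | None = None,
) -> list[PartitionDivergence]:
    """Percent variability per partition, plus pooled coding/non-coding.

    ``partition_alignments`` maps partition name (LSC, SSC, IRa) to its
    alignment.  When ``coding_intervals`` is given (partition -> genome ->
    exon intervals in partition-local ungapped coordinates), two extra
    entries pool the coding and non-coding columns across partitions.
    """
    out: list[PartitionDivergence] = []
    coding_len = coding_snps = noncoding_len = noncoding_snps = 0
    for partition, msa in partition_alignments.items():
        counts = site_counts(msa)
        out.append(
            PartitionDivergence(
                partition=partition,
                aligned_length=msa.aligned_length,
                n_snps=counts.n_variable,
            )
        )
        if coding_intervals is not None:
            mask = coding_column_mask(msa, coding_intervals.get(partition, {}))
            codes = _base_counts(msa)
            usable = codes.sum(axis=0)
            variable = (usable >= 2) & ((codes > 0).sum(axis=0) >= 2)
            coding_len += int(mask.sum())
            coding_snps += int((variable & mask).sum())
            noncoding_len += int((~mask).sum())
            noncoding_snps += int((variable & ~mask).sum())
    if coding_intervals is not None:
        out.append(
            PartitionDivergence("coding", aligned_length=coding_len, n_snps=coding_snps)
        )
        out.append(
            PartitionDivergence(
                "noncoding", aligned_length=noncoding_len, n_snps=noncoding_snps
            )
        )
    return out


def rank_markers(
    loci: list[LocusDivergence],
    top_n: int = 20,
    category: str | None = "noncoding",
) -> list[LocusDivergence]:
    """Rank loci by percent variability, descending.

    Ties break by PIC count (descending) then name (ascending), so the
    ranking is a total, reproducible order.  ``category`` may be
    "noncoding" (spacers + introns), "coding", a specific category name,
    or None for all loci.
    """
    if category == "noncoding":
        pool = [d for d in loci if d.category in ("spacer", "intron")]
    elif category is None:
        pool = list(loci)
    else:
        pool = [d for d in loci if d.category == category]
    ranked = sorted(pool, key=lambda d: (-d.pct_variable, -d.n_pic, d.name))
    return ranked[:top_n]


def sliding_window_identity(
    msa: MultipleAlignment, window: int = 100, step: int = 25
) -> pd.DataFrame:
    """Windowed percent identity along an alignment.

    Identity of a window is the share of its usable columns (>=2
    unambiguous characters) that are constant — the textual stand-in for a
    percent-identity plot.
    """
    counts = _base_counts(msa)
    usable = counts.sum(axis=0) >= 2
    constant = usable & ((counts > 0).sum(axis=0) == 1)
    rows = []
    length = msa.aligned_length
    for start in range(0, max(1, length - window + 1), step):
        end = min(start + window, length)
        n_usable = int(usable[start:end].sum())
        n_const = int(constant[start:end].sum())
        identity = 100.0 * n_const / n_usable if n_usable else float("nan")
        rows.append({"start": start, "end": end, "identity_pct": identity})
    return pd.DataFrame(rows)
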