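# Methods

This note records the models, parameter choices and numerical conventions
behind `cphotspot`, and what the synthetic-data validation does and does
not demonstrate.

## Coordinate and data model

All internal coordinates are 0-based half-open on the forward strand;
GenBank's 1-based inclusive locations are converted once, at the I/O
boundary.  Circular molecules are first-class: features that span the
origin are represented as two intervals flagged `wraps_origin`, and
records can be rotated and reverse-complemented with full feature
liftover.  Gene totals count IR-duplicated copies separately (a plastome
with 113 unique genes, 18 of them duplicated through the IR, has 131
genes); the unique-name count is always reported alongside, since
conventions differ on trans-spliced genes and duplicates.

## Inverted-repeat detection and partitioning

An inverted duplication corresponds to a run of forward matches between
the sequence S and its reverse complement R along one diagonal of the
(S, R) match matrix.  The detector seeds on shared k-mers (k = 31,
sampled at a stride that guarantees a seed inside any repeat of the
minimum length), extends each seed to its maximal run with circular
indexing, and returns the longest pair of disjoint arcs; ties break to
the smaller start coordinate.  Matching is exact — real IR copies are
homogenized by gene conversion — and the minimum length (default
1000 bp) excludes dispersed repeats.  Mismatch-tolerant detection is out
of scope.

Partitioning labels the longer inter-IR arc LSC and the shorter SSC,
then rotates the genome to canonical LSC → IRb → SSC → IRa order.  Of the
two strand orientations the lexicographically smaller canonical sequence
is emitted (forward wins ties), making the output a pure function of the
circular molecule rather than of the file's arbitrary rotation and
strand.  IRa is the copy abutting the origin.  The invariant
`lsc + ssc + 2·ir = genome length` holds by construction and is asserted.

Because detection reports the *maximal* exact repeat, a substitution just
outside the IR that happens to recreate reverse-complementarity extends
the detected repeat past the annotated junction by a base or two; that is
a property of the definition, not a detection error.  The simulator
plants guard bases at the ancestral junctions so the planted IR is
exactly maximal there.

## Locus extraction

Coding loci are spliced CDS features (exons concatenated in translation
order, reverse-complemented to the coding strand); a per-exon mode is
available since annotation pipelines differ on whether "coding fragments"
means genes or exons.  Non-coding loci are intergenic spacers — maximal
intervals between consecutive gene features on the canonical strand,
named `upstream-downstream`, including the origin-spanning spacer — and
introns, the gaps between consecutive exons, named `gene_intronN`.
IR-duplicated loci are kept once (the copy met first in canonical
coordinates); a repeated flank pair is treated as an IR duplicate only
when a copy-tagged gene is involved, so genuine wrap-around spacers
survive.  The length threshold is strictly greater than 200 bp by
default (`strict=False` gives ≥).  Homologs match by name with spacers
keyed on the unordered flank pair; sets missing from any genome are
flagged partial and excluded from ranking.  Name-based matching trusts
the annotations — appropriate for syntenic congeneric plastomes, wrong
for rearranged genomes, which are out of scope.

## Alignment

Loci are aligned progressively: sequences join a growing profile in
decreasing-length order (ties by name).  Profile columns are scored
against an incoming residue by the summed pairwise substitution score
(match +1, mismatch −1, gap −2, N neutral); summing instead of averaging
keeps all arithmetic in integers so tie-breaking (diagonal > up > left)
is exact and reproducible.  Existing profile columns are never reopened.
The gap penalty is linear, which keeps the brute-force oracles tractable
and suits the short indels seen between congeneric plastomes; an affine
scheme was considered and rejected for this reason.  Progressive
alignment is not guaranteed sum-of-pairs optimal; on short test triples
it attains the exact 3-sequence optimum, and all alignments de-gap to
their inputs bit-exactly by construction.

Whole partitions (up to ~90 kb) are aligned by anchor chaining: k-mers
(k = 31) unique within every genome and shared by all become candidate
anchors, consecutive candidates merge into maximal blocks, and the
heaviest strictly co-linear non-overlapping subset is selected by
length-weighted longest-increasing-subsequence.  Anchors are emitted as
identical columns; only the short inter-anchor gaps go through the
progressive aligner.  A gap exceeding 20 kb aborts with an error, since
syntenic partitions never diverge that far; it indicates mispartitioned
input.

## Divergence statistics

A column is *variable* if its non-gap, non-N characters contain at least
two distinct bases, *constant* if exactly one, and *excluded* if fewer
than two usable characters remain (all-gap or singleton columns carry no
comparison).  Gaps are never a fifth state.  A column is
parsimony-informative if at least two states each occur in at least two
rows.  Percent variability is 100·NS/L, reported half-up at two decimals
(table precision); full precision is used internally.  Variable columns
count substitution events once regardless of how many states they hold —
the statistic is a column census, not an event estimate.  Markers are
ranked by raw percent variability with deterministic tie-breaking (PIC
count descending, then name); loci with 0.00% variability stay in the
pool and in any averages.  No significance testing or multiple-testing
correction is applied: the screen is a descriptive ranking.

Partition summaries pool coding columns (any column overlapping an exon
in any genome) and their complement across LSC, SSC and IRa.  Note the
pooled coding figure includes the IR's exons, which evolve at the slow IR
rate, so it sits a little below the single-copy coding level (about
2.1% vs 2.3% under the default simulation).

## Repeat census

All detectors report perfect repeats only; absolute counts from
mismatch-tolerant tools are not comparable, so cross-program comparisons
should be qualitative.  SSRs are maximal tracts of 1–6 bp motifs with
unit minima 10 (mono), 6 (di) and 5 (tri–hexa); a tract is reported once
under its smallest generating unit (checking divisor periods suffices,
by the Fine–Wilf theorem, because tracts span at least two units), and
the canonical motif is the lexicographically smallest rotation, strand
not collapsed.  Tandem repeats need a unit of ≥ 10 bp occurring at least
twice adjacently (unit lengths scanned up to 1 kb by default) and are
binned 10–20 / 20–30 / >30 bp.  Palindromes are maximal pairs of exactly
reverse-complementary arms, arm ≥ 10 bp, spacer 0–2000 bp,
non-overlapping; maximal arms above 1 kb are excluded so the genome-scale
IR does not enter the dispersed-repeat census.  Circular scanning doubles
the sequence and keeps hits starting before the origin copy.  N breaks
every tract and arm.

## The simulator

`build_ancestor` assembles an annotated quadripartite genome from
alternating random spacers and genes at 37% GC: defaults are LSC 89 kb,
SSC 20.4 kb, IR 23.7 kb (~157 kb total), 113 unique genes (18
IR-duplicated, 12 in the SSC, 11 with introns), about half the genome
coding, with SSR tracts planted mid-spacer and recorded.  `evolve` walks
a newick tree (default: five leaves on a star with unit branches)
applying Jukes–Cantor substitutions — per-site substitution probability
p = ¾(1 − e^(−4d/3)) for distance d = rate × branch length — with
per-partition rates, then indels (rate 1e-4 per single-copy site per
unit branch length, geometric lengths with mean 3, never inside the IR).
Substitutions sampled on IRb are mirrored into IRa so the copies stay
byte-identical, emulating gene-conversion homogenization.  Annotations
and junctions are lifted through indels, and the truth record stores
every leaf's final-state substitutions, deletions and insertions; a
replay function reconstructs each leaf byte-exactly from the record.

Default rates are calibrated once through the closed form for a star
tree — a column is variable unless all n leaves agree, so
P(variable) = 1 − (1−p)^n − 3(p/3)^n — to column-variability targets of
1.21% (IR), 2.30% (single-copy coding), 3.58% (LSC non-coding) and
5.54% (SSC non-coding), the non-coding values chosen so the aggregate
LSC and SSC variabilities land near 2.9% and 3.9% at the generator's
~50% coding fraction.  These levels reflect the divergence observed
among congeneric kiwifruit-family plastomes.

What the simulator does not model: transition/transversion bias,
among-site rate variation (gamma), codon structure and selection,
rearrangements, IR expansion/contraction and gene loss.  Passing tests
therefore demonstrate that the pipeline's measurements are correct for
the stated substitution/indel model on syntenic genomes — not that the
aligner or detector is robust to rearrangement or extreme divergence.

## Validation design and problem sizes

Unit and property tests run against independent brute-force oracles
(exhaustive alignment enumeration to length 8, an exact 3-sequence MSA
lattice, per-column site counting, quadratic repeat scans, exhaustive
chain-subset search).  Statistical recovery uses 20 fixed seeds on
desk-scale genomes (~32 kb: LSC 18 kb, SSC 5 kb, IR 4.5 kb, 26 genes)
with indels disabled so the closed form applies exactly; estimates are
required to fall within per-seed 3σ binomial bands (at most one outlier
seed per partition, matching the expected excursion rate of sixty
independent 3σ draws) and to recover the rate ordering in ≥19/20 seeds.
The acceptance script runs the full-size default configuration.  The
desk-scale sizes are the package's choice for routine test turnaround;
the architecture and rates are identical to the full-size defaults.

## Known limitations

Aligned lengths of individual loci can differ by a few columns from
curated alignments, since manual adjustment is replaced by deterministic
alignment.  The reference marker table shipped with the package carries
three printed percentages that are arithmetically inconsistent with their
own printed counts; the loader exposes both printed and recomputed
columns and flags the discrepant rows.  Homolog matching requires
consistent gene naming across inputs; annotation synonyms must be
reconciled upstream.
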