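"""Synthetic quadripartite plastomes with known ground truth.

The generator builds an annotated ancestral genome with the canonical
LSC -> IRb -> SSC -> IRa architecture (about 157 kb by default: LSC 89 kb,
SSC 20 kb, IR 24 kb, 113 unique genes of which 18 are IR-duplicated,
~50% coding, 37% GC) and evolves it down a tree under Jukes-Cantor
substitutions with partition-specific rates plus short indels, recording
every event.  Each pipeline stage can therefore be checked against exact
truth: junction coordinates, spacer intervals, per-partition divergence.

Rates are expressed as expected substitutions per site per unit branch
length.  The default rates are calibrated so that, on the default 5-leaf
star tree, the *expected fraction of variable alignment columns* per
partition reproduces the heterogeneity observed across congeneric
plastomes — IR ~1.2%, coding ~2.3%, with single-copy non-coding DNA
fastest — via the closed form below.  The two IR copies are kept
byte-identical (substitutions sampled on IRb are mirrored into IRa;
indels never fall in the IR), emulating gene-conversion homogenization.

Closed form: on a star tree with ``n`` leaves and per-branch substitution
probability ``p`` per site, a column is variable unless all leaves agree:
``P(variable) = 1 - (1-p)^n - 3*(p/3)^n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

import dendropy

from .io import FeatureAnnotation, PlastomeError, PlastomeRecord

# partition codes over the ancestral (and evolving) genome
IR = 0
LSC_CODING = 1
LSC_NONCODING = 2
SSC_CODING = 3
SSC_NONCODING = 4
IR_MIRROR = 5  # the IRa copy: never sampled, receives mirrored IRb events

PARTITION_LABELS = {
    IR: "IR",
    LSC_CODING: "LSC_coding",
    LSC_NONCODING: "LSC_noncoding",
    SSC_CODING: "SSC_coding",
    SSC_NONCODING: "SSC_noncoding",
    IR_MIRROR: "IR",
}

_BASES = "ACGT"


def substitution_probability(d: float) -> float:
    """Jukes-Cantor probability that a site differs after distance ``d``."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def expected_column_variability(d: float, n_leaves: int) -> float:
    """Expected variable-column fraction on a star tree, branch length d."""
    p = substitution_probability(d)
    return 1.0 - (1.0 - p) ** n_leaves - 3.0 * (p / 3.0) ** n_leaves


def rate_for_column_variability(target: float, n_leaves: int) -> float:
    """Branch rate whose expected star-tree column variability is ``target``."""
    if not 0.0 <= target < 1.0:
        raise PlastomeError(f"target variability {target} out of range")
    if target == 0.0:
        return 0.0
    return float(
        brentq(
            lambda d: expected_column_variability(d, n_leaves) - target,
            1e-12,
            5.0,
            xtol=1e-12,
        )
    )


def default_rates(n_leaves: int = 5) -> dict[str, float]:
    """Per-partition rates targeting realistic column-variability levels.

    Targets (fraction of variable columns across the leaf set): IR 0.0121,
    coding 0.0230 in both single-copy regions, LSC non-coding 0.0358 and
    SSC non-coding 0.0554 — chosen so that with ~50% coding DNA the
    aggregate LSC and SSC variabilities land near 2.9% and 3.9%.
    """
    targets = {
        "IR": 0.0121,
        "LSC_coding": 0.0230,
        "LSC_noncoding": 0.0358,
        "SSC_coding": 0.0230,
        "SSC_noncoding": 0.0554,
    }
    return {
        k: rate_for_column_variability(v, n_leaves) for k, v in targets.items()
    }


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the reference condition."""

    seed: int = 0
    lsc_len: int = 89000
    ssc_len: int = 20400
    ir_len: int = 23700
    n_genes: int = 113  # unique genes
    n_ir_genes: int = 18  # subset duplicated through the IR
    n_ssc_genes: int = 12
    n_intron_genes: int = 11
    tree: str = "(A:1,B:1,C:1,D:1,E:1);"
    rates: dict[str, float] = field(default_factory=default_rates)
    indel_rate: float = 1e-4  # per single-copy site per unit branch length
    indel_mean_len: float = 3.0  # geometric
    ssr_seeds: tuple[tuple[str, int], ...] = (
        ("A", 12),
        ("A", 11),
        ("T", 10),
        ("AT", 7),
        ("AAG", 6),
    )
    gc: float = 0.37

    def __post_init__(self) -> None:
        for key, value in self.rates.items():
            if not 0.0 <= value <= 0.5:
                raise PlastomeError(f"rate {key}={value} outside [0, 0.5]")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Desk-scale variant (~30 kb) with the same architecture and rates."""
        defaults = dict(
            seed=seed,
            lsc_len=18000,
            ssc_len=5000,
            ir_len=4500,
            n_genes=26,
            n_ir_genes=4,
            n_ssc_genes=4,
            n_intron_genes=3,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class LeafTruth:
    """Everything that happened on the path from the ancestor to one leaf."""

    name: str
    # final-state substitutions vs the ancestor, in ancestral coordinates
    substitutions: list[tuple[int, str, str, str]] = field(default_factory=list)
    deleted: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    # (ancestral position after which the run sits, or -1 for a leading run)
    insertions: list[tuple[int, str]] = field(default_factory=list)
    junctions: dict[str, int] = field(default_factory=dict)
    length: int = 0


@dataclass
class SimulationTruth:
    ancestor: PlastomeRecord
    partition_codes: np.ndarray
    junctions: dict[str, int]
    gene_intervals: dict[str, tuple[int, int]]
    spacer_intervals: dict[str, tuple[int, int]]
    planted_ssrs: list[tuple[int, str, int]]  # (start, motif, unit_count)
    leaves: dict[str, LeafTruth] = field(default_factory=dict)
    _leaf_states: np.ndarray | None = None  # (n_leaves, n_anc), -1 = missing

    def realized_column_variability(self) -> dict[str, float]:
        """Fraction of ancestral sites with >=2 distinct leaf states.

        Computed per partition over sites present in at least two leaves;
        the IRa mirror copy is folded into IR so the duplication is not
        double-counted.  This is the simulation-side oracle the pipeline
        estimates should recover.
        """
        if self._leaf_states is None:
            raise PlastomeError("leaf states not recorded; run evolve() first")
        states = self._leaf_states
        present = states >= 0
        n_present = present.sum(axis=0)
        counts = np.stack([((states == b) & present).sum(axis=0) for b in range(4)])
        variable = (counts > 0).sum(axis=0) >= 2
        ok = n_present >= 2
        out: dict[str, float] = {}
        groups = {
            "IR": self.partition_codes == IR,  # IRb copy only
            "LSC": np.isin(self.partition_codes, (LSC_CODING, LSC_NONCODING)),
            "SSC": np.isin(self.partition_codes, (SSC_CODING, SSC_NONCODING)),
            "coding": np.isin(self.partition_codes, (LSC_CODING, SSC_CODING)),
            "noncoding": np.isin(
                self.partition_codes, (LSC_NONCODING, SSC_NONCODING)
            ),
        }
        for label, mask in groups.items():
            usable = mask & ok
            out[label] = (
                float(variable[usable].sum()) / float(usable.sum())
                if usable.any()
                else 0.0
            )
        return out


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=n, p=probs).astype(np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _encode_str(seq: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(_BASES)}
    return np.array([lut[c] for c in seq], dtype=np.int8)


def _build_region(
    rng: np.random.Generator,
    target_len: int,
    n_genes: int,
    name_prefix: str,
    start_index: int,
    gc: float,
    coding_code: int,
    noncoding_code: int,
    intron_genes: set[int],
) -> tuple[np.ndarray, np.ndarray, list[FeatureAnnotation], list[tuple[str, int, int]]]:
    """Assemble one region: alternating spacers and genes, exact length.

    Returns (sequence codes, partition codes, features, gene spans); all
    coordinates are region-local.
    """
    if n_genes == 0:
        seq = _random_bases(rng, target_len, gc)
        return seq, np.full(target_len, noncoding_code, np.int8), [], []
    mean_gene = max(120, int(0.5 * target_len / n_genes))
    gene_lens = rng.integers(
        max(90, int(0.6 * mean_gene)), int(1.4 * mean_gene), size=n_genes
    )
    gene_lens = (gene_lens // 3) * 3
    intron_lens = {
        g: int(rng.integers(150, 400)) for g in range(n_genes) if g in intron_genes
    }
    budget = target_len - int(gene_lens.sum()) - sum(intron_lens.values())
    if budget <= 30 * (n_genes + 1):
        raise PlastomeError(
            f"gene set too large for region of {target_len} bp"
        )
    cuts = np.sort(rng.integers(0, budget - 30 * (n_genes + 1), size=n_genes))
    spacer_lens = np.diff(np.concatenate(([0], cuts, [budget - 30 * (n_genes + 1)])))
    spacer_lens = spacer_lens + 30  # every spacer at least 30 bp

    seq_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    features: list[FeatureAnnotation] = []
    gene_spans: list[tuple[str, int, int]] = []
    pos = 0
    for g in range(n_genes):
        sp = int(spacer_lens[g])
        seq_parts.append(_random_bases(rng, sp, gc))
        code_parts.append(np.full(sp, noncoding_code, np.int8))
        pos += sp
        name = f"{name_prefix}{start_index + g:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        glen = int(gene_lens[g])
        if g in intron_lens:
            ilen = intron_lens[g]
            exon1 = glen // 2 // 3 * 3
            exon2 = glen - exon1
            intervals = [
                (pos, pos + exon1, strand),
                (pos + exon1 + ilen, pos + exon1 + ilen + exon2, strand),
            ]
            seq_parts.append(_random_bases(rng, glen + ilen, gc))
            codes = np.full(glen + ilen, coding_code, np.int8)
            codes[exon1 : exon1 + ilen] = noncoding_code
            code_parts.append(codes)
            span = (pos, pos + glen + ilen)
            pos += glen + ilen
        else:
            intervals = [(pos, pos + glen, strand)]
            seq_parts.append(_random_bases(rng, glen, gc))
            code_parts.append(np.full(glen, coding_code, np.int8))
            span = (pos, pos + glen)
            pos += glen
        features.append(
            FeatureAnnotation(name=name, kind="gene", intervals=[(span[0], span[1], strand)])
        )
        features.append(FeatureAnnotation(name=name, kind="CDS", intervals=intervals))
        gene_spans.append((name, span[0], span[1]))
    sp = int(spacer_lens[n_genes])
    seq_parts.append(_random_bases(rng, sp, gc))
    code_parts.append(np.full(sp, noncoding_code, np.int8))
    seq = np.concatenate(seq_parts)
    codes = np.concatenate(code_parts)
    assert len(seq) == target_len, (len(seq), target_len)
    return seq, codes, features, gene_spans


def build_ancestor(config: SimulationConfig) -> tuple[PlastomeRecord, SimulationTruth]:
    """Construct the annotated ancestral genome and its truth record."""
    rng = np.random.default_rng(config.seed)
    n_lsc_genes = config.n_genes - config.n_ir_genes - config.n_ssc_genes
    if n_lsc_genes < 0:
        raise PlastomeError("n_ir_genes + n_ssc_genes exceeds n_genes")
    intron_picks = set(
        rng.choice(max(n_lsc_genes, 1), size=min(config.n_intron_genes, n_lsc_genes), replace=False).tolist()
    )
    lsc_seq, lsc_codes, lsc_feats, lsc_spans = _build_region(
        rng, config.lsc_len, n_lsc_genes, "g", 1, config.gc,
        LSC_CODING, LSC_NONCODING, intron_picks,
    )
    irb_seq, irb_codes_raw, irb_feats, irb_spans = _build_region(
        rng, config.ir_len, config.n_ir_genes, "g", 1 + n_lsc_genes, config.gc,
        IR, IR, set(),
    )
    ssc_seq, ssc_codes, ssc_feats, ssc_spans = _build_region(
        rng, config.ssc_len, config.n_ssc_genes, "g",
        1 + n_lsc_genes + config.n_ir_genes, config.gc,
        SSC_CODING, SSC_NONCODING, set(),
    )
    irb_codes = np.full(config.ir_len, IR, np.int8)

    # plant SSR tracts into LSC spacers (recorded in truth)
    planted: list[tuple[int, str, int]] = []
    spacer_gaps = [
        (lsc_spans[i][2], lsc_spans[i + 1][1])
        for i in range(len(lsc_spans) - 1)
    ]
    big_gaps = [g for g in spacer_gaps if g[1] - g[0] >= 80]
    rng.shuffle(big_gaps)
    for (motif, count), gap in zip(config.ssr_seeds, big_gaps):
        tract = (motif * count)
        mid = (gap[0] + gap[1] - len(tract)) // 2
        lsc_seq[mid : mid + len(tract)] = _encode_str(tract)
        # break accidental extension on both sides
        for side in (mid - 1, mid + len(tract)):
            if 0 <= side < len(lsc_seq):
                choices = [b for b in range(4) if _BASES[b] != motif[0] and _BASES[b] != motif[-1]]
                lsc_seq[side] = int(rng.choice(choices))
        planted.append((mid, motif, count))

    # assemble LSC | IRb | SSC | IRa, IRa = revcomp(IRb)
    ira_seq = 3 - irb_seq[::-1]  # A<->T, C<->G under the ACGT coding
    offs = {
        "LSC": 0,
        "IRb": config.lsc_len,
        "SSC": config.lsc_len + config.ir_len,
        "IRa": config.lsc_len + config.ir_len + config.ssc_len,
    }
    n_total = offs["IRa"] + config.ir_len
    seq = np.concatenate([lsc_seq, irb_seq, ssc_seq, ira_seq])
    # guard bases: break reverse-complement symmetry just outside the IR so
    # the planted IR is exactly maximal and junctions are well-defined
    b0, b1 = offs["IRb"], offs["SSC"]
    a0 = offs["IRa"]
    if seq[b0 - 1] == 3 - seq[0]:  # outer pair: before IRb vs after IRa (origin)
        seq[b0 - 1] = int(next(c for c in range(4) if c != 3 - seq[0]))
    if seq[b1] == 3 - seq[a0 - 1]:  # inner pair: after IRb vs before IRa
        seq[b1] = int(next(c for c in range(4) if c != 3 - seq[a0 - 1]))
    codes = np.concatenate(
        [lsc_codes, irb_codes, ssc_codes, np.full(config.ir_len, IR_MIRROR, np.int8)]
    )

    def shift(feats: list[FeatureAnnotation], off: int) -> list[FeatureAnnotation]:
        out = []
        for f in feats:
            out.append(
                FeatureAnnotation(
                    name=f.name,
                    kind=f.kind,
                    intervals=[(s + off, e + off, st) for s, e, st in f.intervals],
                    copy_tag=f.copy_tag,
                )
            )
        return out

    features = shift(lsc_feats, offs["LSC"]) + shift(irb_feats, offs["IRb"]) + shift(
        ssc_feats, offs["SSC"]
    )
    # mirrored IRa copies of the IR genes
    ir_len = config.ir_len
    for f in irb_feats:
        intervals = []
        for s, e, st in f.intervals:
            ms, me = ir_len - e, ir_len - s
            intervals.append(
                (offs["IRa"] + ms, offs["IRa"] + me, "-" if st == "+" else "+")
            )
        intervals.sort()
        features.append(
            FeatureAnnotation(
                name=f.name, kind=f.kind, intervals=intervals, copy_tag="copy2"
            )
        )
    features.sort(key=lambda f: (f.start, f.kind, f.name))

    record = PlastomeRecord(
        identifier="ancestor",
        sequence=_codes_to_str(seq),
        features=features,
        is_circular=True,
    )
    junctions = {
        "JLB": offs["IRb"],
        "JSB": offs["SSC"],
        "JSA": offs["IRa"],
        "JLA": n_total,
    }
    gene_intervals = {
        name: (s + off, e + off)
        for spans, off in (
            (lsc_spans, offs["LSC"]),
            (irb_spans, offs["IRb"]),
            (ssc_spans, offs["SSC"]),
        )
        for name, s, e in spans
    }
    spacer_intervals: dict[str, tuple[int, int]] = {}
    for spans, off in (
        (lsc_spans, offs["LSC"]),
        (irb_spans, offs["IRb"]),
        (ssc_spans, offs["SSC"]),
    ):
        for (na, _, ea), (nb, sb, _) in zip(spans, spans[1:]):
            spacer_intervals[f"{na}-{nb}"] = (ea + off, sb + off)
    truth = SimulationTruth(
        ancestor=record,
        partition_codes=codes,
        junctions=junctions,
        gene_intervals=gene_intervals,
        spacer_intervals=spacer_intervals,
        planted_ssrs=[(p + offs["LSC"], m, c) for p, m, c in planted],
    )
    return record, truth


def _mirror_ir(seq: np.ndarray, codes: np.ndarray) -> None:
    """Overwrite the IRa copy with the reverse complement of IRb, in place."""
    irb = np.nonzero(codes == IR)[0]
    ira = np.nonzero(codes == IR_MIRROR)[0]
    if irb.size != ira.size:
        raise PlastomeError("IR copies out of sync")
    seq[ira] = (3 - seq[irb])[::-1]


def _evolve_branch(
    rng: np.random.Generator,
    seq: np.ndarray,
    codes: np.ndarray,
    anc_idx: np.ndarray,
    length: float,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One branch: JC substitutions at partition rates, then indels."""
    seq = seq.copy()
    rate_by_code = np.array(
        [
            config.rates["IR"],
            config.rates["LSC_coding"],
            config.rates["LSC_noncoding"],
            config.rates["SSC_coding"],
            config.rates["SSC_noncoding"],
            0.0,  # IRa mirror: receives IRb events by mirroring
        ]
    )
    p_site = 0.75 * (1.0 - np.exp(-4.0 * rate_by_code * length / 3.0))
    hit = rng.random(len(seq)) < p_site[codes]
    idx = np.nonzero(hit)[0]
    if idx.size:
        seq[idx] = (seq[idx] + 1 + rng.integers(0, 3, size=idx.size)) % 4
    _mirror_ir(seq, codes)

    if config.indel_rate > 0:
        single_copy = np.nonzero((codes != IR) & (codes != IR_MIRROR))[0]
        n_events = rng.binomial(single_copy.size, min(1.0, config.indel_rate * length))
        if n_events:
            positions = np.sort(rng.choice(single_copy, size=n_events, replace=False))[::-1]
            for pos in positions:
                ilen = int(rng.geometric(1.0 / config.indel_mean_len))
                if rng.random() < 0.5:  # deletion, clipped to the single-copy run
                    end = pos + ilen
                    run_end = pos
                    while run_end < len(seq) and run_end < end and codes[run_end] not in (IR, IR_MIRROR):
                        run_end += 1
                    seq = np.delete(seq, slice(pos, run_end))
                    codes = np.delete(codes, slice(pos, run_end))
                    anc_idx = np.delete(anc_idx, slice(pos, run_end))
                else:  # insertion
                    ins = _random_bases(rng, ilen, config.gc)
                    seq = np.insert(seq, pos, ins)
                    codes = np.insert(codes, pos, np.full(ilen, codes[pos]))
                    anc_idx = np.insert(anc_idx, pos, np.full(ilen, -1))
    return seq, codes, anc_idx


def evolve(
    ancestor: PlastomeRecord,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> tuple[list[PlastomeRecord], SimulationTruth]:
    """Evolve the ancestor down ``config.tree``; returns leaves and truth.

    Each leaf record carries lifted-over annotations; ``truth`` is filled
    with per-leaf event lists and the leaf-state matrix that backs
    :meth:`SimulationTruth.realized_column_variability`.
    """
    rng = np.random.default_rng(config.seed + 1)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    anc_seq = _encode_str(ancestor.sequence)
    n_anc = len(anc_seq)
    anc_idx0 = np.arange(n_anc, dtype=np.int64)

    leaves: list[PlastomeRecord] = []
    leaf_states: list[np.ndarray] = []
    leaf_names: list[str] = []

    def recurse(node, seq, codes, anc_idx):
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 1.0
            cseq, ccodes, cidx = _evolve_branch(rng, seq, codes, anc_idx, bl, config)
            if child.is_leaf():
                name = child.taxon.label if child.taxon else f"leaf{len(leaves)}"
                _finish_leaf(name, cseq, ccodes, cidx)
            else:
                recurse(child, cseq, ccodes, cidx)

    def _finish_leaf(name, seq, codes, anc_idx):
        mapped = anc_idx >= 0
        anc_positions = anc_idx[mapped]
        cur_positions = np.nonzero(mapped)[0]
        # final-state substitutions
        state = np.full(n_anc, -1, dtype=np.int8)
        state[anc_positions] = seq[cur_positions]
        subs = []
        diff = np.nonzero((state >= 0) & (state != anc_seq))[0]
        for pos in diff:
            subs.append(
                (
                    int(pos),
                    _BASES[anc_seq[pos]],
                    _BASES[state[pos]],
                    PARTITION_LABELS[int(truth.partition_codes[pos])],
                )
            )
        deleted = np.setdiff1d(np.arange(n_anc), anc_positions, assume_unique=True)
        insertions: list[tuple[int, str]] = []
        run_start = None
        for i in range(len(seq)):
            if anc_idx[i] < 0:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                prev_anc = int(anc_idx[run_start - 1]) if run_start > 0 else -1
                insertions.append(
                    (prev_anc, _codes_to_str(seq[run_start:i]))
                )
                run_start = None
        if run_start is not None:
            prev_anc = int(anc_idx[run_start - 1]) if run_start > 0 else -1
            insertions.append((prev_anc, _codes_to_str(seq[run_start:])))
        # lift junctions: current index of the first mapped site >= junction
        junctions = {
            jn: int(cur_positions[np.searchsorted(anc_positions, j)])
            if np.searchsorted(anc_positions, j) < len(anc_positions)
            else len(seq)
            for jn, j in truth.junctions.items()
        }
        features = _lift_features(ancestor.features, anc_positions, cur_positions)
        rec = PlastomeRecord(
            identifier=name,
            sequence=_codes_to_str(seq),
            features=features,
            is_circular=True,
        )
        leaves.append(rec)
        leaf_names.append(name)
        leaf_states.append(state)
        truth.leaves[name] = LeafTruth(
            name=name,
            substitutions=subs,
            deleted=deleted,
            insertions=insertions,
            junctions=junctions,
            length=len(seq),
        )

    recurse(tree.seed_node, anc_seq, truth.partition_codes.copy(), anc_idx0)
    truth._leaf_states = np.vstack(leaf_states) if leaf_states else None
    return leaves, truth


def _lift_features(
    features: list[FeatureAnnotation],
    anc_positions: np.ndarray,
    cur_positions: np.ndarray,
) -> list[FeatureAnnotation]:
    """Map ancestral feature intervals into leaf coordinates."""
    out = []
    for feat in features:
        intervals = []
        ok = True
        for s, e, st in feat.intervals:
            lo = np.searchsorted(anc_positions, s)
            hi = np.searchsorted(anc_positions, e)
            if lo >= hi:
                ok = False  # interval entirely deleted
                break
            intervals.append(
                (int(cur_positions[lo]), int(cur_positions[hi - 1]) + 1, st)
            )
        if ok:
            out.append(
                FeatureAnnotation(
                    name=feat.name,
                    kind=feat.kind,
                    intervals=intervals,
                    copy_tag=feat.copy_tag,
                )
            )
    return out


def reconstruct_leaf(ancestor_sequence: str, leaf: LeafTruth) -> str:
    """Replay a leaf's recorded events against the ancestor.

    Used as the truth-consistency check: the result must equal the leaf
    sequence byte-exactly.
    """
    n = len(ancestor_sequence)
    bases = list(ancestor_sequence)
    for pos, ref, alt, _ in leaf.substitutions:
        if bases[pos] != ref:
            raise PlastomeError(f"substitution ref mismatch at {pos}")
        bases[pos] = alt
    deleted = set(int(d) for d in leaf.deleted)
    ins_by_anchor: dict[int, list[str]] = {}
    for anchor, segment in leaf.insertions:
        ins_by_anchor.setdefault(anchor, []).append(segment)
    out: list[str] = []
    for segment in ins_by_anchor.get(-1, []):
        out.append(segment)
    for pos in range(n):
        if pos not in deleted:
            out.append(bases[pos])
        for segment in ins_by_anchor.get(pos, []):
            out.append(segment)
    return "".join(out)
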