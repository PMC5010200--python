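"""Alignment of homologous loci and whole plastome partitions.

Two layers:

* a deterministic global aligner (Needleman-Wunsch, linear gap penalty)
  extended to sequence-vs-profile alignment for progressive MSA of short,
  near-identical loci, and
* an anchor-chaining layer for whole partitions (tens of kb): k-mers that
  are unique in every genome and shared by all are chained co-linearly
  (MUM-style) and only the short inter-anchor gaps are passed to the
  progressive aligner.

Profile columns are scored by the summed pairwise substitution score
against the incoming residue (equivalent to mean scoring up to a constant
factor, but exact in integer arithmetic, which keeps tie-breaking
reproducible).  Traceback prefers diagonal over up over left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import PlastomeError

logger = logging.getLogger(__name__)

MATCH = 1
MISMATCH = -1
GAP = -2

_CODE = np.full(256, 4, dtype=np.int8)  # unknown -> N
for _i, _c in enumerate("ACGTN-"):
    _CODE[ord(_c)] = _i
_DECODE = np.frombuffer(b"ACGTN-", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _score_matrix(match: int, mismatch: int, gap: int) -> np.ndarray:
    s = np.full((6, 6), mismatch, dtype=np.int64)
    for i in range(4):
        s[i, i] = match
    s[4, :] = s[:, 4] = 0  # N is not a state: neutral against everything
    s[5, :] = s[:, 5] = gap
    s[5, 5] = 0
    return s


@dataclass
class MultipleAlignment:
    """Gapped rows over {A,C,G,T,N,-}, one per genome, equal length."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise PlastomeError("names/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PlastomeError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, index: int) -> str:
        return self.rows[index].replace("-", "")

    def codes(self) -> np.ndarray:
        """(n_rows, aligned_length) int8 matrix; A0 C1 G2 T3 N4 gap5."""
        if not self.rows:
            return np.zeros((0, 0), dtype=np.int8)
        return np.vstack([_encode(r) for r in self.rows])

    def ungapped_to_column(self, index: int) -> np.ndarray:
        """Column index of each ungapped position of row ``index``."""
        return np.nonzero(_encode(self.rows[index]) != 5)[0]


# ---------------------------------------------------------------------------
# Pairwise global alignment


def _nw_fill(sub: np.ndarray, gap_up: np.ndarray, gap_left: int) -> np.ndarray:
    """Fill the DP matrix.

    ``sub[i, j]``: score of pairing unit i of the vertical sequence with
    unit j of the horizontal one; ``gap_up[i]``: cost of consuming vertical
    unit i against a gap; ``gap_left``: cost of consuming one horizontal
    unit against a gap.  The within-row 'left' dependency is closed in
    vectorized form: F[i,j] = j*g + max_{k<=j}(cand[k] - k*g).
    """
    n, m = sub.shape
    F = np.empty((n + 1, m + 1), dtype=np.int64)
    jg = gap_left * np.arange(m + 1, dtype=np.int64)
    F[0] = jg
    cand = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        cand[0] = F[i - 1, 0] + gap_up[i - 1]
        np.maximum(F[i - 1, :-1] + sub[i - 1], F[i - 1, 1:] + gap_up[i - 1], out=cand[1:])
        F[i] = np.maximum.accumulate(cand - jg) + jg
    return F


def pairwise_nw(
    a: str,
    b: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
) -> tuple[str, str, int]:
    """Optimal global alignment of two sequences under a linear gap penalty.

    Returns ``(aligned_a, aligned_b, score)``.  Traceback is deterministic:
    on ties the diagonal move wins over up (gap in ``b``) which wins over
    left (gap in ``a``).
    """
    if not a or not b:
        raise PlastomeError("pairwise_nw requires non-empty sequences")
    ac, bc = _encode(a), _encode(b)
    S = _score_matrix(match, mismatch, gap)
    sub = S[ac[:, None], bc[None, :]]
    gap_up = np.full(len(ac), gap, dtype=np.int64)
    F = _nw_fill(sub, gap_up, gap)
    i, j = len(ac), len(bc)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + sub[i - 1, j - 1]:
            i, j = i - 1, j - 1
            out_a.append(a[i])
            out_b.append(b[j])
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            i -= 1
            out_a.append(a[i])
            out_b.append("-")
        else:
            j -= 1
            out_a.append("-")
            out_b.append(b[j])
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(F[-1, -1])


# ---------------------------------------------------------------------------
# Progressive MSA


def _align_seq_to_profile(
    profile: np.ndarray, seq: np.ndarray, S: np.ndarray, gap: int
) -> np.ndarray:
    """Align one encoded sequence to a profile (2-D code matrix).

    Returns the merged profile with one more row.  Existing profile columns
    are never reopened (once a gap, always a gap); new all-gap columns are
    inserted where the sequence demands them.
    """
    R, P = profile.shape
    m = len(seq)
    if P == 0:
        merged = np.full((R + 1, m), 5, dtype=np.int8)
        merged[R] = seq
        return merged
    if m == 0:
        merged = np.vstack([profile, np.full(P, 5, dtype=np.int8)])
        return merged
    counts = np.stack([(profile == c).sum(axis=0) for c in range(6)], axis=1)
    col_scores = counts @ S  # (P, 6) summed score of column vs each code
    sub = col_scores[:, seq]  # (P, m)
    gap_up = col_scores[:, 5]  # profile column vs gap in sequence
    gap_left = R * gap  # new all-gap column vs sequence residue
    F = _nw_fill(sub, gap_up, gap_left)
    i, j = P, m
    cols: list[np.ndarray] = []
    gapcol = np.full(R + 1, 5, dtype=np.int8)
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + sub[i - 1, j - 1]:
            i, j = i - 1, j - 1
            cols.append(np.append(profile[:, i], seq[j]))
        elif i > 0 and F[i, j] == F[i - 1, j] + gap_up[i - 1]:
            i -= 1
            cols.append(np.append(profile[:, i], np.int8(5)))
        else:
            j -= 1
            col = gapcol.copy()
            col[R] = seq[j]
            cols.append(col)
    return np.stack(cols[::-1], axis=1)


def progressive_msa(
    sequences: list[tuple[str, str]],
    guide: list[int] | None = None,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
) -> MultipleAlignment:
    """Progressive multiple alignment of named sequences.

    Sequences join a growing profile in guide order — by default decreasing
    length, ties broken by name — so long, information-rich sequences shape
    the profile first.  Rows of the result follow the input order.
    """
    if len(sequences) < 2:
        raise PlastomeError("progressive_msa needs at least two sequences")
    S = _score_matrix(match, mismatch, gap)
    if guide is None:
        guide = sorted(
            range(len(sequences)),
            key=lambda i: (-len(sequences[i][1]), sequences[i][0]),
        )
    profile = _encode(sequences[guide[0]][1]).reshape(1, -1)
    for idx in guide[1:]:
        profile = _align_seq_to_profile(profile, _encode(sequences[idx][1]), S, gap)
    # profile row r holds sequence guide[r]; restore input order
    inv = np.empty(len(guide), dtype=int)
    for r, idx in enumerate(guide):
        inv[idx] = r
    rows = [_decode(profile[inv[i]]) for i in range(len(sequences))]
    return MultipleAlignment(names=[name for name, _ in sequences], rows=rows)


# ---------------------------------------------------------------------------
# Anchor chaining


@dataclass
class Anchor:
    positions: tuple[int, ...]  # start in each sequence
    length: int


@dataclass
class AnchorChain:
    anchors: list[Anchor] = field(default_factory=list)
    n_seqs: int = 0


def build_anchor_chain(seqs: list[str], k: int = 31) -> AnchorChain:
    """Chain k-mers unique in every sequence and shared by all.

    Candidate anchors are merged when they continue each other on the same
    offset, then the heaviest strictly co-linear, non-overlapping subset is
    selected by length-weighted longest-increasing-subsequence.
    """
    n_seqs = len(seqs)
    if n_seqs < 2:
        raise PlastomeError("anchor chaining needs at least two sequences")
    maps: list[dict[str, int]] = []
    for s in seqs:
        first: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if km in first:
                dup.add(km)
            else:
                first[km] = i
        maps.append({km: i for km, i in first.items() if km not in dup})
    shared = set(maps[0]).intersection(*maps[1:]) if maps else set()
    if not shared:
        return AnchorChain(anchors=[], n_seqs=n_seqs)
    cands = sorted(tuple(m[km] for m in maps) for km in shared)

    merged: list[Anchor] = []
    for pos in cands:
        if merged:
            last = merged[-1]
            delta = pos[0] - last.positions[0]
            if 0 < delta <= last.length and all(
                pos[g] - last.positions[g] == delta for g in range(1, n_seqs)
            ):
                last.length = delta + k
                continue
        merged.append(Anchor(positions=pos, length=k))

    pos = np.array([a.positions for a in merged], dtype=np.int64)
    lens = np.array([a.length for a in merged], dtype=np.int64)
    r = len(merged)
    best = np.zeros(r, dtype=np.int64)
    parent = np.full(r, -1, dtype=np.int64)
    for j in range(r):
        ok = np.nonzero((pos[:j] + lens[:j, None] <= pos[j]).all(axis=1))[0]
        if ok.size:
            i = ok[np.argmax(best[ok])]
            best[j] = best[i] + lens[j]
            parent[j] = i
        else:
            best[j] = lens[j]
    j = int(np.argmax(best))
    chain: list[Anchor] = []
    while j >= 0:
        chain.append(merged[j])
        j = int(parent[j])
    chain.reverse()
    return AnchorChain(anchors=chain, n_seqs=n_seqs)


def _align_segment(
    names: list[str],
    parts: list[str],
    match: int,
    mismatch: int,
    gap: int,
) -> list[str]:
    """Align one inter-anchor segment; returns one gapped string per genome."""
    if all(p == parts[0] for p in parts):
        return list(parts)
    nonempty = [p for p in parts if p]
    if len(nonempty) == 1:
        width = len(nonempty[0])
        return [p if p else "-" * width for p in parts]
    msa = progressive_msa(
        list(zip(names, parts)), match=match, mismatch=mismatch, gap=gap
    )
    return msa.rows


def align_partition(
    sequences: list[tuple[str, str]],
    k: int = 31,
    max_gap: int = 20000,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
) -> MultipleAlignment:
    """Anchored co-linear alignment of one partition across genomes.

    Anchors become runs of identical columns; the inter-anchor gaps are
    aligned progressively.  An inter-anchor gap longer than ``max_gap``
    aborts with an error suggesting the partitions be checked — syntenic
    plastome partitions never diverge that much.
    """
    names = [name for name, _ in sequences]
    seqs = [seq for _, seq in sequences]
    chain = build_anchor_chain(seqs, k=k)
    if not chain.anchors:
        if max(len(s) for s in seqs) > max_gap:
            raise PlastomeError(
                "no shared anchors in long sequences; check that inputs "
                "come from the same partition"
            )
        logger.warning("no anchors found; falling back to progressive MSA")
        return progressive_msa(sequences, match=match, mismatch=mismatch, gap=gap)

    pieces: list[list[str]] = [[] for _ in seqs]
    prev_end = [0] * len(seqs)
    for anchor in chain.anchors:
        parts = [seqs[g][prev_end[g] : anchor.positions[g]] for g in range(len(seqs))]
        if max(len(p) for p in parts) > max_gap:
            raise PlastomeError(
                f"inter-anchor gap exceeds {max_gap} bp; check partition inputs"
            )
        if any(parts):
            aligned = _align_segment(names, parts, match, mismatch, gap)
            for g, row in enumerate(aligned):
                pieces[g].append(row)
        block = seqs[0][anchor.positions[0] : anchor.positions[0] + anchor.length]
        for g in range(len(seqs)):
            pieces[g].append(block)
            prev_end[g] = anchor.positions[g] + anchor.length
    tails = [seqs[g][prev_end[g] :] for g in range(len(seqs))]
    if any(tails):
        if max(len(t) for t in tails) > max_gap:
            raise PlastomeError(
                f"inter-anchor gap exceeds {max_gap} bp; check partition inputs"
            )
        aligned = _align_segment(names, tails, match, mismatch, gap)
        for g, row in enumerate(aligned):
            pieces[g].append(row)
    rows = ["".join(p) for p in pieces]
    return MultipleAlignment(names=names, rows=rows)
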