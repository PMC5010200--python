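"""Quadripartite structure detection.

Land-plant plastomes carry two identical inverted-repeat copies (IRa/IRb)
separating a large and a small single-copy region (LSC/SSC).  This module
finds the maximal exact inverted duplication in a circular sequence and
partitions the genome into canonical LSC -> IRb -> SSC -> IRa order.

IR equality is exact: the two copies are homogenized by gene conversion in
real plastomes, and the detector extends seed matches until the first
mismatch.  Detection works in "match space" between the sequence S and its
reverse complement R: an inverted duplication corresponds to a run of
forward matches S[p+i] == R[q+i] along one diagonal, so maximal runs on
diagonals are exactly the maximal inverted repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import PlastomeError, PlastomeRecord, revcomp, reverse_complement_record, rotate_record

Interval = tuple[int, int]  # (start, end) 0-based half-open; end may exceed n (wrap)


class StructureNotFoundError(PlastomeError):
    """No inverted duplication of the required length: non-quadripartite genome."""


def _circular_overlap(s1: int, l1: int, s2: int, l2: int, n: int) -> bool:
    """Do two circular arcs overlap?"""
    for a_start, a_len, b_start, b_len in ((s1, l1, s2, l2), (s2, l2, s1, l1)):
        off = (b_start - a_start) % n
        if off < a_len:
            return True
    return False


def detect_inverted_repeat(
    sequence: str, min_len: int = 1000, k: int = 31
) -> tuple[Interval, Interval]:
    """Find the maximal pair of disjoint, exactly reverse-complementary arcs.

    Parameters
    ----------
    sequence:
        Circular DNA over A/C/G/T/N.
    min_len:
        Minimum repeat length to accept; the default of 1000 bp skips small
        dispersed palindromes so only the genome-scale IR qualifies.
    k:
        Seed k-mer size (capped at ``min_len``).

    Returns the two arm intervals ordered by start coordinate; an interval
    whose end exceeds the sequence length wraps the origin.  Ties on length
    are broken by the smaller start coordinate.

    Raises :class:`StructureNotFoundError` when no inverted duplication of
    at least ``min_len`` exists.
    """
    seq = sequence.upper()
    n = len(seq)
    if n <= 2 * min_len:
        raise PlastomeError(
            f"sequence length {n} too short for min_len {min_len}"
        )
    k = min(k, min_len)
    rc = revcomp(seq)

    kmer_pos: dict[str, list[int]] = {}
    for q in range(n - k + 1):
        kmer_pos.setdefault(rc[q : q + k], []).append(q)

    stride = max(1, (min_len - k) // 2)
    max_occ = 50  # skip hyper-repetitive seeds (SSR tracts)
    covered: dict[int, list[tuple[int, int]]] = {}  # diagonal -> p-runs seen
    hits: list[tuple[int, int, int]] = []  # (p0, q0, length) runs in match space

    def _extend(p: int, q: int) -> tuple[int, int, int]:
        # maximal run through (p, q) with circular indexing; capped at n
        back = 0
        while back < n and seq[(p - back - 1) % n] == rc[(q - back - 1) % n]:
            back += 1
        fwd = k
        while back + fwd < n and seq[(p + fwd) % n] == rc[(q + fwd) % n]:
            fwd += 1
        return (p - back) % n, (q - back) % n, back + fwd

    for p in range(0, n, stride):
        candidates = kmer_pos.get(seq[p : p + k])
        if not candidates or len(candidates) > max_occ:
            continue
        for q in candidates:
            d = (p - q) % n
            runs = covered.setdefault(d, [])
            off = p  # position along the diagonal, parameterized by p
            if any(
                (off - r0) % n < rl for r0, rl in runs
            ):
                continue
            p0, q0, length = _extend(p, q)
            runs.append((p0, length))
            if length >= min_len:
                hits.append((p0, q0, length))

    best: tuple[int, int, Interval, Interval] | None = None
    for p0, q0, length in hits:
        # arm in S coordinates: S[p0 : p0+length] (circular)
        # partner: R[q0 : q0+length] == revcomp(S[n-q0-length : n-q0])
        s1 = p0
        s2 = (n - q0 - length) % n
        if _circular_overlap(s1, length, s2, length, n):
            continue  # self-overlapping palindrome, not a two-copy IR
        a, b = sorted((s1, s2))
        i1: Interval = (a, a + length)
        i2: Interval = (b, b + length)
        key = (-length, a, b)
        if best is None or key < (-best[0], best[2][0], best[3][0]):
            best = (length, p0, i1, i2)
    if best is None:
        raise StructureNotFoundError(
            f"no inverted duplication >= {min_len} bp found"
        )
    return best[2], best[3]


@dataclass
class QuadripartiteStructure:
    """Canonical quadripartite partition of one genome.

    All coordinates refer to ``record``, the genome rotated (and possibly
    reverse-complemented) into canonical LSC -> IRb -> SSC -> IRa order.
    ``junctions`` holds the four boundary positions JLB (LSC/IRb),
    JSB (IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC, == genome length, i.e.
    the origin).  IRa is the copy that abuts the origin / LSC start.
    """

    record: PlastomeRecord
    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    ir_length: int
    junctions: dict[str, int]
    reversed_input: bool = False
    rotation_offset: int = 0

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    def region_of(self, position: int) -> str:
        n = self.record.length
        position %= n
        for name, (s, e) in (
            ("LSC", self.lsc),
            ("IRb", self.irb),
            ("SSC", self.ssc),
            ("IRa", self.ira),
        ):
            if s <= position < e:
                return name
        raise PlastomeError(f"position {position} outside genome")

    def region_of_interval(self, start: int, end: int) -> tuple[str, bool]:
        """Region holding the majority of [start, end), plus a
        spans-junction flag.  ``end`` may exceed the genome length to
        denote an origin-wrapping interval."""
        n = self.record.length
        pieces = [(start, end)] if end <= n else [(start, n), (0, end - n)]
        overlaps: dict[str, int] = {}
        for name, (s, e) in (
            ("LSC", self.lsc),
            ("IRb", self.irb),
            ("SSC", self.ssc),
            ("IRa", self.ira),
        ):
            ov = sum(max(0, min(pe, e) - max(ps, s)) for ps, pe in pieces)
            if ov:
                overlaps[name] = ov
        if not overlaps:
            raise PlastomeError(f"interval ({start}, {end}) outside genome")
        best = max(overlaps, key=lambda r: (overlaps[r], r))
        return best, len(overlaps) > 1

    def partition_sequence(self, name: str) -> str:
        iv = {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}[
            name
        ]
        return self.record.sequence[iv[0] : iv[1]]


def partition_genome(
    record: PlastomeRecord,
    ir: tuple[Interval, Interval] | None = None,
    min_len: int = 1000,
) -> QuadripartiteStructure:
    """Partition a genome into LSC/IRb/SSC/IRa given (or detecting) its IR.

    The two arcs between the IR copies are labelled LSC (longer) and SSC
    (shorter); the genome is rotated so the LSC starts at position 0.  Of
    the two strand orientations the one whose canonical sequence is
    lexicographically smaller is emitted (forward wins ties), which makes
    the output a pure function of the circular molecule rather than of the
    arbitrary rotation/strand the input file happened to use.
    """
    n = record.length
    if ir is None:
        ir = detect_inverted_repeat(record.sequence, min_len=min_len)
    (s1, e1), (s2, e2) = ir
    l1, l2 = e1 - s1, e2 - s2
    if l1 != l2:
        raise PlastomeError("IR copies must have equal length")
    if _circular_overlap(s1 % n, l1, s2 % n, l2, n):
        raise PlastomeError("IR intervals overlap")
    ir_len = l1
    # arcs between the copies (circular)
    gap_after_1 = (s2 - e1) % n
    gap_after_2 = (s1 - e2) % n
    if gap_after_1 + gap_after_2 + 2 * ir_len != n:
        raise PlastomeError("IR intervals do not tile the genome with two arcs")
    # choose LSC = longer arc
    if gap_after_1 >= gap_after_2:
        lsc_start, lsc_len = e1 % n, gap_after_1
        ssc_len = gap_after_2
    else:
        lsc_start, lsc_len = e2 % n, gap_after_2
        ssc_len = gap_after_1

    def canonical(rec: PlastomeRecord, lsc_start_: int) -> PlastomeRecord:
        return rotate_record(rec, lsc_start_)

    fwd = canonical(record, lsc_start)
    # mirror coordinates for the reverse-complement orientation: the LSC is
    # the same arc read on the other strand; its start maps to n - (lsc_start
    # + lsc_len) ... i.e. revcomp then rotate to that arc's start.
    rc_rec = reverse_complement_record(record)
    rc_lsc_start = (n - lsc_start - lsc_len) % n
    rev = canonical(rc_rec, rc_lsc_start)
    if rev.sequence < fwd.sequence:
        chosen, reversed_input, offset = rev, True, rc_lsc_start
    else:
        chosen, reversed_input, offset = fwd, False, lsc_start

    lsc = (0, lsc_len)
    irb = (lsc_len, lsc_len + ir_len)
    ssc = (lsc_len + ir_len, lsc_len + ir_len + ssc_len)
    ira = (lsc_len + ir_len + ssc_len, n)
    seq = chosen.sequence
    if seq[irb[0] : irb[1]] != revcomp(seq[ira[0] : ira[1]]):
        raise PlastomeError("IR copies are not exact reverse complements")
    junctions = {"JLB": lsc[1], "JSB": irb[1], "JSA": ssc[1], "JLA": n}
    return QuadripartiteStructure(
        record=chosen,
        lsc=lsc,
        irb=irb,
        ssc=ssc,
        ira=ira,
        ir_length=ir_len,
        junctions=junctions,
        reversed_input=reversed_input,
        rotation_offset=offset,
    )
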