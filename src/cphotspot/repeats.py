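"""Repeat census: microsatellites, tandem repeats and palindromes.

All three detectors report *perfect* (exact-match) repeats under explicit
thresholds:

* SSRs: maximal tracts of a 1-6 bp motif, with minimum complete unit
  counts of 10 for mono-, 6 for di- and 5 for tri- through hexanucleotide
  motifs; a tract is reported once, under its smallest generating unit.
* Tandem repeats: maximal runs of a unit of at least ``min_size`` bp
  (default 10) occurring at least twice adjacently; unit lengths let hits
  be binned 10-20 / 20-30 / >30 bp.
* Palindromes: pairs of exactly reverse-complementary arms separated by a
  spacer of at most 2 kb; arms above ``max_arm`` (default 1 kb) are
  excluded so the genome-scale inverted repeat does not drown the census
  of dispersed palindromes.

Absolute repeat counts are algorithm-sensitive (seed sizes, mismatch
tolerance); these exact-match rules are stated so results are exactly
reproducible, and cross-program count comparisons should be qualitative.
N bases break all tracts and arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import revcomp

DEFAULT_SSR_MINIMA = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

TANDEM_BINS = ((10, 20), (20, 30), (30, None))


@dataclass(frozen=True)
class RepeatHit:
    kind: str  # ssr | tandem | palindrome
    start: int  # 0-based half-open; tract for ssr/tandem, first arm for palindrome
    end: int
    unit: str = ""  # canonical motif (ssr) / repeat unit (tandem)
    unit_count: int = 0
    arm_length: int = 0  # palindrome only
    spacer_length: int = 0  # palindrome only
    arm2_start: int = -1  # palindrome only

    def validate(self, sequence: str) -> bool:
        """Re-check the defining property against the source sequence.

        Hits from a circular scan may extend past the sequence end; the
        sequence is doubled transparently in that case.
        """
        src = sequence if self.end <= len(sequence) else sequence + sequence
        if self.kind == "palindrome":
            arm1 = src[self.start : self.start + self.arm_length]
            arm2 = src[self.arm2_start : self.arm2_start + self.arm_length]
            return arm2 == revcomp(arm1)
        u = len(self.unit)
        tract = src[self.start : self.end]
        return len(tract) >= 2 * u and all(
            tract[i] == tract[i - u] for i in range(u, len(tract))
        )


def _codes(sequence: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    return lut[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]


def _match_runs(arr: np.ndarray, u: int) -> list[tuple[int, int]]:
    """Maximal runs of positions i with arr[i] == arr[i+u], both unambiguous.

    Returns (run_start, run_length) pairs; a run of length r corresponds to
    a period-``u`` stretch of r + u characters.
    """
    if len(arr) <= u:
        return []
    eq = (arr[u:] == arr[:-u]) & (arr[u:] >= 0) & (arr[:-u] >= 0)
    padded = np.concatenate(([False], eq, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e - s)) for s, e in zip(edges[::2], edges[1::2])]


def _has_smaller_period(sequence: str, start: int, end: int, u: int) -> bool:
    """Does the stretch [start, end) have period d for a proper divisor d of u?

    A stretch of length >= 2u with any period p < u also has period
    gcd(p, u) (Fine and Wilf), so checking divisors is exhaustive here.
    """
    stretch = sequence[start:end]
    for d in range(1, u):
        if u % d == 0 and all(
            stretch[i] == stretch[i - d] for i in range(d, len(stretch))
        ):
            return True
    return False


def canonical_unit(motif: str) -> str:
    """Lexicographically smallest rotation of the motif (strand kept)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(
    sequence: str,
    minima: dict[int, int] | None = None,
    circular: bool = False,
) -> list[RepeatHit]:
    """Maximal perfect microsatellite tracts meeting per-class unit minima.

    The tract spans the full maximal period-``u`` stretch (a trailing
    partial unit extends the tract but not the unit count); tracts whose
    motif is itself periodic are reported only under the smaller unit.
    """
    minima = DEFAULT_SSR_MINIMA if minima is None else minima
    seq = sequence.upper()
    n = len(seq)
    scan = seq + seq[: max(minima) * (max(minima.values()) + 1)] if circular else seq
    arr = _codes(scan)
    hits: list[RepeatHit] = []
    for u, min_count in sorted(minima.items()):
        for run_start, run_len in _match_runs(arr, u):
            start, end = run_start, run_start + run_len + u
            if circular and start >= n:
                continue
            count = (end - start) // u
            if count < min_count:
                continue
            if _has_smaller_period(scan, start, end, u):
                continue
            hits.append(
                RepeatHit(
                    kind="ssr",
                    start=start,
                    end=end,
                    unit=canonical_unit(scan[start : start + u]),
                    unit_count=count,
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.end, h.unit))


def find_tandem_repeats(
    sequence: str,
    min_size: int = 10,
    max_unit: int = 1000,
    circular: bool = False,
) -> list[RepeatHit]:
    """Maximal exact tandem repeats with unit length >= ``min_size``.

    A hit requires at least two adjacent copies of the unit; ``max_unit``
    bounds the unit lengths scanned.
    """
    seq = sequence.upper()
    n = len(seq)
    scan = seq + seq[: 2 * max_unit] if circular else seq
    arr = _codes(scan)
    hits: list[RepeatHit] = []
    for u in range(min_size, min(max_unit, len(scan) // 2) + 1):
        for run_start, run_len in _match_runs(arr, u):
            if run_len < u:  # fewer than two complete adjacent copies
                continue
            start, end = run_start, run_start + run_len + u
            if circular and start >= n:
                continue
            if _has_smaller_period(scan, start, end, u):
                continue
            hits.append(
                RepeatHit(
                    kind="tandem",
                    start=start,
                    end=end,
                    unit=scan[start : start + u],
                    unit_count=(end - start) // u,
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.end, len(h.unit)))


def tandem_bin(unit_length: int) -> str:
    """Histogram bin label for a tandem unit length: 10-20, 20-30 or >30."""
    if unit_length <= 20:
        return "10-20"
    if unit_length <= 30:
        return "20-30"
    return ">30"


def find_palindromes(
    sequence: str,
    min_arm: int = 10,
    max_spacer: int = 2000,
    max_arm: int = 1000,
    circular: bool = False,
) -> list[RepeatHit]:
    """Pairs of maximal exactly reverse-complementary arms.

    Arms are maximal on both ends (extending either arm in either
    direction breaks reverse-complementarity), at least ``min_arm`` long,
    separated by 0..``max_spacer`` bp, and non-overlapping.  Maximal arms
    longer than ``max_arm`` are dropped: that is the genome-scale IR, not a
    dispersed repeat.
    """
    seq = sequence.upper()
    n0 = len(seq)
    scan = seq + seq[: max_spacer + 2 * max_arm] if circular else seq
    n = len(scan)
    rc = revcomp(scan)
    k = min_arm
    if n < 2 * k:
        return []
    kmer_pos: dict[str, list[int]] = {}
    for q in range(n - k + 1):
        kmer_pos.setdefault(rc[q : q + k], []).append(q)
    lo = n - max_spacer - 2 * max_arm
    hi = n - 2 * min_arm
    covered: dict[int, list[tuple[int, int]]] = {}
    hits: set[RepeatHit] = set()
    for p in range(n - k + 1):
        candidates = kmer_pos.get(scan[p : p + k])
        if not candidates:
            continue
        for q in candidates:
            if not lo <= p + q <= hi:
                continue
            d = p - q
            runs = covered.setdefault(d, [])
            if any(r0 <= p < r0 + rl for r0, rl in runs):
                continue
            back = 0
            while (
                p - back - 1 >= 0
                and q - back - 1 >= 0
                and scan[p - back - 1] == rc[q - back - 1]
            ):
                back += 1
            fwd = k
            while p + fwd < n and q + fwd < n and scan[p + fwd] == rc[q + fwd]:
                fwd += 1
            p0, q0, length = p - back, q - back, back + fwd
            runs.append((p0, length))
            if length < min_arm or length > max_arm:
                continue
            j0 = n - q0 - length  # start of the partner arm in scan coords
            a1, a2 = sorted((p0, j0))
            spacer = a2 - (a1 + length)
            if spacer < 0 or spacer > max_spacer:
                continue
            if circular and a1 >= n0:
                continue
            hits.add(
                RepeatHit(
                    kind="palindrome",
                    start=a1,
                    end=a2 + length,
                    arm_length=length,
                    spacer_length=spacer,
                    arm2_start=a2,
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.arm2_start, h.arm_length))
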