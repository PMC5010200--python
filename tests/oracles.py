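"""Independent brute-force oracles used by the test suite.

Every function here re-derives a quantity from its definition by plain
enumeration, deliberately avoiding the package's own code paths (no shared
DP, no numpy vectorization), so agreement is evidence of correctness
rather than of shared bugs.
"""

from __future__ import annotations

from itertools import combinations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Alignment


def nw_score_bruteforce(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> int:
    """Optimal global alignment score by enumerating aligned-pair subsets.

    Under a linear gap penalty an alignment is fully described by the
    order-preserving set of matched index pairs; every unmatched character
    costs one gap.  Enumerates all subset pairs (feasible up to ~length 8).
    """
    n, m = len(a), len(b)
    best = gap * (n + m)  # align nothing
    for k in range(1, min(n, m) + 1):
        for ii in combinations(range(n), k):
            for jj in combinations(range(m), k):
                s = sum(
                    (match if a[i] == b[j] else mismatch) for i, j in zip(ii, jj)
                )
                s += gap * (n + m - 2 * k)
                if s > best:
                    best = s
    return best


def msa3_optimal_sp_score(
    seqs: list[str], match: int = 1, mismatch: int = -1, gap: int = -2
) -> int:
    """Exact 3-sequence MSA by dynamic programming over the 3-D lattice,
    maximizing the sum-of-pairs score.  Tractable for sequences <= ~12 bp."""
    assert len(seqs) == 3
    a, b, c = seqs

    def pair(x: str, y: str) -> int:
        if x == "-" and y == "-":
            return 0
        if x == "-" or y == "-":
            return gap
        return match if x == y else mismatch

    def col_score(x: str, y: str, z: str) -> int:
        return pair(x, y) + pair(x, z) + pair(y, z)

    NEG = -(10**9)
    F = [
        [[NEG] * (len(c) + 1) for _ in range(len(b) + 1)]
        for _ in range(len(a) + 1)
    ]
    F[0][0][0] = 0
    moves = [
        (1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 1),
    ]
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            for k in range(len(c) + 1):
                cur = F[i][j][k]
                if cur == NEG:
                    continue
                for di, dj, dk in moves:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni > len(a) or nj > len(b) or nk > len(c):
                        continue
                    col = col_score(
                        a[i] if di else "-", b[j] if dj else "-", c[k] if dk else "-"
                    )
                    if cur + col > F[ni][nj][nk]:
                        F[ni][nj][nk] = cur + col
    return F[len(a)][len(b)][len(c)]


def msa_sp_score(
    rows: list[str], match: int = 1, mismatch: int = -1, gap: int = -2
) -> int:
    """Sum-of-pairs score of a given alignment."""
    total = 0
    for x, y in combinations(rows, 2):
        for cx, cy in zip(x, y):
            if cx == "-" and cy == "-":
                continue
            if cx == "-" or cy == "-":
                total += gap
            elif cx == cy:
                total += match
            else:
                total += mismatch
    return total


# ---------------------------------------------------------------------------
# Site counting


def site_counts_bruteforce(rows: list[str]) -> tuple[int, int, int, int]:
    """(constant, variable, pic, excluded) by per-column set arithmetic."""
    n_const = n_var = n_pic = n_excl = 0
    for col in zip(*rows):
        bases = [ch for ch in col if ch in "ACGT"]
        if len(bases) < 2:
            n_excl += 1
            continue
        states = set(bases)
        if len(states) >= 2:
            n_var += 1
        else:
            n_const += 1
        if sum(1 for s in states if bases.count(s) >= 2) >= 2:
            n_pic += 1
    return n_const, n_var, n_pic, n_excl


# ---------------------------------------------------------------------------
# Repeats


def _valid(ch: str) -> bool:
    return ch in "ACGT"


def ssrs_bruteforce(seq: str, minima: dict[int, int]) -> set[tuple[int, int, int]]:
    """Set of (start, end, unit_len) maximal SSR tracts meeting the minima."""
    out = set()
    n = len(seq)
    for u, min_count in minima.items():
        i = 0
        while i < n:
            if not _valid(seq[i]):
                i += 1
                continue
            # maximal period-u stretch starting at i (i must be a stretch start)
            if i > 0 and i + u <= n and _valid(seq[i - 1]) and seq[i - 1] == seq[i - 1 + u]:
                i += 1
                continue
            j = i + u
            while j < n and _valid(seq[j]) and seq[j] == seq[j - u]:
                j += 1
            if not all(_valid(seq[t]) for t in range(i, min(j, i + u, n))):
                i += 1
                continue
            if j - i >= u and (j - i) // u >= min_count:
                # smallest generating unit: no proper divisor period
                smaller = False
                for d in range(1, u):
                    if u % d == 0 and all(
                        seq[t] == seq[t - d] for t in range(i + d, j)
                    ):
                        smaller = True
                        break
                if not smaller:
                    out.add((i, j, u))
            i += 1
    return out


def tandems_bruteforce(seq: str, min_size: int, max_unit: int) -> set[tuple[int, int, int]]:
    """Set of (start, end, unit_len) maximal tandem repeats (>=2 copies)."""
    out = set()
    n = len(seq)
    for u in range(min_size, min(max_unit, n // 2) + 1):
        i = 0
        while i < n:
            if i > 0 and i + u <= n and _valid(seq[i - 1]) and _valid(seq[i - 1 + u]) and seq[i - 1] == seq[i - 1 + u]:
                i += 1
                continue
            j = i + u
            while j < n and _valid(seq[j]) and _valid(seq[j - u]) and seq[j] == seq[j - u]:
                j += 1
            if j - i >= 2 * u and all(_valid(seq[t]) for t in range(i, min(j, i + u))):
                smaller = False
                for d in range(1, u):
                    if u % d == 0 and all(
                        seq[t] == seq[t - d] for t in range(i + d, j)
                    ):
                        smaller = True
                        break
                if not smaller:
                    out.add((i, j, u))
            i += 1
    return out


def palindromes_bruteforce(
    seq: str, min_arm: int, max_spacer: int, max_arm: int
) -> set[tuple[int, int, int]]:
    """Set of (arm1_start, arm2_start, arm_length) maximal palindrome pairs.

    Quadratic scan of the match matrix between the sequence and its
    reverse complement; maximal diagonal runs are read off by checking the
    cells just before and after each run.
    """
    n = len(seq)
    rc = revcomp(seq)

    def m(p: int, q: int) -> bool:
        return (
            0 <= p < n and 0 <= q < n and _valid(seq[p]) and seq[p] == rc[q]
        )

    out = set()
    for p in range(n):
        for q in range(n):
            if not m(p, q) or m(p - 1, q - 1):
                continue  # not the start of a maximal run
            length = 0
            while m(p + length, q + length):
                length += 1
            if not (min_arm <= length <= max_arm):
                continue
            j = n - q - length
            a1, a2 = min(p, j), max(p, j)
            spacer = a2 - (a1 + length)
            if 0 <= spacer <= max_spacer:
                out.add((a1, a2, length))
    return out


def inverted_repeat_exists_bruteforce(seq: str, min_len: int) -> bool:
    """Any pair of disjoint intervals of length >= min_len that are exact
    reverse complements?  O(n^2 * L) scan, fine for ~200 bp."""
    n = len(seq)
    for i in range(n - min_len + 1):
        arm = revcomp(seq[i : i + min_len])
        j = seq.find(arm)
        while j != -1:
            if j >= i + min_len or i >= j + min_len:
                return True
            j = seq.find(arm, j + 1)
    return False


def best_colinear_chain_bruteforce(
    anchors: list[tuple[tuple[int, ...], int]]
) -> int:
    """Max total anchor length over all strictly co-linear, non-overlapping
    subsets, by exhaustive subset enumeration (<= ~15 anchors)."""
    best = 0
    m = len(anchors)
    for mask in range(1, 1 << m):
        subset = [anchors[i] for i in range(m) if mask >> i & 1]
        subset.sort(key=lambda a: a[0][0])
        ok = True
        for (pa, la), (pb, _) in zip(subset, subset[1:]):
            if any(pa[g] + la > pb[g] for g in range(len(pa))):
                ok = False
                break
        if ok:
            total = sum(l for _, l in subset)
            if total > best:
                best = total
    return best
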