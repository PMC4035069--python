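"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exact rationals, exhaustive
enumeration, full scans) and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# --- two-library exact count test ----------------------------------------

def ac_pmf(k: int, x: int, n1: int, n2: int) -> Fraction:
    """Exact conditional probability of the second count being k."""
    q = Fraction(n2, n1)
    return q**k * comb(x + k, k) / (1 + q) ** (x + k + 1)


def ac_two_sided(x: int, y: int, n1: int, n2: int) -> Fraction:
    lower = sum(ac_pmf(k, x, n1, n2) for k in range(0, y + 1))
    upper = 1 - sum(ac_pmf(k, x, n1, n2) for k in range(0, y))
    return min(Fraction(1), 2 * min(lower, upper))


def ac_pmf_equal_depths(k: int, x: int) -> Fraction:
    """Closed form at N1 = N2: C(x+k, x) / 2^(x+k+1)."""
    return Fraction(comb(x + k, x), 2 ** (x + k + 1))


# --- hypergeometric upper tail -------------------------------------------

def hypergeom_enum(N: int, n: int, M: int, m: int) -> Fraction:
    """P(X >= m) by enumerating all C(N, n) target subsets."""
    total = 0
    hits = 0
    for subset in combinations(range(N), n):
        total += 1
        if sum(1 for g in subset if g < M) >= m:
            hits += 1
    return Fraction(hits, total)


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg by the definition: q_i = min_{j: p_j >= p_i} p_j * n / rank_j."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * n / rank)
        q[i] = running
    return q


# --- RNA structure enumeration -------------------------------------------

_CANONICAL = {"AT", "TA", "GC", "CG", "GT", "TG"}


def enumerate_structures(seq: str, min_loop: int = 3) -> list[frozenset]:
    """All nested pair sets with loop >= min_loop and canonical pairs."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple:
        if i >= j:
            return (frozenset(),)
        out = list(structs(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in _CANONICAL:
                for a in structs(i + 1, k - 1):
                    for b in structs(k + 1, j):
                        out.append(a | b | {(i, k)})
        return tuple(out)

    return list(structs(0, n - 1))


# --- string scans ---------------------------------------------------------

def naive_genome_hits(tag: str, genome: dict[str, str], max_mismatch: int = 0,
                      ) -> list[tuple[str, int, str]]:
    """Full scan of every position on both strands."""
    hits = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        for query, strand in ((tag, "+"), (naive_revcomp(tag), "-")):
            for start in range(0, len(seq) - len(query) + 1):
                mm = sum(1 for a, b in zip(seq[start : start + len(query)], query) if a != b)
                if mm <= max_mismatch:
                    hits.append((chrom, start, strand))
    hits.sort()
    return hits


def naive_seed_sites(mirna: str, utr: str) -> list[int]:
    """All positions where the seed (miRNA 2-8) reverse complement occurs."""
    seq = mirna.upper().replace("U", "T")
    motif = naive_revcomp(seq[1:8])
    utr = utr.upper().replace("U", "T")
    return [i for i in range(len(utr) - 6) if utr[i : i + 7] == motif]
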