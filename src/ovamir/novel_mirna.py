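"""Novel miRNA prediction from unannotated tags.

Unannotated tags with genomic hits seed candidate precursor windows; each
window is folded with a nearest-neighbour stack-energy dynamic program
and kept only when it shows a stable hairpin with the supporting reads
sitting on one stem arm and sharing a homogeneous 5' end (the signature
of precise Dicer cleavage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import revcomp
from .references import feature_type

MIN_LOOP = 3

# canonical pairs on the DNA alphabet (U folded onto T); strengths scale
# pair and stacking contributions with Turner-like ordering GC > AU > GU
_PAIR_STRENGTH = {"GC": 1.5, "CG": 1.5, "AT": 1.0, "TA": 1.0, "GT": 0.5, "TG": 0.5}
_PAIR_WEIGHT = 1.0
_STACK_WEIGHT = 0.8
_INF = float("inf")


def pair_energy(a: str, b: str) -> float:
    s = _PAIR_STRENGTH.get(a + b)
    return -_PAIR_WEIGHT * s if s is not None else _INF


def stack_energy(outer: str, inner: str) -> float:
    """Stacking bonus for adjacent pairs (outer on top of inner)."""
    return -_STACK_WEIGHT * (_PAIR_STRENGTH[outer] + _PAIR_STRENGTH[inner])


def can_pair(a: str, b: str) -> bool:
    return a + b in _PAIR_STRENGTH


def structure_energy(seq: str, pairs: Sequence[tuple[int, int]]) -> float:
    """Energy of an explicit structure: pair terms plus stacking bonuses
    for each directly nested adjacent pair.  Shared with the enumeration
    oracle in the tests."""
    pair_set = set(pairs)
    total = 0.0
    for i, j in pairs:
        total += pair_energy(seq[i], seq[j])
        if (i + 1, j - 1) in pair_set:
            total += stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1])
    return total


def fold_sequence(sequence: str) -> tuple[str, float]:
    """Minimum-energy nested structure (dot-bracket, energy).

    Model: every canonical pair (i, j) with j - i > ``MIN_LOOP`` scores a
    pair energy; directly stacked pairs add a stacking bonus.  Exact
    dynamic program with deterministic traceback (prefer leaving the last
    base unpaired, then the leftmost bifurcation, then stacking).
    """
    seq = sequence.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValueError(f"invalid characters in sequence: {sorted(set(seq) - set('ACGT'))}")
    n = len(seq)
    if n == 0:
        return "", 0.0

    # E[i][j]: best energy for seq[i..j]; P[i][j]: best given (i, j) paired.
    # Backpointers are recorded during the fill so the traceback never has
    # to re-derive a choice from rounded floats.
    E = [[0.0] * n for _ in range(n)]
    P = [[_INF] * n for _ in range(n)]
    p_stacked = [[False] * n for _ in range(n)]
    e_choice = [[-1] * n for _ in range(n)]  # -1: j unpaired; else bifurcation k
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can_pair(seq[i], seq[j]):
                best = E[i + 1][j - 1] if j - 1 >= i + 1 else 0.0
                if P[i + 1][j - 1] < _INF:
                    stacked = P[i + 1][j - 1] + stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1])
                    if stacked < best:
                        best = stacked
                        p_stacked[i][j] = True
                P[i][j] = pair_energy(seq[i], seq[j]) + best
            best = E[i][j - 1]
            choice = -1
            for k in range(i, j - MIN_LOOP):
                if P[k][j] < _INF:
                    cand = (E[i][k - 1] if k > i else 0.0) + P[k][j]
                    if cand < best:
                        best = cand
                        choice = k
            E[i][j] = best
            e_choice[i][j] = choice

    structure = ["."] * n
    stack: list[tuple[int, int, bool]] = [(0, n - 1, False)]  # (i, j, paired)
    while stack:
        i, j, paired = stack.pop()
        if j <= i:
            continue
        if not paired:
            k = e_choice[i][j]
            if k == -1:
                if E[i][j] < 0.0:
                    stack.append((i, j - 1, False))
                continue
            if k > i:
                stack.append((i, k - 1, False))
            stack.append((k, j, True))
            continue
        structure[i], structure[j] = "(", ")"
        if j - 1 >= i + 1:
            stack.append((i + 1, j - 1, p_stacked[i][j]))
    return "".join(structure), E[0][n - 1]


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    partners = [-1] * len(structure)
    opens: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            opens.append(i)
        elif c == ")":
            if not opens:
                raise ValueError("unbalanced structure")
            j = opens.pop()
            partners[i], partners[j] = j, i
    if opens:
        raise ValueError("unbalanced structure")
    return partners


@dataclass
class SupportTag:
    tag: str
    count_lib1: int
    count_lib2: int
    local_start: int  # 5' position in window-oriented coordinates

    @property
    def count(self) -> int:
        return self.count_lib1 + self.count_lib2


@dataclass
class PrecursorWindow:
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # oriented 5'->3' on `strand`
    support: list[SupportTag] = field(default_factory=list)


@dataclass
class HairpinCandidate:
    chrom: str
    start: int          # genomic, 0-based half-open, precursor span
    end: int
    strand: str
    precursor: str      # oriented 5'->3'
    structure: str
    energy_score: float
    mature_seq: str
    mature_local: tuple[int, int]   # within precursor
    star_local: tuple[int, int]
    support: list[SupportTag]
    flags: dict[str, bool]

    @property
    def passes(self) -> bool:
        return all(self.flags.values())

    @property
    def count_lib1(self) -> int:
        return sum(t.count_lib1 for t in self.support)

    @property
    def count_lib2(self) -> int:
        return sum(t.count_lib2 for t in self.support)


def extract_candidates(tag_hits: Sequence[tuple[str, int, int, Sequence[tuple[str, int, str]]]],
                       genome: Mapping[str, str], flank: int = 70,
                       max_loci: int = 15) -> list[PrecursorWindow]:
    """Candidate precursor windows around unannotated tags.

    ``tag_hits`` rows: (tag, count_lib1, count_lib2, genome hits).  Tags
    hitting more than ``max_loci`` positions are treated as repeats and
    dropped; overlapping windows on the same chromosome and strand merge.
    """
    raw: list[tuple[str, int, int, str, str, int, int, int]] = []
    for tag, c1, c2, hits in tag_hits:
        if len(hits) == 0 or len(hits) > max_loci:
            continue
        for chrom, start, strand in hits:
            chrom_len = len(genome[chrom])
            w_start = max(0, start - flank)
            w_end = min(chrom_len, start + len(tag) + flank)
            raw.append((chrom, strand, tag, c1, c2, start, w_start, w_end))

    windows: list[PrecursorWindow] = []
    raw.sort(key=lambda r: (r[0], r[1], r[6], r[7]))
    for chrom, strand, tag, c1, c2, t_start, w_start, w_end in raw:
        if windows and windows[-1].chrom == chrom and windows[-1].strand == strand \
                and w_start <= windows[-1].end:
            windows[-1].end = max(windows[-1].end, w_end)
        else:
            windows.append(PrecursorWindow(chrom, w_start, w_end, strand, ""))
        windows[-1].support.append(SupportTag(tag, c1, c2, t_start))  # genomic for now

    for w in windows:
        forward = genome[w.chrom][w.start : w.end]
        w.sequence = forward if w.strand == "+" else revcomp(forward)
        for s in w.support:
            if w.strand == "+":
                s.local_start = s.local_start - w.start
            else:  # 5' end of a minus-strand read sits at the genomic 3' edge
                s.local_start = w.end - (s.local_start + len(s.tag))
    return windows


def find_star_arm(sequence: str, m_start: int, m_end: int,
                  max_mismatch: int = 3) -> tuple[int, int, int] | None:
    """Best near-reverse-complement of the mature arm elsewhere in the
    window: (start, end, mismatches) of the star arm, or None.

    Candidate positions must not overlap the mature arm and must leave a
    loop gap of at least MIN_LOOP nt; ties break toward the closest locus.
    """
    mature = sequence[m_start:m_end]
    probe = revcomp(mature)
    m = len(probe)
    best: tuple[int, int, int] | None = None  # (mismatches, distance, start)
    for start in range(0, len(sequence) - m + 1):
        end = start + m
        if end + MIN_LOOP > m_start and start < m_end + MIN_LOOP:
            continue  # overlaps the mature arm or leaves no loop
        mm = sum(1 for a, b in zip(sequence[start:end], probe) if a != b)
        if mm > max_mismatch:
            continue
        distance = start - m_end if start >= m_end else m_start - end
        key = (mm, distance, start)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[2] + m, best[0]


def call_novel(windows: Sequence[PrecursorWindow], features: pd.DataFrame | None = None,
               energy_max: float = -18.0, pair_fraction: float = 0.6,
               dicer_fraction: float = 0.7, mature_length: tuple[int, int] = (20, 24),
               min_precursor: int = 60, max_precursor: int = 120,
               star_max_mismatch: int = 3,
               keep_failed: bool = False) -> list[HairpinCandidate]:
    """Evaluate hairpin criteria on candidate windows.

    A candidate passes when: the supporting reads' modal 5' end carries at
    least ``dicer_fraction`` of the support; the modal read (the mature
    arm) is ``mature_length`` nt; a star arm (near reverse complement of
    the mature arm) exists across a >= 3 nt loop, and in the fold of the
    star-arm alignment at least ``pair_fraction`` of the mature bases are
    complementary; the precursor folds at or below ``energy_max``; and
    the locus overlaps no annotated feature.
    """
    out: list[HairpinCandidate] = []
    for w in windows:
        total = sum(t.count for t in w.support)
        if total == 0:
            continue
        by_5p: dict[int, int] = {}
        for t in w.support:
            by_5p[t.local_start] = by_5p.get(t.local_start, 0) + t.count
        modal_5p = min((p for p in by_5p), key=lambda p: (-by_5p[p], p))
        dicer_ok = by_5p[modal_5p] / total >= dicer_fraction
        mature_tag = min((t for t in w.support if t.local_start == modal_5p),
                         key=lambda t: (-t.count, t.tag))
        m_start, m_end = modal_5p, modal_5p + len(mature_tag.tag)
        length_ok = mature_length[0] <= len(mature_tag.tag) <= mature_length[1]

        star = find_star_arm(w.sequence, m_start, m_end, star_max_mismatch)
        flags = {"dicer": dicer_ok, "mature_length": length_ok, "star_arm": star is not None}
        if star is None:
            if not keep_failed:
                continue
            pairing_ok = False
            star_span = (m_end, m_end)
            pre_lo, pre_hi = m_start, m_end
            pre_struct, energy = "", 0.0
        else:
            star_lo, star_hi, star_mm = star
            pairing_ok = (len(mature_tag.tag) - star_mm) / len(mature_tag.tag) >= pair_fraction
            loop_len = star_lo - m_end if star_lo >= m_end else m_start - star_hi
            flags["loop"] = loop_len >= MIN_LOOP
            lo = min(m_start, star_lo)
            hi = max(m_end, star_hi)
            pre_lo = max(0, lo - 5)
            pre_hi = min(len(w.sequence), hi + 5)
            while pre_hi - pre_lo < min_precursor and (pre_lo > 0 or pre_hi < len(w.sequence)):
                if pre_lo > 0:
                    pre_lo -= 1
                if pre_hi < len(w.sequence) and pre_hi - pre_lo < min_precursor:
                    pre_hi += 1
            precursor = w.sequence[pre_lo:pre_hi]
            flags["precursor_size"] = min_precursor <= len(precursor) <= max_precursor
            pre_struct, energy = fold_sequence(precursor)
            flags["energy"] = energy <= energy_max
            star_span = (star_lo - pre_lo, star_hi - pre_lo)
        flags["pairing"] = pairing_ok

        # genomic coordinates of the precursor span
        if w.strand == "+":
            g_start, g_end = w.start + pre_lo, w.start + pre_hi
        else:
            g_start, g_end = w.end - pre_hi, w.end - pre_lo
        if features is not None and len(features):
            overlap = features[(features["chrom"] == w.chrom)
                               & (features["start"] < g_end) & (features["end"] > g_start)]
            flags["unannotated"] = len(overlap) == 0
        cand = HairpinCandidate(
            chrom=w.chrom, start=g_start, end=g_end, strand=w.strand,
            precursor=w.sequence[pre_lo:pre_hi] if star is not None else "",
            structure=pre_struct, energy_score=energy,
            mature_seq=mature_tag.tag,
            mature_local=(m_start - pre_lo, m_end - pre_lo),
            star_local=star_span, support=list(w.support), flags=flags)
        if cand.passes or keep_failed:
            out.append(cand)
    return out


def merge_candidates_by_locus(candidates: Sequence[HairpinCandidate],
                              ) -> list[HairpinCandidate]:
    """Collapse candidates whose precursor spans overlap on the same
    chromosome (e.g. the two strand orientations of one hairpin), keeping
    the one with the most read support, then the lower energy."""
    ranked = sorted(candidates,
                    key=lambda c: (-(c.count_lib1 + c.count_lib2), c.energy_score,
                                   c.chrom, c.start))
    kept: list[HairpinCandidate] = []
    for cand in ranked:
        if any(k.chrom == cand.chrom and k.start < cand.end and cand.start < k.end
               for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: (c.chrom, c.start))
    return kept


def candidates_to_bed(candidates: Sequence[HairpinCandidate]) -> pd.DataFrame:
    rows = [
        {"chrom": c.chrom, "start": c.start, "end": c.end,
         "name": f"novel:{i + 1}", "score": c.count_lib1 + c.count_lib2,
         "strand": c.strand}
        for i, c in enumerate(candidates)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def candidates_to_table(candidates: Sequence[HairpinCandidate]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(candidates):
        rows.append({
            "candidate_id": f"novel-{i + 1}", "chrom": c.chrom, "start": c.start,
            "end": c.end, "strand": c.strand, "mature": c.mature_seq,
            "precursor": c.precursor, "structure": c.structure,
            "energy": round(c.energy_score, 2),
            "count_lib1": c.count_lib1, "count_lib2": c.count_lib2,
            "passes": c.passes,
        })
    return pd.DataFrame(rows, columns=["candidate_id", "chrom", "start", "end", "strand",
                                       "mature", "precursor", "structure", "energy",
                                       "count_lib1", "count_lib2", "passes"])
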