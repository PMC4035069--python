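"""Known-miRNA expression counting and expression-set calling.

Tags annotated as known miRNA are credited to their closest mature
reference (small mismatch / end-offset tolerance, deterministic tie
break), giving per-library counts per miRNA; miRNAs are then split into
co-expressed and library-specific sets.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import rna_to_dna

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 2
DEFAULT_MAX_OFFSET = 2


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _align(tag: str, mature: str, offset: int) -> int | None:
    """Mismatch count aligning tag position k to mature position k+offset."""
    lo = max(0, -offset)
    hi = min(len(tag), len(mature) - offset)
    if hi <= lo:
        return None
    return sum(1 for k in range(lo, hi) if tag[k] != mature[k + offset])


def match_tag_to_matures(tag: str, mature: Mapping[str, str],
                         max_mismatch: int = DEFAULT_MAX_MISMATCH,
                         max_offset: int = DEFAULT_MAX_OFFSET,
                         ) -> tuple[str, int, int] | None:
    """Best mature match for a tag: (mirna_id, mismatches, 5'-offset).

    A candidate alignment shifts the tag 5' end by ``offset`` relative to
    the mature 5' end; both end offsets must stay within ``max_offset``
    and mismatches over the overlap within ``max_mismatch``.  Ties break
    by (mismatches, |5' offset| + |3' offset|, id).
    """
    best: tuple[int, int, str] | None = None
    for mid, mseq in mature.items():
        mseq = rna_to_dna(mseq)
        if tag == mseq:
            return (mid, 0, 0)  # exact match beats everything
        for offset in range(-max_offset, max_offset + 1):
            off3 = (offset + len(tag)) - len(mseq)
            if abs(off3) > max_offset:
                continue
            mm = _align(tag, mseq, offset)
            if mm is None or mm > max_mismatch:
                continue
            key = (mm, abs(offset) + abs(off3), mid)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    mm, _, mid = best
    # recover the winning offset for reporting
    for offset in range(-max_offset, max_offset + 1):
        mseq = rna_to_dna(mature[mid])
        if _align(tag, mseq, offset) == mm and abs((offset + len(tag)) - len(mseq)) <= max_offset:
            return (mid, mm, offset)
    return (mid, mm, 0)


class MatureMatcher:
    """Vectorised drop-in for :func:`match_tag_to_matures`.

    Groups matures by length into byte matrices so each (length, offset)
    pair is one numpy comparison; picks the same (mismatches,
    offset-penalty, id) minimum as the scalar reference implementation.
    """

    def __init__(self, mature: Mapping[str, str],
                 max_mismatch: int = DEFAULT_MAX_MISMATCH,
                 max_offset: int = DEFAULT_MAX_OFFSET) -> None:
        self.max_mismatch = max_mismatch
        self.max_offset = max_offset
        self.mature_dna = {mid: rna_to_dna(seq) for mid, seq in mature.items()}
        self.exact: dict[str, str] = {}
        for mid, seq in sorted(self.mature_dna.items()):
            self.exact.setdefault(seq, mid)
        self._by_length: dict[int, tuple[list[str], np.ndarray]] = {}
        for length in sorted({len(s) for s in self.mature_dna.values()}):
            ids = sorted(m for m, s in self.mature_dna.items() if len(s) == length)
            mat = np.frombuffer("".join(self.mature_dna[m] for m in ids).encode(),
                                dtype=np.uint8).reshape(len(ids), length)
            self._by_length[length] = (ids, mat)

    def match(self, tag: str) -> tuple[str, int, int] | None:
        if tag in self.exact:
            return (self.exact[tag], 0, 0)
        tag_arr = np.frombuffer(tag.encode(), dtype=np.uint8)
        nt = len(tag)
        best: tuple[int, int, str, int] | None = None
        for length, (ids, mat) in self._by_length.items():
            for offset in range(-self.max_offset, self.max_offset + 1):
                off3 = (offset + nt) - length
                if abs(off3) > self.max_offset:
                    continue
                lo = max(0, -offset)
                hi = min(nt, length - offset)
                if hi <= lo:
                    continue
                mism = (mat[:, lo + offset : hi + offset] != tag_arr[lo:hi]).sum(axis=1)
                for row in np.nonzero(mism <= self.max_mismatch)[0]:
                    key = (int(mism[row]), abs(offset) + abs(off3), ids[row], offset)
                    if best is None or key[:3] < best[:3]:
                        best = key
        if best is None:
            return None
        return (best[2], best[0], best[3])


def assign_tags_to_mirnas(tag_table: pd.DataFrame, mature: Mapping[str, str],
                          max_mismatch: int = DEFAULT_MAX_MISMATCH,
                          max_offset: int = DEFAULT_MAX_OFFSET,
                          category_column: str = "category",
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Credit each known-miRNA tag to exactly one miRNA.

    Returns (expression table, list of tags reassigned to unann because no
    mature lies within tolerance).  The expression table has one row per
    miRNA with any credited tag: mirna_id, sequence, count_lib1, count_lib2.
    """
    matcher = MatureMatcher(mature, max_mismatch, max_offset)
    mature_dna = matcher.mature_dna
    counts: dict[str, list[int]] = {}
    unassigned: list[str] = []
    sub = tag_table[tag_table[category_column] == "known_miRNA"]
    for _, row in sub.iterrows():
        tag = row["tag"]
        hit = matcher.match(tag)
        if hit is None:
            unassigned.append(tag)
            logger.warning("known_miRNA tag without mature within tolerance: %s", tag)
            continue
        mid = hit[0]
        acc = counts.setdefault(mid, [0, 0])
        acc[0] += int(row["count_lib1"])
        acc[1] += int(row["count_lib2"])
    rows = [
        {"mirna_id": mid, "sequence": mature_dna[mid],
         "count_lib1": c1, "count_lib2": c2}
        for mid, (c1, c2) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "sequence", "count_lib1", "count_lib2"]), unassigned


def call_expression_sets(records: pd.DataFrame) -> pd.DataFrame:
    """Label each detected miRNA co_expressed / specific_lib1 / specific_lib2.

    Specific = zero count in exactly one library; the three sets partition
    the detected miRNAs (rows with both counts zero are absent upstream).
    """
    out = records.copy()

    def label(row) -> str:
        c1, c2 = row["count_lib1"], row["count_lib2"]
        if c1 > 0 and c2 > 0:
            return "co_expressed"
        if c1 > 0:
            return "specific_lib1"
        if c2 > 0:
            return "specific_lib2"
        raise ValueError(f"undetected miRNA in expression table: {row['mirna_id']}")

    out["expression_set"] = out.apply(label, axis=1)
    return out


def top_specific_report(records: pd.DataFrame, clean_total_lib1: int,
                        clean_total_lib2: int, threshold: int = 1000,
                        ) -> dict[str, pd.DataFrame]:
    """Library-specific miRNAs with raw count above ``threshold``.

    One table per library, sorted by normalized expression descending;
    the displayed std is the TPM value rounded half away from zero.
    """
    from .diffexpr import normalize_tpm

    labelled = call_expression_sets(records)
    out: dict[str, pd.DataFrame] = {}
    for lib, (count_col, total) in {
        "lib1": ("count_lib1", clean_total_lib1),
        "lib2": ("count_lib2", clean_total_lib2),
    }.items():
        sub = labelled[(labelled["expression_set"] == f"specific_{lib}")
                       & (labelled[count_col] > threshold)].copy()
        sub["std"] = [round_half_away(normalize_tpm(c, total)) for c in sub[count_col]]
        sub = sub.sort_values("std", ascending=False, kind="mergesort")
        out[lib] = sub[["mirna_id", count_col, "std"]].reset_index(drop=True)
    return out
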