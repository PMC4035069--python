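"""Raw-read cleaning with per-category accounting.

Reads are screened in a fixed order -- low quality, 3'-adapter absent,
empty insert, 5'-adapter contamination, length < 18 nt, polyA -- and each
read is charged to the first category it fails, so the category counts
plus the clean reads always add back up to the high-quality total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import read_fastq

#: Removal categories in report (and screening) order.
REMOVAL_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminants",
    "shorter_than_18nt",
    "polyA",
)

DEFAULT_QUALITY_THRESHOLD = 20.0
DEFAULT_MIN_OVERLAP = 6
DEFAULT_MIN_INSERT = 18
DEFAULT_MAX_INSERT = 30
POLYA_FRACTION = 0.8


@dataclass
class FilterReport:
    """Per-library read-removal accounting.

    Invariant: ``high_quality == clean_reads + sum(removals)``.
    """

    total_reads: int = 0
    high_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminants: int = 0
    shorter_than_18nt: int = 0
    polyA: int = 0
    clean_reads: int = 0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")

    @classmethod
    def from_counts(cls, high_quality: int, removals: Sequence[int],
                    total_reads: int | None = None) -> "FilterReport":
        """Build a report from a high-quality total and the five removal
        counts (report order); clean reads follow from the identity."""
        if len(removals) != len(REMOVAL_CATEGORIES):
            raise ValueError(f"expected {len(REMOVAL_CATEGORIES)} removal counts")
        clean = high_quality - sum(removals)
        kwargs = dict(zip(REMOVAL_CATEGORIES, removals))
        return cls(total_reads=total_reads if total_reads is not None else high_quality,
                   high_quality=high_quality, clean_reads=clean, **kwargs)

    def check(self) -> None:
        removed = sum(getattr(self, c) for c in REMOVAL_CATEGORIES)
        if self.high_quality != self.clean_reads + removed:
            raise AssertionError("FilterReport accounting identity violated")

    def percentages(self) -> dict[str, float]:
        """Category percentages relative to high-quality reads, 2 decimals."""
        if self.high_quality == 0:
            return {c: 0.0 for c in ("high_quality", *REMOVAL_CATEGORIES, "clean_reads")}
        out = {"high_quality": 100.0}
        for c in (*REMOVAL_CATEGORIES, "clean_reads"):
            out[c] = round(100.0 * getattr(self, c) / self.high_quality, 2)
        return out

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [("total_reads", self.total_reads, "")]
        for c in ("high_quality", *REMOVAL_CATEGORIES, "clean_reads"):
            rows.append((c, getattr(self, c), f"{pct[c]:.2f}%"))
        return pd.DataFrame(rows, columns=["type", "count", "percent"])


def mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)


def _adapter_matches_at(seq: str, adapter: str, start: int, min_overlap: int) -> bool:
    """Some overlap length L >= min_overlap has <= L // 10 mismatches."""
    max_overlap = min(len(adapter), len(seq) - start)
    if max_overlap < min_overlap:
        return False
    mismatches = 0
    for length in range(1, max_overlap + 1):
        if seq[start + length - 1] != adapter[length - 1]:
            mismatches += 1
        if length >= min_overlap and mismatches <= length // 10:
            return True
    return False


def find_adapter3(seq: str, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> int | None:
    """Locate the 3' adapter; returns the insert length (adapter start).

    Best match = leftmost start where the read/adapter overlap is at least
    ``min_overlap`` nt with at most 1 mismatch per 10 nt of overlap.
    """
    if not adapter:
        raise ValueError("empty 3' adapter")
    # fast path: leftmost exact occurrence of the adapter head bounds the scan
    head = adapter[: max(min_overlap, min(10, len(adapter)))]
    exact = seq.find(head)
    n = len(seq)
    limit = exact if exact != -1 else n - min_overlap + 1
    for start in range(0, limit):
        if _adapter_matches_at(seq, adapter, start, min_overlap):
            return start
    return exact if exact != -1 else None


def has_adapter5_prefix(insert: str, adapter5: str, min_len: int = 8,
                        max_mismatch: int = 1) -> bool:
    """True if the insert begins with a >=min_len prefix of the 5' adapter
    (at most ``max_mismatch`` substitutions over the first ``min_len`` nt)."""
    if len(insert) < min_len or len(adapter5) < min_len:
        return False
    mismatches = sum(1 for a, b in zip(insert[:min_len], adapter5[:min_len]) if a != b)
    return mismatches <= max_mismatch


def is_polya(insert: str, fraction: float = POLYA_FRACTION) -> bool:
    return bool(insert) and insert.count("A") / len(insert) >= fraction


def classify_insert(insert: str, adapter5: str,
                    min_insert: int = DEFAULT_MIN_INSERT) -> str | None:
    """Post-trimming screen; returns a removal category or None if clean."""
    if not insert:
        return "insert_null"
    if has_adapter5_prefix(insert, adapter5):
        return "adapter5_contaminants"
    if len(insert) < min_insert:
        return "shorter_than_18nt"
    if is_polya(insert):
        return "polyA"
    return None


def filter_inserts(tags: Iterable[str], adapter5: str,
                   min_insert: int = DEFAULT_MIN_INSERT) -> tuple[list[str], Counter]:
    """Re-screen already-trimmed inserts (idempotent on clean output)."""
    kept: list[str] = []
    removed: Counter = Counter()
    for tag in tags:
        cat = classify_insert(tag, adapter5, min_insert)
        if cat is None:
            kept.append(tag)
        else:
            removed[cat] += 1
    return kept, removed


def clean_reads(fastq_path: str | Path, adapter3: str, adapter5: str,
                quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
                min_overlap: int = DEFAULT_MIN_OVERLAP,
                min_insert: int = DEFAULT_MIN_INSERT) -> tuple[list[str], FilterReport]:
    """Clean one FASTQ library; returns (clean insert list, FilterReport).

    The insert list keeps one entry per surviving read (multiplicity
    preserved), already adapter-trimmed.
    """
    report = FilterReport()
    tags: list[str] = []
    for read in read_fastq(fastq_path):
        report.total_reads += 1
        if "N" in read.seq or mean_quality(read.qual) < quality_threshold:
            continue  # low quality: excluded from the high-quality pool
        report.high_quality += 1
        pos = find_adapter3(read.seq, adapter3, min_overlap)
        if pos is None:
            report.adapter3_null += 1
            continue
        insert = read.seq[:pos]
        cat = classify_insert(insert, adapter5, min_insert)
        if cat is None:
            report.clean_reads += 1
            tags.append(insert)
        else:
            setattr(report, cat, getattr(report, cat) + 1)
    report.check()
    return tags, report


def length_distribution(tags: Iterable[str]) -> dict[int, tuple[int, float]]:
    """Read-weighted length histogram: length -> (count, fraction)."""
    counts = Counter(len(t) for t in tags)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {length: (c, c / total) for length, c in sorted(counts.items())}


def collapse_tags(tags_lib1: Iterable[str], tags_lib2: Iterable[str],
                  min_len: int = DEFAULT_MIN_INSERT,
                  max_len: int = DEFAULT_MAX_INSERT) -> pd.DataFrame:
    """Collapse two tag streams into a unique-tag table.

    Rows: (tag, count_lib1, count_lib2), ordered by total count descending
    then tag lexicographically.  Tags outside [min_len, max_len] are
    dropped (library construction size selection).
    """
    c1 = Counter(t for t in tags_lib1 if min_len <= len(t) <= max_len)
    c2 = Counter(t for t in tags_lib2 if min_len <= len(t) <= max_len)
    all_tags = set(c1) | set(c2)
    rows = [(t, c1.get(t, 0), c2.get(t, 0)) for t in all_tags]
    rows.sort(key=lambda r: (-(r[1] + r[2]), r[0]))
    return pd.DataFrame(rows, columns=["tag", "count_lib1", "count_lib2"])
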