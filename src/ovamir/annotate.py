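"""Priority annotation of unique tags and composition summaries.

Every tag is assigned exactly one category by a fixed precedence:
housekeeping ncRNAs first (rRNA > tRNA > snRNA > snoRNA > scRNA > srpRNA),
then known miRNA, repeat, exon, intron; tags matching nothing are "unann".
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import revcomp
from .references import ReferenceBundle, feature_type, ncrna_type

logger = logging.getLogger(__name__)

NCRNA_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA", "srpRNA")

#: Highest priority first; "unann" is the fallback.
CATEGORY_PRIORITY = (
    *NCRNA_PRIORITY,
    "known_miRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unann",
)

_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}

GenomeHit = tuple[str, int, str]  # (chrom, 0-based start, strand)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_chrom(chrom_arr: np.ndarray, tag: str, max_mismatch: int) -> np.ndarray:
    """Start positions where tag matches with <= max_mismatch substitutions."""
    m = len(tag)
    n = len(chrom_arr)
    if m == 0 or m > n:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(chrom_arr, m)
    mism = (windows != _encode(tag)).sum(axis=1)
    return np.nonzero(mism <= max_mismatch)[0]


def map_to_genome(tags: Iterable[str], genome: Mapping[str, str],
                  max_mismatch: int = 0) -> dict[str, list[GenomeHit]]:
    """All genomic hits (both strands) per tag.

    A reverse-strand hit is reported at the forward-strand coordinate of
    the matching window.  Tags with non-ACGT characters get zero hits.
    """
    hits: dict[str, list[GenomeHit]] = {}
    arrays = {c: _encode(s) for c, s in genome.items()}
    for tag in tags:
        if tag in hits:
            continue
        if set(tag) - set("ACGT"):
            warnings.warn(f"tag with non-ACGT characters gets no hits: {tag[:30]}")
            hits[tag] = []
            continue
        tag_hits: list[GenomeHit] = []
        rc = revcomp(tag)
        for chrom in sorted(genome):
            if max_mismatch == 0:
                seq = genome[chrom]
                for query, strand in ((tag, "+"), (rc, "-")):
                    start = seq.find(query)
                    while start != -1:
                        tag_hits.append((chrom, start, strand))
                        start = seq.find(query, start + 1)
            else:
                arr = arrays[chrom]
                for query, strand in ((tag, "+"), (rc, "-")):
                    for start in _scan_chrom(arr, query, max_mismatch):
                        tag_hits.append((chrom, int(start), strand))
        tag_hits.sort()
        hits[tag] = tag_hits
    return hits


def matches_ncrna(tag: str, ncrna: Mapping[str, str]) -> str | None:
    """Best-priority ncRNA subtype whose reference contains the tag."""
    best: str | None = None
    for rec_id, seq in ncrna.items():
        if tag in seq:
            subtype = ncrna_type(rec_id)
            if best is None or _RANK.get(subtype, 99) < _RANK.get(best, 99):
                best = subtype
    return best


def matches_known_mirna(tag: str, refs: ReferenceBundle,
                        max_mismatch: int = 2, max_offset: int = 2,
                        matcher=None) -> bool:
    from .quantify import MatureMatcher  # deferred: avoids cycle

    if matcher is None:
        matcher = MatureMatcher(refs.mature, max_mismatch, max_offset)
    if matcher.match(tag) is not None:
        return True
    return any(tag in seq for seq in refs.precursor.values())


def _feature_categories(tag: str, hits: Sequence[GenomeHit],
                        features: pd.DataFrame) -> list[str]:
    cats: list[str] = []
    if not len(hits):
        return cats
    m = len(tag)
    for chrom, start, strand in hits:
        end = start + m
        rows = features[(features["chrom"] == chrom)
                        & (features["start"] < end) & (features["end"] > start)]
        for _, row in rows.iterrows():
            ftype = feature_type(row["name"])
            if ftype == "repeat":
                cats.append("repeat")
            elif ftype in ("exon", "intron"):
                orientation = "sense" if strand == row["strand"] else "antisense"
                cats.append(f"{ftype}_{orientation}")
    return cats


def classify_tag(tag: str, hits: Sequence[GenomeHit], refs: ReferenceBundle,
                 mirna_max_mismatch: int = 2, mirna_max_offset: int = 2,
                 matcher=None) -> str:
    """Single highest-priority category for a tag given its genome hits."""
    candidates: list[str] = []
    nc = matches_ncrna(tag, refs.ncrna)
    if nc is not None:
        candidates.append(nc)
    if matches_known_mirna(tag, refs, mirna_max_mismatch, mirna_max_offset, matcher):
        candidates.append("known_miRNA")
    candidates.extend(_feature_categories(tag, hits, refs.features))
    if not candidates:
        return "unann"
    return min(candidates, key=lambda c: _RANK[c])


def annotate_table(tag_table: pd.DataFrame, refs: ReferenceBundle,
                   max_mismatch: int = 0, mirna_max_mismatch: int = 2,
                   mirna_max_offset: int = 2) -> pd.DataFrame:
    """Add 'category' and 'n_hits' columns to a unique-tag table."""
    from .quantify import MatureMatcher  # deferred: avoids cycle

    matcher = MatureMatcher(refs.mature, mirna_max_mismatch, mirna_max_offset)
    hits = map_to_genome(tag_table["tag"], refs.genome, max_mismatch)
    out = tag_table.copy()
    out["n_hits"] = [len(hits[t]) for t in out["tag"]]
    out["category"] = [
        classify_tag(t, hits[t], refs, mirna_max_mismatch, mirna_max_offset, matcher)
        for t in out["tag"]
    ]
    return out


def mapped_fraction(tag_table: pd.DataFrame, hits: Mapping[str, Sequence[GenomeHit]],
                    count_columns: Sequence[str] = ("count_lib1", "count_lib2"),
                    ) -> dict[str, float]:
    """Read-weighted fraction of clean reads with >= 1 genomic hit."""
    out = {}
    mapped_mask = tag_table["tag"].map(lambda t: len(hits[t]) > 0)
    for col in count_columns:
        total = tag_table[col].sum()
        out[col] = float(tag_table.loc[mapped_mask, col].sum() / total) if total else 0.0
    return out


def summarize_composition(annotated: pd.DataFrame,
                          count_columns: Sequence[str] = ("count_lib1", "count_lib2"),
                          ) -> pd.DataFrame:
    """Per-category unique-tag and read tallies with fractions, per library."""
    rows = []
    for cat in CATEGORY_PRIORITY:
        sub = annotated[annotated["category"] == cat]
        row: dict[str, object] = {"category": cat, "unique_tags": len(sub)}
        for col in count_columns:
            row[f"reads_{col}"] = int(sub[col].sum())
        rows.append(row)
    df = pd.DataFrame(rows)
    total_unique = df["unique_tags"].sum()
    df["unique_fraction"] = df["unique_tags"] / total_unique if total_unique else 0.0
    for col in count_columns:
        total = df[f"reads_{col}"].sum()
        df[f"read_fraction_{col}"] = df[f"reads_{col}"] / total if total else 0.0
    return df
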