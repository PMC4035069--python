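"""Seed-match target prediction against 3' UTRs.

A target site is any exact occurrence in a UTR of the reverse complement
of the miRNA seed (positions 2-8, a 7-mer).  U and T are interchangeable
on input; scanning happens on the DNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import revcomp, rna_to_dna

SEED_START = 1  # 0-based: seed = positions 2..8 inclusive
SEED_END = 8


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    gene_id: str
    position: int  # 0-based site start within the UTR
    site: str      # the matched 7-mer


def seed_site(mirna_seq: str) -> str:
    """Reverse complement of the seed region (the UTR site motif)."""
    seq = rna_to_dna(mirna_seq)
    if len(seq) < SEED_END:
        raise ValueError("miRNA shorter than the seed region")
    return revcomp(seq[SEED_START:SEED_END])


def scan_targets(mirnas: Mapping[str, str], utrs: Mapping[str, str],
                 ) -> tuple[list[TargetHit], pd.DataFrame]:
    """All seed-complement sites of each miRNA in each UTR.

    Returns (hit list, per-miRNA tally of distinct target genes and total
    sites).  UTRs shorter than the 7-mer are skipped; overlapping
    occurrences all count.
    """
    hits: list[TargetHit] = []
    tallies = []
    for mid in sorted(mirnas):
        motif = seed_site(mirnas[mid])
        genes: set[str] = set()
        n_sites = 0
        for gene in sorted(utrs):
            utr = rna_to_dna(utrs[gene])
            if len(utr) < len(motif):
                continue
            pos = utr.find(motif)
            while pos != -1:
                hits.append(TargetHit(mid, gene, pos, motif))
                genes.add(gene)
                n_sites += 1
                pos = utr.find(motif, pos + 1)
        tallies.append({"mirna_id": mid, "target_genes": len(genes), "target_sites": n_sites})
    return hits, pd.DataFrame(tallies, columns=["mirna_id", "target_genes", "target_sites"])


def hits_to_frame(hits: list[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mirna_id": h.mirna_id, "gene_id": h.gene_id, "position": h.position,
          "site": h.site} for h in hits],
        columns=["mirna_id", "gene_id", "position", "site"])


def target_gene_set(hits: list[TargetHit]) -> set[str]:
    """Distinct genes targeted by any miRNA (enrichment unit)."""
    return {h.gene_id for h in hits}
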