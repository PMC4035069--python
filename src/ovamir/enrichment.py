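"""Hypergeometric enrichment of target-gene sets.

For each term: N annotated background genes, n of them targets, M genes
carrying the term, m targets carrying it.  GO ontologies are corrected
per ontology with Bonferroni; pathways with Benjamini-Hochberg FDR.
Significance cut-off is 0.05 on the corrected value in both cases.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_qvalues

SIGNIFICANCE_CUTOFF = 0.05

GO_ONTOLOGIES = ("cellular_component", "molecular_function", "biological_process")


def hypergeom_upper_tail(N: int, n: int, M: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n).

    N: background genes with annotation; n: target genes among them;
    M: background genes with the term; m: target genes with the term.
    """
    if not (0 <= m <= min(n, M) and n <= N and M <= N):
        raise ValueError(f"invalid hypergeometric configuration N={N} n={n} M={M} m={m}")
    return float(hypergeom.sf(m - 1, N, M, n))


def enrichment_table(target_genes: Iterable[str], term_map: pd.DataFrame,
                     ontology: str = "pathway",
                     background: Iterable[str] | None = None) -> pd.DataFrame:
    """Raw enrichment of a target-gene set against a gene->term map.

    The background N is every gene in the map (or the supplied set
    intersected with it); only terms with m >= 1 get a row, but every
    tested term enters the correction multiplier downstream.
    """
    tmap = term_map.copy()
    if background is not None:
        tmap = tmap[tmap["gene"].isin(set(background))]
    annotated = set(tmap["gene"])
    targets = set(target_genes) & annotated
    N, n = len(annotated), len(targets)
    rows = []
    for term, genes in tmap.groupby("term")["gene"]:
        gene_set = set(genes)
        M = len(gene_set)
        m = len(gene_set & targets)
        rows.append({"term_id": term, "ontology": ontology, "N": N, "n": n,
                     "M": M, "m": m,
                     "p_raw": hypergeom_upper_tail(N, n, M, m)})
    df = pd.DataFrame(rows, columns=["term_id", "ontology", "N", "n", "M", "m", "p_raw"])
    return df.sort_values(["p_raw", "term_id"], kind="mergesort").reset_index(drop=True)


def correct_go(terms: pd.DataFrame) -> pd.DataFrame:
    """Bonferroni within each ontology; significant iff p_adj <= 0.05."""
    out = terms.copy()
    out["p_adj"] = np.nan
    for ont, idx in out.groupby("ontology").groups.items():
        k = len(idx)
        out.loc[idx, "p_adj"] = np.minimum(out.loc[idx, "p_raw"] * k, 1.0)
    out["significant"] = out["p_adj"] <= SIGNIFICANCE_CUTOFF
    return out


def correct_pathways(terms: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg over all pathways; significant iff q <= 0.05."""
    out = terms.copy()
    out["p_adj"] = bh_qvalues(out["p_raw"].to_numpy()) if len(out) else []
    out["significant"] = out["p_adj"] <= SIGNIFICANCE_CUTOFF
    return out
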