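"""qPCR validation: relative expression and group comparison.

Relative expression per replicate is 2^-(CT_mirna - CT_reference); group
differences are tested with a two-group linear model on log2 relative
expression (equivalent to a pooled-variance t-test), flagged at P < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["mirna", "group", "rep1", "rep2", "rep3", "ref1", "ref2", "ref3"]
SIG_CUTOFF = 0.01


def relative_expression(ct_mirna: float, ct_reference: float) -> float:
    """2^-(CT_mirna - CT_reference) for one replicate."""
    if not (math.isfinite(ct_mirna) and math.isfinite(ct_reference)):
        raise ValueError("CT values must be finite")
    return 2.0 ** -(ct_mirna - ct_reference)


def expression_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-level relative expression in long form.

    Input columns: mirna, group, rep1..rep3 (miRNA CTs), ref1..ref3
    (reference-gene CTs); replicate i is paired with reference i.
    """
    rows = []
    for _, r in ct_table.iterrows():
        for i in (1, 2, 3):
            rows.append({
                "mirna": r["mirna"], "group": r["group"], "replicate": i,
                "rel_expr": relative_expression(float(r[f"rep{i}"]), float(r[f"ref{i}"])),
            })
    return pd.DataFrame(rows, columns=["mirna", "group", "replicate", "rel_expr"])


def summarize(expr: pd.DataFrame) -> pd.DataFrame:
    """Per miRNA and group: mean and SD of relative expression."""
    g = expr.groupby(["mirna", "group"])["rel_expr"]
    out = g.agg(["mean", "std"]).reset_index()
    return out.rename(columns={"mean": "rel_expr_mean", "std": "rel_expr_sd"})


@dataclass
class GroupComparison:
    mirna: str
    log2_ratio: float  # treatment over control
    pvalue: float
    significant: bool


def group_compare(expr: pd.DataFrame, control: str = "control",
                  treatment: str = "treatment") -> list[GroupComparison]:
    """Two-group linear-model test on log2 relative expression per miRNA."""
    out = []
    for mirna, sub in expr.groupby("mirna"):
        a = np.log2(sub.loc[sub["group"] == control, "rel_expr"].to_numpy(dtype=float))
        b = np.log2(sub.loc[sub["group"] == treatment, "rel_expr"].to_numpy(dtype=float))
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >=2 replicates per group for {mirna}")
        estimate = float(b.mean() - a.mean())
        if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(a.mean(), b.mean()):
            p = 1.0  # degenerate: identical groups, no variance
        else:
            p = float(stats.ttest_ind(b, a, equal_var=True).pvalue)
            if math.isnan(p):
                p = 1.0
        out.append(GroupComparison(str(mirna), estimate, p, p < SIG_CUTOFF))
    return sorted(out, key=lambda c: c.mirna)


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mirna": c.mirna, "log2_ratio": c.log2_ratio, "pvalue": c.pvalue,
          "significant": c.significant} for c in comparisons],
        columns=["mirna", "log2_ratio", "pvalue", "significant"])


def concordance_with_sequencing(qpcr: pd.DataFrame, de: pd.DataFrame) -> pd.DataFrame:
    """Direction agreement between qPCR log2 ratios and sequencing log2fc.

    Joins on miRNA id; rows with a zero on either side count as
    'no direction' and are excluded from the agreement fraction (stored in
    the DataFrame attrs as 'agreement').
    """
    merged = qpcr.merge(de[["mirna_id", "log2fc"]], left_on="mirna",
                        right_on="mirna_id", how="inner")
    if merged.empty:
        raise ValueError("no shared miRNA ids between qPCR and sequencing tables")
    merged["qpcr_direction"] = np.sign(merged["log2_ratio"])
    merged["seq_direction"] = np.sign(merged["log2fc"])
    directed = merged[(merged["qpcr_direction"] != 0) & (merged["seq_direction"] != 0)]
    merged["agree"] = merged["qpcr_direction"] == merged["seq_direction"]
    agreement = float((directed["qpcr_direction"] == directed["seq_direction"]).mean()) \
        if len(directed) else float("nan")
    result = merged[["mirna", "log2_ratio", "log2fc", "agree"]].copy()
    result.attrs["agreement"] = agreement
    result.attrs["n_directed"] = int(len(directed))
    return result
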