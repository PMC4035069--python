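"""Two-library differential expression statistics.

Normalization to tags-per-million, the zero / low-expression revision
rules, log2 fold change with ratio classes, the exact two-library count
test, significance labelling, and average-linkage clustering of the
differentially expressed set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import nbinom

ZERO_REVISION = 0.01
LOW_EXPRESSION_CUTOFF = 1.0

RATIO_GT2 = ">2"
RATIO_MID = "(1/2,2]"
RATIO_LE_HALF = "<=1/2"


def normalize_tpm(count: float, clean_total: int) -> float:
    """Tags per million: count / total clean reads * 1e6 (full precision)."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 1e6 * count / clean_total


def revise_zero(std: float) -> float:
    return ZERO_REVISION if std == 0 else std


def adjust_and_filter(table: pd.DataFrame, std1_col: str = "std_lib1",
                      std2_col: str = "std_lib2") -> pd.DataFrame:
    """Apply the zero revision, then drop rows with both std below 1.

    Zero normalized expression in either library becomes 0.01; miRNAs
    whose expression is below 1 in both libraries leave the DE analysis.
    """
    out = table.copy()
    out[std1_col] = out[std1_col].map(revise_zero)
    out[std2_col] = out[std2_col].map(revise_zero)
    keep = (out[std1_col] >= LOW_EXPRESSION_CUTOFF) | (out[std2_col] >= LOW_EXPRESSION_CUTOFF)
    return out[keep].reset_index(drop=True)


def exact_count_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact p-value for observing counts (x, y) in libraries of
    total depth (n1, n2) under equal relative expression.

    The conditional law of y given x,
    ``p(y|x) = (n2/n1)^y (x+y)! / (x! y! (1 + n2/n1)^(x+y+1))``,
    is the negative-binomial pmf with size x+1 and success probability
    n1/(n1+n2); tails are therefore evaluated through the stable
    regularized-beta CDF rather than term-by-term summation.  The smaller
    tail is doubled and capped at 1.
    """
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p_success = n1 / (n1 + n2)
    lower = nbinom.cdf(y, x + 1, p_success)          # P(Y <= y | x)
    upper = nbinom.sf(y - 1, x + 1, p_success)       # P(Y >= y | x)
    return float(min(1.0, 2.0 * min(lower, upper)))


def fold_change(std_control: float, std_treatment: float) -> tuple[float, str]:
    """log2(treatment/control) and the scatter-plot ratio class."""
    if std_control <= 0 or std_treatment <= 0:
        raise ValueError("std values must be positive (apply the zero revision first)")
    ratio = std_treatment / std_control
    log2fc = float(np.log2(ratio))
    if ratio > 2:
        cls = RATIO_GT2
    elif ratio <= 0.5:
        cls = RATIO_LE_HALF
    else:
        cls = RATIO_MID
    return log2fc, cls


def sig_label(log2fc: float, p: float) -> str:
    """'**' / '*' / 'None' per the fold-change + p-value rule."""
    if not (np.isfinite(log2fc) and np.isfinite(p)):
        raise ValueError("inputs must be finite")
    if abs(log2fc) > 1 and p < 0.01:
        return "**"
    if abs(log2fc) > 1 and 0.01 <= p < 0.05:
        return "*"
    return "None"


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def de_table(records: pd.DataFrame, clean_total_lib1: int, clean_total_lib2: int,
             control: str = "lib1") -> pd.DataFrame:
    """Full differential-expression table from raw per-miRNA counts.

    ``records`` needs mirna_id, count_lib1, count_lib2.  The p-value is
    computed from raw counts and library totals; the 0.01 zero revision
    only affects the fold change.  An advisory BH column is included but
    plays no part in the significance labels.
    """
    if control not in ("lib1", "lib2"):
        raise ValueError("control must be 'lib1' or 'lib2'")
    treatment = "lib2" if control == "lib1" else "lib1"
    totals = {"lib1": clean_total_lib1, "lib2": clean_total_lib2}

    out = records.copy()
    out["std_lib1"] = [normalize_tpm(c, totals["lib1"]) for c in out["count_lib1"]]
    out["std_lib2"] = [normalize_tpm(c, totals["lib2"]) for c in out["count_lib2"]]
    out = adjust_and_filter(out)

    log2fcs, classes, pvals = [], [], []
    for _, row in out.iterrows():
        fc, cls = fold_change(row[f"std_{control}"], row[f"std_{treatment}"])
        log2fcs.append(fc)
        classes.append(cls)
        pvals.append(exact_count_pvalue(
            int(row[f"count_{control}"]), int(row[f"count_{treatment}"]),
            totals[control], totals[treatment]))
    out["log2fc"] = log2fcs
    out["ratio_class"] = classes
    out["pvalue"] = pvals
    out["qvalue_bh"] = bh_qvalues(np.array(pvals)) if len(out) else []
    out["sig_label"] = [sig_label(fc, p) for fc, p in zip(log2fcs, pvals)]
    return out


def ratio_class_summary(de: pd.DataFrame) -> pd.Series:
    """Fraction of miRNAs per ratio class (scatter-plot colour split)."""
    return de["ratio_class"].value_counts(normalize=True)


def label_summary(de: pd.DataFrame) -> pd.Series:
    """Fraction of miRNAs per significance label."""
    return de["sig_label"].value_counts(normalize=True)


@dataclass
class ClusterTree:
    linkage: np.ndarray
    leaf_ids: list[str]          # input order
    leaf_order: list[str]        # dendrogram display order
    profiles: pd.DataFrame       # per-leaf log2 std vectors

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"

    def cut(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.leaf_ids, (int(v) for v in labels)))


def cluster_de(de: pd.DataFrame, only_significant: bool = True) -> ClusterTree:
    """Average-linkage Euclidean clustering on log2 std profiles of the
    differentially expressed miRNAs (labelled * or **)."""
    sub = de[de["sig_label"] != "None"] if only_significant and "sig_label" in de else de
    if len(sub) < 2:
        raise ValueError("need at least 2 differentially expressed records to cluster")
    profiles = np.log2(sub[["std_lib1", "std_lib2"]].to_numpy(dtype=float))
    z = hierarchy.linkage(profiles, method="average", metric="euclidean")
    leaf_ids = list(sub["mirna_id"])
    order = [leaf_ids[i] for i in hierarchy.leaves_list(z)]
    prof_df = pd.DataFrame(profiles, index=leaf_ids, columns=["log2_std_lib1", "log2_std_lib2"])
    return ClusterTree(linkage=z, leaf_ids=leaf_ids, leaf_order=order, profiles=prof_df)
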