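"""Expression summaries: CPM normalization, transcription flags, DE filters.

The differential-expression engine here (``naive_de``) is a deliberately
simple Welch test on log2(CPM+1) with BH adjustment — adequate for planted
synthetic effects and for threshold bookkeeping, and clearly labelled as an
approximation; externally computed statistics tables (negative-binomial
engines) can be fed straight into ``de_filter``.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .models import NESTED_CATEGORIES, RelationshipRecord


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization (each sample column sums to 1e6)."""
    colsum = counts.sum(axis=0)
    if (colsum <= 0).any():
        bad = list(colsum.index[colsum <= 0])
        raise ValueError(f"zero-sum sample column(s): {bad}")
    return counts * (1e6 / colsum)


def transcribed_flag(breadth: Union[float, np.ndarray, pd.Series],
                     min_breadth: float = 1.0):
    """Feature counts as transcribed when reads cover at least
    ``min_breadth`` of its length (default: the entire length)."""
    return breadth >= min_breadth


def naive_de(cpm_matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-group Welch test per feature on log2(CPM + 1).

    ``groups`` maps sample -> group label (exactly two labels, each with at
    least two samples). log2 fold change is mean(log2(cpm+1)) of the second
    group (order of first appearance) minus the first. Returns a stats table
    with baseMean (mean CPM over all samples), log2fc, pvalue, padj (BH).
    """
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    g1 = groups.index[groups == labels[0]]
    g2 = groups.index[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples")
    X = np.log2(cpm_matrix + 1.0)
    A = X[g1].to_numpy(dtype=float)
    B = X[g2].to_numpy(dtype=float)
    lfc = B.mean(axis=1) - A.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = _st.ttest_ind(B, A, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # constant features -> no evidence
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "baseMean": cpm_matrix.mean(axis=1),
        "log2fc": lfc,
        "pvalue": p,
        "padj": padj,
    }, index=cpm_matrix.index)


def de_filter(
    stats: pd.DataFrame,
    base_min: float = 10.0,
    lfc_min: float = 2.0,
    alpha: float = 0.05,
) -> tuple[set, set]:
    """Published-style DE thresholds: baseMean strictly > base_min,
    |log2fc| >= lfc_min, padj strictly < alpha. Returns (up, down) id sets."""
    if stats.empty:
        return set(), set()
    ok = (stats["baseMean"] > base_min) & (stats["padj"] < alpha)
    up = set(stats.index[ok & (stats["log2fc"] >= lfc_min)])
    down = set(stats.index[ok & (stats["log2fc"] <= -lfc_min)])
    return up, down


def de_te_gene_overlap(
    de_tes: Iterable[str],
    de_genes: Iterable[str],
    relations: Sequence[RelationshipRecord],
    max_dist: int = 5000,
) -> list[dict]:
    """Differentially expressed TEs near or within differentially expressed
    genes: the TE's relationship record must point at a DE gene and be a
    nested/overlap category or lie within ``max_dist`` bp."""
    de_te_set, de_gene_set = set(de_tes), set(de_genes)
    out = []
    for r in relations:
        if r.te_id not in de_te_set or r.gene_id not in de_gene_set:
            continue
        near = r.category in NESTED_CATEGORIES or r.category in ("overlap5", "overlap3")
        if not near and r.distance is not None and r.distance <= max_dist:
            near = True
        if near:
            out.append({
                "te_id": r.te_id, "gene_id": r.gene_id,
                "category": r.category, "distance": r.distance,
            })
    return out


def expression_proportions(counts: dict, total: Optional[int] = None,
                           digits: int = 1) -> dict:
    """Percentages of expressed elements per group to ``digits`` decimals
    (e.g. DNA-transposon transcripts among all transcribed TEs)."""
    tot = total if total is not None else sum(counts.values())
    if tot <= 0:
        raise ValueError("total must be positive")
    return {k: round(100.0 * v / tot, digits) for k, v in counts.items()}
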