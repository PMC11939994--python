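"""TE islands: sliding-window TE coverage, island calling and enrichment.

A TE island is a run of sliding windows whose TE base-pair coverage exceeds
a threshold (strictly > 0.5 by default, on 500 kb windows stepped by
100 kb); qualifying windows that overlap or abut are merged into maximal
disjoint regions. Gene-density depletion inside islands is tested with
Fisher's exact test on a genes-vs-kilobases 2x2 table, and a generic
hypergeometric term-enrichment with Benjamini-Hochberg FDR is provided for
user-supplied term maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GeneModel, GenomicInterval, TECopy

logger = logging.getLogger(__name__)


@dataclass
class WindowCoverage:
    interval: GenomicInterval
    te_bp: int
    fraction: float


@dataclass
class Island:
    interval: GenomicInterval
    n_windows: int
    te_fraction: float
    gene_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open (start, end) pairs as sorted disjoint pairs."""
    srt = sorted(pairs)
    out: list[tuple[int, int]] = []
    for s, e in srt:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _covered_bp(merged: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Base pairs of the merged set falling inside [lo, hi)."""
    total = 0
    for s, e in merged:
        if s >= hi:
            break
        if e <= lo:
            continue
        total += min(e, hi) - max(s, lo)
    return total


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def _window_starts(length: int, window: int, step: int) -> list[tuple[int, int]]:
    if length <= window:
        return [(0, length)]
    wins = []
    start = 0
    while start + window <= length:
        wins.append((start, start + window))
        start += step
    if wins[-1][1] < length:
        wins.append((start, length))  # terminal partial window
    return wins


def window_scan(
    tes: Sequence[TECopy],
    chrom_sizes: Mapping[str, int],
    window: int = 500_000,
    step: int = 100_000,
) -> list[WindowCoverage]:
    """Per-window TE base-pair coverage fraction along each chromosome.

    Windows of size ``window`` advance by ``step`` from 0; a terminal partial
    window (normalized by its true length) covers any remainder, and a
    chromosome shorter than ``window`` yields one full-length window. TE
    coverage is the union of TE intervals clipped to the window, so nested or
    overlapping copies never double-count a base.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    if step > window:
        raise ValueError("step must be <= window")
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for te in tes:
        iv = te.interval
        if iv.chrom in by_chrom:
            by_chrom[iv.chrom].append((iv.start, iv.end))
    out: list[WindowCoverage] = []
    for chrom, length in chrom_sizes.items():
        merged = merge_intervals(by_chrom[chrom])
        for lo, hi in _window_starts(length, window, step):
            bp = _covered_bp(merged, lo, hi)
            out.append(WindowCoverage(
                interval=GenomicInterval(chrom, lo, hi),
                te_bp=bp,
                fraction=bp / (hi - lo),
            ))
    return out


def call_islands(
    windows: Sequence[WindowCoverage],
    threshold: float = 0.5,
    tes: Optional[Sequence[TECopy]] = None,
) -> list[Island]:
    """Merge windows with TE fraction strictly above ``threshold`` into islands.

    Qualifying windows that overlap or abut are merged into maximal disjoint
    regions per chromosome. When the TE set is supplied, each island's
    ``te_fraction`` is recomputed exactly on the merged interval; otherwise it
    falls back to the mean fraction of the merged windows (overlapping
    windows cannot be summed exactly).
    """
    kept = [w for w in windows if w.fraction > threshold]
    if not kept:
        return []
    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if tes is not None:
        for te in tes:
            te_by_chrom.setdefault(te.interval.chrom, []).append(
                (te.interval.start, te.interval.end)
            )
        te_by_chrom = {c: merge_intervals(v) for c, v in te_by_chrom.items()}

    islands: list[Island] = []
    by_chrom: dict[str, list[WindowCoverage]] = {}
    for w in kept:
        by_chrom.setdefault(w.interval.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: w.interval.start)
        runs: list[list[WindowCoverage]] = [[ws[0]]]
        for w in ws[1:]:
            if w.interval.start <= runs[-1][-1].interval.end:
                runs[-1].append(w)
            else:
                runs.append([w])
        for run in runs:
            lo = run[0].interval.start
            hi = max(w.interval.end for w in run)
            if tes is not None:
                bp = _covered_bp(te_by_chrom.get(chrom, []), lo, hi)
                frac = bp / (hi - lo)
            else:
                frac = float(np.mean([w.fraction for w in run]))
            islands.append(Island(
                interval=GenomicInterval(chrom, lo, hi),
                n_windows=len(run),
                te_fraction=frac,
            ))
    return islands


def assign_genes(islands: Sequence[Island], genes: Sequence[GeneModel]) -> None:
    """Fill each island's gene_ids with genes whose midpoint lies inside.

    The midpoint rule keeps the Fisher 2x2 table free of double-counted
    boundary genes.
    """
    for isl in islands:
        isl.gene_ids = []
    for g in genes:
        mid = (g.interval.start + g.interval.end) // 2
        for isl in islands:
            iv = isl.interval
            if iv.chrom == g.interval.chrom and iv.start <= mid < iv.end:
                isl.gene_ids.append(g.id)
                break


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test (odds ratio, p) on a 2x2 count table.

    Degenerate tables (a zero margin) return (nan, 1.0) with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1")
        return float("nan"), 1.0
    orat, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(orat), float(p)


def gene_density_test(
    islands: Sequence[Island],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
) -> dict:
    """Gene-density contrast between islands and the rest of the genome.

    Builds a 2x2 table of gene counts (midpoint rule) versus kilobases of
    sequence inside/outside islands and applies a two-sided Fisher exact
    test. Returns odds ratio, p, and the table.
    """
    assign_genes(islands, genes)
    genome_bp = sum(chrom_sizes.values())
    island_bp = sum(isl.interval.length for isl in islands)
    genes_in = sum(len(isl.gene_ids) for isl in islands)
    genes_out = len(genes) - genes_in
    kb_in = int(round(island_bp / 1000))
    kb_out = int(round((genome_bp - island_bp) / 1000))
    table = [[genes_in, genes_out], [kb_in, kb_out]]
    orat, p = fisher_2x2(table)
    return {"odds_ratio": orat, "p_value": p, "table": table,
            "genes_in": genes_in, "genes_out": genes_out,
            "island_bp": island_bp, "genome_bp": genome_bp}


def term_enrichment(
    fg_genes: Iterable[str],
    bg_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a foreground gene set.

    For each term with K background genes, k of n foreground genes annotated,
    in a universe of N background genes, the upper-tail hypergeometric p is
    P(X >= k); q-values are Benjamini-Hochberg adjusted across terms and rows
    come back sorted by q. Terms with no background genes are skipped.
    """
    fg = set(fg_genes)
    bg = set(bg_genes)
    if not fg <= bg:
        raise ValueError("foreground genes must be a subset of the background")
    N, n = len(bg), len(fg)
    rows = []
    for term, members in term_map.items():
        mem = set(members) & bg
        K = len(mem)
        if K == 0:
            logger.info("term %s has no background genes; skipped", term)
            continue
        k = len(mem & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "fdr", "significant"])
    df = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = df["fdr"] < alpha
    return df.sort_values(["fdr", "p"]).reset_index(drop=True)
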