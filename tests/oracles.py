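"""Independent brute-force oracles used to validate the fast implementations.

Everything here works per base pair, by exhaustive enumeration, or from a
closed form evaluated along a different code path than the library; the
oracles deliberately share no interval arithmetic with the package.
"""

from __future__ import annotations

import numpy as np

from telandscape.models import GeneModel, TECopy


# ---------------------------------------------------------------------------
# per-base-pair TE-gene classification
# ---------------------------------------------------------------------------

def _gene_segment_map(gene: GeneModel) -> dict[int, int]:
    """bp -> segment index (segments enumerated in genomic order)."""
    out: dict[int, int] = {}
    for idx, (_kind, seg) in enumerate(gene.feature_segments()):
        for bp in range(seg.start, seg.end):
            out[bp] = idx
    return out


def classify_oracle(te: TECopy, genes: list[GeneModel], promoter_window: int = 1000) -> str:
    """Category of a TE by exhaustive per-bp overlap enumeration."""
    chrom_genes = [g for g in genes if g.interval.chrom == te.interval.chrom]
    if not chrom_genes:
        return "unanchored"
    te_bps = set(range(te.interval.start, te.interval.end))

    overlaps = []
    for g in chrom_genes:
        gene_bps = set(range(g.interval.start, g.interval.end))
        ov = len(te_bps & gene_bps)
        if ov > 0:
            overlaps.append((ov, g))
    if overlaps:
        best = max(ov for ov, _ in overlaps)
        cands = sorted((g for ov, g in overlaps if ov == best),
                       key=lambda g: (g.interval.start, g.id))
        g = cands[0]
        covers_before = any(bp < g.interval.start for bp in te_bps)
        covers_after = any(bp >= g.interval.end for bp in te_bps)
        inside = any(g.interval.start <= bp < g.interval.end for bp in te_bps)
        crosses_left = covers_before and inside
        crosses_right = covers_after and inside
        if g.strand == "-":
            c5, c3 = crosses_right, crosses_left
        else:
            c5, c3 = crosses_left, crosses_right
        if c5:
            return "overlap5"
        if c3:
            return "overlap3"
        seg_map = _gene_segment_map(g)
        kinds = [k for _, (k, _) in enumerate(g.feature_segments())]
        touched = sorted({seg_map[bp] for bp in te_bps if bp in seg_map})
        if len(touched) == 1:
            return kinds[touched[0]]
        return "exon_intron"

    # intergenic: nearest gene by per-bp minimum gap
    def bp_gap(g: GeneModel) -> int:
        gene_bps = range(g.interval.start, g.interval.end)
        return min(abs(a - b) - 1 for a in te_bps
                   for b in (g.interval.start, g.interval.end - 1)
                   ) if gene_bps else 10**9

    g = sorted(chrom_genes, key=lambda g: (bp_gap(g), g.interval.start, g.id))[0]
    te_left = max(te_bps) < g.interval.start
    strand = g.strand if g.strand in ("+", "-") else "+"
    upstream = te_left if strand == "+" else not te_left
    if not upstream:
        return "downstream"
    if strand == "+":
        d_tss = g.tss - (max(te_bps) + 1)
    else:
        d_tss = min(te_bps) - g.tss - 1
    return "promoter" if 0 <= d_tss <= promoter_window else "upstream"


def spanned_oracle(te: TECopy, gene: GeneModel) -> dict[str, int]:
    """Per-kind overlap bp of a TE with a gene, counted base by base."""
    out: dict[str, int] = {}
    for kind, seg in gene.feature_segments():
        n = sum(1 for bp in range(te.interval.start, te.interval.end)
                if seg.start <= bp < seg.end)
        if n:
            out[kind] = out.get(kind, 0) + n
    return out


# ---------------------------------------------------------------------------
# bitmap window coverage
# ---------------------------------------------------------------------------

def coverage_bitmap(tes, chrom: str, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=bool)
    for te in tes:
        iv = te.interval
        if iv.chrom == chrom:
            arr[iv.start:min(iv.end, length)] = True
    return arr


# ---------------------------------------------------------------------------
# LD from phased binary haplotypes
# ---------------------------------------------------------------------------

def r2_haplotype_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Classical D^2 / (pA pa pB pb) for phased binary data."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pA, pB = x.mean(), y.mean()
    pAB = (x * y).mean()
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return float(D * D / denom)


# ---------------------------------------------------------------------------
# exhaustive hypergeometric two-sided Fisher p
# ---------------------------------------------------------------------------

def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total
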