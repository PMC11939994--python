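"""Positional relationship of each TE copy to its nearest gene.

Each mapped TE receives exactly one category:

* gene-body overlap: ``overlap5``/``overlap3`` when the TE crosses the
  strand-aware 5'/3' gene boundary; otherwise a nested category — ``intron``,
  ``utr5``, ``utr3`` or ``cds`` when the TE lies entirely within a single
  feature segment, ``exon_intron`` when it touches two or more segments;
* intergenic: ``upstream`` or ``downstream`` of the nearest gene
  (edge-to-edge distance, gene-strand-relative side), with ``upstream``
  promoted to ``promoter`` when the TE's 3'-proximal edge lies within the
  promoter window upstream of the TSS;
* ``unanchored`` when the TE sits on a chromosome without annotated genes.

Tie-break rules (equidistant or equally-overlapping genes) favour the gene
with the smaller start coordinate, then the lexicographically smaller id.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import (
    DISTANCE_CATEGORIES,
    GeneModel,
    NESTED_CATEGORIES,
    RelationshipRecord,
    TECopy,
)


@dataclass
class TopologyParams:
    """Tunable distances for TE-gene classification.

    promoter_window : bp upstream of the TSS within which an upstream TE is
        a promoter insertion (default 1000).
    proximity_bin : bp bound of the "near gene" distance bin (default 5000,
        closed: a TE at exactly this distance counts as near).
    """

    promoter_window: int = 1000
    proximity_bin: int = 5000

    def __post_init__(self) -> None:
        if self.promoter_window <= 0:
            raise ValueError("promoter_window must be > 0")


def _genes_by_chrom(genes: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    d: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        d[g.interval.chrom].append(g)
    for lst in d.values():
        lst.sort(key=lambda g: (g.interval.start, g.id))
    return d


def integrate_nested(te: TECopy, gene: GeneModel) -> list[tuple[str, int]]:
    """Overlap of a gene-body TE with every gene feature segment.

    Returns ordered (feature_type, overlap_bp) pairs in transcription order
    for every exon/intron/UTR/CDS segment the TE intersects; overlaps sum to
    the TE-gene intersection length.
    """
    spans = []
    for kind, seg in gene.feature_segments():
        ov = te.interval.overlap_len(seg)
        if ov > 0:
            spans.append((kind, ov))
    if gene.strand == "-":
        spans.reverse()
    return spans


def _classify_overlapping(te: TECopy, gene: GeneModel) -> RelationshipRecord:
    iv, giv = te.interval, gene.interval
    crosses_left = iv.start < giv.start < iv.end
    crosses_right = iv.start < giv.end < iv.end
    if gene.strand == "-":
        crosses5, crosses3 = crosses_right, crosses_left
    else:
        crosses5, crosses3 = crosses_left, crosses_right
    spans = integrate_nested(te, gene)
    if crosses5:
        cat = "overlap5"
    elif crosses3:
        cat = "overlap3"
    elif len(spans) == 1:
        cat = spans[0][0]  # intron / utr5 / utr3 / cds
    else:
        cat = "exon_intron"
    return RelationshipRecord(
        te_id=te.id, gene_id=gene.id, category=cat,
        spanned_features=spans, superfamily=te.superfamily,
    )


def classify(
    te: TECopy,
    genes: Sequence[GeneModel],
    params: Optional[TopologyParams] = None,
) -> RelationshipRecord:
    """Classify one TE against the genes of its chromosome."""
    params = params or TopologyParams()
    chrom_genes = [g for g in genes if g.interval.chrom == te.interval.chrom]
    if not chrom_genes:
        return RelationshipRecord(te.id, None, "unanchored", superfamily=te.superfamily)

    overlapping = [g for g in chrom_genes if te.interval.overlaps(g.interval)]
    if overlapping:
        # largest overlap wins; tie -> 5'-most (smaller start), then id
        gene = sorted(
            overlapping,
            key=lambda g: (-te.interval.overlap_len(g.interval), g.interval.start, g.id),
        )[0]
        return _classify_overlapping(te, gene)

    def gap(g: GeneModel) -> int:
        if te.interval.end <= g.interval.start:
            return g.interval.start - te.interval.end
        return te.interval.start - g.interval.end

    gene = sorted(chrom_genes, key=lambda g: (gap(g), g.interval.start, g.id))[0]
    dist = gap(gene)
    strand = gene.strand if gene.strand in ("+", "-") else "+"
    te_left = te.interval.end <= gene.interval.start
    upstream_side = te_left if strand == "+" else not te_left

    cat = "upstream" if upstream_side else "downstream"
    if upstream_side:
        # distance from the TE's 3'-proximal (gene-facing) edge to the TSS
        if strand == "+":
            d_tss = gene.tss - te.interval.end
        else:
            d_tss = te.interval.start - gene.tss - 1
        if 0 <= d_tss <= params.promoter_window:
            cat = "promoter"
    return RelationshipRecord(
        te_id=te.id, gene_id=gene.id, category=cat,
        distance=dist, superfamily=te.superfamily,
    )


def classify_all(
    tes: Iterable[TECopy],
    genes: Sequence[GeneModel],
    params: Optional[TopologyParams] = None,
) -> list[RelationshipRecord]:
    """Classify every TE; genes are grouped per chromosome once."""
    params = params or TopologyParams()
    by_chrom = _genes_by_chrom(genes)
    return [classify(te, by_chrom.get(te.interval.chrom, []), params) for te in tes]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def category_proportions(
    counts: Mapping[str, int], total: Optional[int] = None, digits: int = 1
) -> dict[str, float]:
    """Percentages of mapped TEs per category, rounded to ``digits`` decimals.

    ``total`` defaults to the sum of the counts; pass it explicitly when the
    counts are a subset (e.g. sub-categories of a published table).
    """
    tot = total if total is not None else sum(counts.values())
    if tot <= 0:
        raise ValueError("total must be positive")
    return {k: round(100.0 * v / tot, digits) for k, v in counts.items()}


_CATEGORY_ORDER = [
    "promoter", "upstream", "downstream", "overlap5", "overlap3",
    "intron", "utr5", "utr3", "cds", "exon_intron", "unanchored",
]


def relation_summary(
    records: Iterable[RelationshipRecord], merge_mite: bool = False
) -> pd.DataFrame:
    """Category x superfamily count matrix with row totals and proportions.

    Proportions are percentages of mapped (non-unanchored) TEs, to 1 decimal.
    MITEs are kept as their own column by default; ``merge_mite=True`` folds
    them into DTM (they are mostly non-autonomous Mutator derivatives), for
    summaries that report a single TIR-like block.
    """
    rows = []
    for r in records:
        sf = r.superfamily
        if merge_mite and sf == "MITE":
            sf = "DTM"
        rows.append((r.category, sf))
    df = pd.DataFrame(rows, columns=["category", "superfamily"])
    if df.empty:
        return pd.DataFrame()
    mat = pd.crosstab(df["category"], df["superfamily"])
    mat = mat.reindex([c for c in _CATEGORY_ORDER if c in mat.index])
    mat["Total"] = mat.sum(axis=1)
    mapped_total = int(mat.loc[mat.index != "unanchored", "Total"].sum())
    if mapped_total > 0:
        mat["Proportion_pct"] = [
            round(100.0 * t / mapped_total, 1) if cat != "unanchored" else float("nan")
            for cat, t in mat["Total"].items()
        ]
    return mat


def distance_profile(
    records: Iterable[RelationshipRecord],
    params: Optional[TopologyParams] = None,
) -> pd.DataFrame:
    """Counts of proximal TEs within/beyond the proximity bin.

    Only distance-bearing records (promoter/upstream/downstream) are used;
    promoter records count on the upstream side. The near bin is closed:
    distance <= proximity_bin is "within".
    """
    params = params or TopologyParams()
    rows = []
    for r in records:
        if r.category not in DISTANCE_CATEGORIES:
            continue
        side = "upstream" if r.category in ("promoter", "upstream") else "downstream"
        near = r.distance <= params.proximity_bin
        rows.append((side, r.superfamily, "within" if near else "beyond"))
    df = pd.DataFrame(rows, columns=["side", "superfamily", "bin"])
    if df.empty:
        return pd.DataFrame()
    out = df.groupby(["side", "superfamily", "bin"]).size().unstack("bin", fill_value=0)
    for col in ("within", "beyond"):
        if col not in out.columns:
            out[col] = 0
    return out[["within", "beyond"]]


def records_to_frame(records: Iterable[RelationshipRecord]) -> pd.DataFrame:
    """Flat table of relationship records (one row per TE)."""
    rows = []
    for r in records:
        rows.append({
            "te_id": r.te_id,
            "gene_id": r.gene_id if r.gene_id is not None else ".",
            "category": r.category,
            "distance": r.distance if r.distance is not None else "",
            "superfamily": r.superfamily,
            "spanned_features": ";".join(f"{k}:{bp}" for k, bp in r.spanned_features),
        })
    return pd.DataFrame(rows)


def feature_context(record: RelationshipRecord) -> str:
    """Collapse a relationship category to the coarse genomic-feature context
    used for TIP stratification: CDS, intron, UTR or intergenic."""
    if record.category == "cds":
        return "CDS"
    if record.category == "intron":
        return "intron"
    if record.category in ("utr5", "utr3"):
        return "UTR"
    if record.category == "exon_intron":
        # dominant feature by spanned bp
        by_kind: dict[str, int] = {}
        for kind, bp in record.spanned_features:
            by_kind[kind] = by_kind.get(kind, 0) + bp
        top = max(by_kind.items(), key=lambda kv: kv[1])[0]
        return {"cds": "CDS", "intron": "intron", "utr5": "UTR", "utr3": "UTR"}[top]
    return "intergenic"
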