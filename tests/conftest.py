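"""Shared fixtures: tiny hand-built gene models and random small genomes."""

from __future__ import annotations

import numpy as np
import pytest

from telandscape.models import GeneModel, GenomicInterval, TECopy


def make_gene(
    gid: str,
    chrom: str,
    exon_spans: list[tuple[int, int]],
    strand: str = "+",
    utr5_bp: int = 0,
    utr3_bp: int = 0,
) -> GeneModel:
    """Gene from exon spans; optional UTRs carved off the transcript ends."""
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(exon_spans)]
    start, end = exons[0].start, exons[-1].end
    utr5, utr3, cds = [], [], []
    left = utr5_bp if strand == "+" else utr3_bp
    right = utr3_bp if strand == "+" else utr5_bp
    left_iv = GenomicInterval(chrom, start, start + left, strand) if left else None
    right_iv = GenomicInterval(chrom, end - right, end, strand) if right else None
    for i, ex in enumerate(exons):
        lo, hi = ex.start, ex.end
        if i == 0 and left_iv is not None:
            lo = left_iv.end
        if i == len(exons) - 1 and right_iv is not None:
            hi = right_iv.start
        if lo < hi:
            cds.append(GenomicInterval(chrom, lo, hi, strand))
    if strand == "+":
        utr5 = [left_iv] if left_iv else []
        utr3 = [right_iv] if right_iv else []
    else:
        utr5 = [right_iv] if right_iv else []
        utr3 = [left_iv] if left_iv else []
    return GeneModel(id=gid, interval=GenomicInterval(chrom, start, end, strand),
                     exons=exons, cds=cds, utr5=utr5, utr3=utr3)


def te(chrom: str, start: int, end: int, te_id: str = "te1",
       superfamily: str = "Gypsy") -> TECopy:
    return TECopy(id=te_id, interval=GenomicInterval(chrom, start, end),
                  superfamily=superfamily)


def random_layout(rng: np.random.Generator, chrom: str = "c",
                  length: int = 12_000) -> list[GeneModel]:
    """1-4 random non-overlapping genes with exon/intron/UTR structure."""
    n_genes = int(rng.integers(1, 5))
    slot = length // n_genes
    genes = []
    for k in range(n_genes):
        n_ex = int(rng.integers(1, 4))
        exon_lens = rng.integers(60, 200, size=n_ex)
        intron_lens = rng.integers(50, 300, size=max(n_ex - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        lo = k * slot + int(rng.integers(0, max(slot - span - 200, 1)))
        spans, pos = [], lo
        for i in range(n_ex):
            spans.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = int(rng.integers(0, 40))
        u3 = int(rng.integers(0, 40))
        genes.append(make_gene(f"g{k}", chrom, spans, strand, u5, u3))
    return genes


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def two_exon_gene() -> GeneModel:
    # exons [100,200) and [300,400), derived intron [200,300), '+' strand
    return make_gene("gA", "chr1", [(100, 200), (300, 400)], "+",
                     utr5_bp=30, utr3_bp=30)
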