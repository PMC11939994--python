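"""Synthetic data with known ground truth for every pipeline input.

The generators emulate the structure of a compact plant genome analysed for
its TE landscape: a small multi-chromosome genome with gene models and TE
copies placed to hit target TE-gene relation-category fractions; a
two-population resequencing cohort (9 + 11 individuals, mirroring a
red/white ecotype design) with shared and fixed-difference TE insertion
polymorphisms, Beta-distributed allele frequencies and founder-haplotype
SNP backgrounds with tunable TIP tagging; per-copy divergence values with a
recent proliferation burst plus an older component; and count matrices with
a planted differentially-expressed fraction. Coordinates, genotypes and
counts only — no nucleotide sequence is simulated.

Every generator is a pure function of its configuration: the same
``SimConfig`` always produces identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .models import GeneModel, GenomicInterval, TECopy
from .te_age import DivergenceRecord

# relation-category mix and per-superfamily weights default to the shape of
# a Gypsy/Mutator-dominated compact genome
_DEFAULT_CATEGORY_FRACTIONS = {
    "upstream": 0.45, "downstream": 0.42, "nested": 0.10, "overlap": 0.03,
}
_DEFAULT_NESTED_FRACTIONS = {
    "intron": 0.830, "utr5": 0.029, "utr3": 0.056, "cds": 0.012, "exon_intron": 0.073,
}
_DEFAULT_SF_WEIGHTS = {
    "Gypsy": 0.37, "Copia": 0.15, "DTM": 0.21, "DTC": 0.045, "DTA": 0.01,
    "DTH": 0.012, "DTT": 0.002, "Helitron": 0.145, "MITE": 0.035, "nLTR": 0.021,
}
_DEFAULT_TIP_SF_WEIGHTS = {
    "Gypsy": 0.716, "DTM": 0.127, "Copia": 0.060, "Helitron": 0.040,
    "DTA": 0.033, "DTC": 0.015, "Unknown": 0.009,
}
_DEFAULT_FEATURE_FRACTIONS = {
    "intergenic": 0.687, "intron": 0.168, "UTR": 0.107, "CDS": 0.038,
}


@dataclass
class SimConfig:
    """Study conditions for all generators (see module docstring)."""

    seed: int = 0
    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 1_500_000
    n_genes: int = 100
    n_tes: int = 2000
    te_category_fractions: dict = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_FRACTIONS))
    nested_fractions: dict = field(
        default_factory=lambda: dict(_DEFAULT_NESTED_FRACTIONS))
    te_superfamily_weights: dict = field(
        default_factory=lambda: dict(_DEFAULT_SF_WEIGHTS))
    max_intergenic_dist: int = 7000
    # divergence landscape
    n_divergence_records: int = 2000
    burst_fraction: float = 0.7
    burst_scale: float = 0.002
    burst_max: float = 0.01
    old_component_range: tuple = (0.04, 0.13)
    # TIP cohort: two populations, 9 + 11 individuals
    n_individuals: tuple = (9, 11)
    pop_labels: tuple = ("HD", "YC")
    n_tips: int = 400
    fixed_diff_fraction: float = 0.05
    maf_beta_params: tuple = (0.5, 3.0)
    tip_superfamily_weights: dict = field(
        default_factory=lambda: dict(_DEFAULT_TIP_SF_WEIGHTS))
    feature_fractions: dict = field(
        default_factory=lambda: dict(_DEFAULT_FEATURE_FRACTIONS))
    nonref_fraction: float = 0.937
    depth_mean: float = 20.0
    noise_read_rate: float = 0.1
    na_rate: float = 0.02
    # SNP background: per haplotype block, two diverged regional haplotype
    # groups with homozygous individuals (strong structure/selfing) and
    # per-site discordance noise; blocks are independent so no single
    # genome-wide axis dominates the genotype space
    n_snps: int = 3200
    snp_spacing: int = 50
    ld_block_snps: int = 800
    haplotype_discordance: float = 0.05
    ld_tagged_fraction: float = 0.5
    # expression counts: 3 replicates x 2 ecotypes
    n_features: int = 2000
    n_reps: int = 3
    de_fraction: float = 0.1
    effect_size: float = 4.0
    nb_dispersion: float = 50.0
    expr_mean: float = 100.0   # median of the lognormal baseline mean
    expr_sigma: float = 1.0    # lognormal sigma of the baseline mean

    def __post_init__(self) -> None:
        for name in ("te_category_fractions", "nested_fractions",
                     "feature_fractions"):
            fr = getattr(self, name)
            if abs(sum(fr.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_tes", "n_tips",
                     "n_snps", "n_features", "n_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.burst_fraction <= 1):
            raise ValueError("burst_fraction in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("n_individuals", "pop_labels", "maf_beta_params",
                    "old_component_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _weighted_choice(rng, weights: dict, size: int) -> np.ndarray:
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    w = w / w.sum()
    return rng.choice(keys, size=size, p=w)


# ---------------------------------------------------------------------------
# annotation generator
# ---------------------------------------------------------------------------

def _make_gene(rng, chrom: str, slot_lo: int, slot_hi: int, gid: str) -> GeneModel:
    """One gene centered in its slot: 2-4 exons, introns, UTRs at both ends."""
    n_ex = int(rng.integers(2, 5))
    exon_lens = rng.integers(250, 601, size=n_ex)
    intron_lens = rng.integers(400, 901, size=n_ex - 1)
    span = int(exon_lens.sum() + intron_lens.sum())
    strand = "+" if rng.random() < 0.5 else "-"
    start = slot_lo + (slot_hi - slot_lo - span) // 2
    exons = []
    pos = start
    for i in range(n_ex):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
        pos += int(exon_lens[i])
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    end = pos
    u5 = int(rng.integers(150, 251))
    u3 = int(rng.integers(150, 251))
    first, last = exons[0], exons[-1]
    left_utr = GenomicInterval(chrom, first.start, first.start + u5, strand)
    right_utr = GenomicInterval(chrom, last.end - u3, last.end, strand)
    if strand == "+":
        utr5, utr3 = [left_utr], [right_utr]
    else:
        utr5, utr3 = [right_utr], [left_utr]
    cds = []
    for i, ex in enumerate(exons):
        lo, hi = ex.start, ex.end
        if i == 0:
            lo = left_utr.end
        if i == n_ex - 1:
            hi = right_utr.start
        if lo < hi:
            cds.append(GenomicInterval(chrom, lo, hi, strand))
    return GeneModel(id=gid, interval=GenomicInterval(chrom, start, end, strand),
                     exons=exons, cds=cds, utr5=utr5, utr3=utr3)


def _place_intergenic(rng, gene: GeneModel, side_upstream: bool, d: int,
                      te_len: int, chrom: str) -> GenomicInterval:
    strand = gene.strand
    left = (strand == "+") == side_upstream  # genomic-left placement?
    if left:
        end = gene.interval.start - d
        return GenomicInterval(chrom, end - te_len, end, ".")
    start = gene.interval.end + d
    return GenomicInterval(chrom, start, start + te_len, ".")


def gen_annotation(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Genes + TE copies with a recorded true relation category per TE.

    Returns ``(genes, tes, chrom_sizes, truth)`` where truth is a DataFrame
    with columns te_id, chrom, start, end, superfamily, category, gene_id,
    distance. Categories are sampled from the configured target fractions
    (promoter insertions arise from upstream placements within 1 kb of the
    TSS and are recorded as such).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    sizes = {c: cfg.chrom_length for c in chroms}

    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    gi = 0
    for c in chroms:
        n_here = min(per_chrom, cfg.n_genes - gi)
        slot = cfg.chrom_length // max(n_here, 1)
        for k in range(n_here):
            gi += 1
            genes.append(_make_gene(rng, c, k * slot, (k + 1) * slot, f"gene_{gi:04d}"))
        if gi >= cfg.n_genes:
            continue
    slot_margin = min(
        (cfg.chrom_length // per_chrom - 5200) // 2, 20_000
    )  # worst-case gene span ~5.1 kb

    cats = _weighted_choice(rng, cfg.te_category_fractions, cfg.n_tes)
    sfs = _weighted_choice(rng, cfg.te_superfamily_weights, cfg.n_tes)
    tes: list[TECopy] = []
    truth_rows = []
    for i in range(cfg.n_tes):
        cat = cats[i]
        te_id = f"te_{i + 1:05d}"
        placed = None
        true_cat, gene_id, dist = None, None, None
        for _attempt in range(100):
            g = genes[int(rng.integers(len(genes)))]
            chrom = g.interval.chrom
            if cat in ("upstream", "downstream"):
                te_len = int(rng.integers(100, 2001))
                d_max = min(cfg.max_intergenic_dist, slot_margin - te_len - 10)
                if d_max < 1:
                    continue
                d = int(rng.integers(0, d_max + 1))
                placed = _place_intergenic(rng, g, cat == "upstream", d, te_len, chrom)
                if cat == "upstream":
                    true_cat = "promoter" if d <= 1000 else "upstream"
                else:
                    true_cat = "downstream"
                gene_id, dist = g.id, d
            elif cat == "overlap":
                five = rng.random() < 0.5
                out = int(rng.integers(20, 1001))
                ins = int(rng.integers(20, min(500, g.interval.length - 20)))
                if (g.strand == "+") == five:
                    placed = GenomicInterval(chrom, g.interval.start - out,
                                             g.interval.start + ins, ".")
                else:
                    placed = GenomicInterval(chrom, g.interval.end - ins,
                                             g.interval.end + out, ".")
                true_cat, gene_id = ("overlap5" if five else "overlap3"), g.id
            else:  # nested
                sub = _weighted_choice(rng, cfg.nested_fractions, 1)[0]
                placed = _place_nested(rng, g, sub)
                if placed is None:
                    continue
                true_cat, gene_id = sub, g.id
            if placed is not None:
                break
        if placed is None:
            raise RuntimeError(f"could not place TE of category {cat!r}")
        tes.append(TECopy(id=te_id, interval=placed, superfamily=str(sfs[i])))
        truth_rows.append({
            "te_id": te_id, "chrom": placed.chrom, "start": placed.start,
            "end": placed.end, "superfamily": str(sfs[i]),
            "category": true_cat, "gene_id": gene_id,
            "distance": dist if dist is not None else -1,
        })
    truth = pd.DataFrame(truth_rows)
    return genes, tes, sizes, truth


def _place_nested(rng, g: GeneModel, sub: str) -> Optional[GenomicInterval]:
    chrom = g.interval.chrom
    if sub == "intron":
        introns = g.introns
        if not introns:
            return None
        iv = introns[int(rng.integers(len(introns)))]
        if iv.length < 60:
            return None
        te_len = int(rng.integers(40, iv.length - 10))
        start = iv.start + int(rng.integers(1, iv.length - te_len))
        return GenomicInterval(chrom, start, start + te_len, ".")
    if sub in ("utr5", "utr3"):
        segs = g.utr5 if sub == "utr5" else g.utr3
        iv = segs[int(rng.integers(len(segs)))]
        if iv.length < 40:
            return None
        te_len = int(rng.integers(20, iv.length - 10))
        start = iv.start + int(rng.integers(1, iv.length - te_len))
        return GenomicInterval(chrom, start, start + te_len, ".")
    if sub == "cds":
        big = [c for c in g.cds if c.length >= 80]
        if not big:
            return None
        iv = big[int(rng.integers(len(big)))]
        te_len = int(rng.integers(30, iv.length - 10))
        start = iv.start + int(rng.integers(1, iv.length - te_len))
        return GenomicInterval(chrom, start, start + te_len, ".")
    # exon_intron: span an internal exon/intron junction
    introns = g.introns
    if not introns:
        return None
    k = int(rng.integers(len(introns)))
    intron = introns[k]
    exon = g.exons[k]  # the exon genomically preceding intron k
    a = int(rng.integers(10, min(100, exon.length - 10)))
    b = int(rng.integers(10, min(100, intron.length - 10)))
    return GenomicInterval(chrom, exon.end - a, intron.start + b, ".")


# ---------------------------------------------------------------------------
# TIP cohort generator
# ---------------------------------------------------------------------------

@dataclass
class SimTipCohort:
    """All inputs + ground truth for the TIP module."""

    candidates: pd.DataFrame       # tidy per-(locus, individual) records
    median_depth: pd.Series        # individual -> genome-wide median depth
    pops: pd.Series                # individual -> population label
    snp_positions: pd.DataFrame    # snp id -> chrom, pos
    snp_dosages: pd.DataFrame      # snps x individuals, 0/1/2
    tip_positions: pd.DataFrame    # locus -> chrom, pos
    truth_genotypes: pd.DataFrame  # loci x individuals, planted 0/1
    truth_loci: pd.DataFrame       # locus -> superfamily, feature, fixed, ld_class, maf


def gen_tip_cohort(cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> SimTipCohort:
    """Two-population TIP cohort with planted genotypes, fixed differences,
    founder-haplotype SNP LD structure, and per-individual read support.

    Carrier read support is Poisson(depth_mean / 2) (the insertion haplotype
    carries roughly half the reads); non-carriers get 0 reads or occasional
    stray support of at most 2 reads, so the >= 3-read filter is the
    discriminating rule. Flank depths are means over 100 bp, hence tightly
    concentrated around the genome-wide median; a small dropout rate plants
    low-coverage NA sites. The SNP background is two diverged regional
    haplotype groups with homozygous individuals (heavy structure/selfing)
    plus per-site discordance noise, giving the strong local SNP-SNP LD of a
    real flanking panel. "Tagged" TIPs sit on one haplotype group (copying
    the nearest SNP's presence pattern -> high relative LD); untagged TIPs
    are drawn independently of the SNP background (low relative LD);
    fixed-difference loci separate the populations.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    nA, nB = cfg.n_individuals
    popA, popB = cfg.pop_labels
    individuals = ([f"{popA}_{i + 1:02d}" for i in range(nA)]
                   + [f"{popB}_{i + 1:02d}" for i in range(nB)])
    pops = pd.Series([popA] * nA + [popB] * nB, index=individuals, name="pop")
    n_ind = nA + nB

    # SNP background on one chromosome, in independent haplotype blocks
    snp_pos = np.arange(1, cfg.n_snps + 1) * cfg.snp_spacing
    n_blocks = max(1, cfg.n_snps // cfg.ld_block_snps)
    block_of = np.minimum(np.arange(cfg.n_snps) // (cfg.n_snps // n_blocks),
                          n_blocks - 1)
    anc = (rng.random(cfg.n_snps) < 0.5).astype(np.int8)
    group_idx = rng.integers(2, size=(n_ind, n_blocks))  # individual x block
    hap = np.where(group_idx[:, block_of] == 0, anc[None, :], 1 - anc[None, :])
    hap = hap.astype(np.int8)
    flips = rng.random(hap.shape) < cfg.haplotype_discordance
    hap[flips] = 1 - hap[flips]
    dosages = (2 * hap).T  # snps x individuals, homozygous 0/2
    snp_ids = [f"snp_{i + 1:05d}" for i in range(cfg.n_snps)]
    snp_positions = pd.DataFrame({"chrom": "chr1", "pos": snp_pos}, index=snp_ids)
    snp_dosages = pd.DataFrame(dosages, index=snp_ids, columns=individuals)

    # plant TIP loci
    n_fixed = int(round(cfg.n_tips * cfg.fixed_diff_fraction))
    n_tagged = int(round((cfg.n_tips - n_fixed) * cfg.ld_tagged_fraction))
    kinds = (["fixed"] * n_fixed + ["tagged"] * n_tagged
             + ["untagged"] * (cfg.n_tips - n_fixed - n_tagged))
    rng.shuffle(kinds)

    # TIP insertion points sit inside block interiors so each 300-SNP flank
    # window stays (mostly) within one haplotype block
    block_len = cfg.n_snps // n_blocks
    margin = min(300, block_len // 3)
    tip_block = rng.integers(n_blocks, size=cfg.n_tips)
    offset = rng.integers(margin, block_len - margin, size=cfg.n_tips)
    tip_pos = np.sort(cfg.snp_spacing * (tip_block * block_len + offset))
    loci = [f"tip_{i + 1:04d}" for i in range(cfg.n_tips)]
    sfs = _weighted_choice(rng, cfg.tip_superfamily_weights, cfg.n_tips)
    feats = _weighted_choice(rng, cfg.feature_fractions, cfg.n_tips)

    G = np.zeros((cfg.n_tips, n_ind), dtype=np.int8)
    ld_class = []
    a, b = cfg.maf_beta_params
    is_A = np.array([p == popA for p in pops])
    for i, kind in enumerate(kinds):
        if kind == "fixed":
            carrier_pop = is_A if rng.random() < 0.5 else ~is_A
            G[i] = carrier_pop.astype(np.int8)
            ld_class.append("none")
        elif kind == "tagged":
            # ride the haplotype pattern of the nearest polymorphic SNP
            order = np.argsort(np.abs(snp_pos - tip_pos[i]))
            for s in order:
                g = (dosages[s] >= 1).astype(np.int8)
                if 0 < g.sum() < n_ind:
                    break
            G[i] = g
            ld_class.append("high")
        else:
            while True:
                p = rng.beta(a, b)
                g = (rng.random(n_ind) < p).astype(np.int8)
                if g.any():
                    break
            G[i] = g
            ld_class.append("low")

    # read support and flank coverage
    med = cfg.depth_mean
    carrier = G.astype(bool)
    reads = np.zeros_like(G, dtype=np.int64)
    reads[carrier] = rng.poisson(med / 2.0, size=int(carrier.sum()))
    stray = (~carrier) & (rng.random(G.shape) < cfg.noise_read_rate)
    reads[stray] = rng.integers(1, 3, size=int(stray.sum()))
    flank_up = rng.poisson(med * 100, size=G.shape) / 100.0
    flank_dn = rng.poisson(med * 100, size=G.shape) / 100.0
    dropout = rng.random(G.shape) < cfg.na_rate
    reads[dropout] = 0
    flank_up[dropout] = rng.poisson(med * 10, size=int(dropout.sum())) / 100.0
    flank_dn[dropout] = rng.poisson(med * 10, size=int(dropout.sum())) / 100.0

    tip_types = np.where(rng.random(cfg.n_tips) < cfg.nonref_fraction,
                         "non_reference_insertion", "reference_absence")
    rows = []
    for i, locus in enumerate(loci):
        for j, ind in enumerate(individuals):
            rows.append((locus, "chr1", int(tip_pos[i]), str(sfs[i]),
                         str(tip_types[i]), ind, int(reads[i, j]),
                         float(flank_up[i, j]), float(flank_dn[i, j])))
    candidates = pd.DataFrame(rows, columns=[
        "locus_id", "chrom", "pos", "superfamily", "tip_type", "individual",
        "supporting_reads", "flank_up_cov", "flank_down_cov",
    ])
    truth_genotypes = pd.DataFrame(G, index=loci, columns=individuals)
    truth_genotypes = truth_genotypes.mask(pd.DataFrame(dropout, index=loci,
                                                        columns=individuals))
    p_all = pd.DataFrame(G, index=loci, columns=individuals).mean(axis=1)
    # a locus is truly fixed iff its planted genotypes split the populations
    # perfectly, whatever kind planted it
    pa = G[:, is_A].mean(axis=1)
    pb = G[:, ~is_A].mean(axis=1)
    truly_fixed = ((pa == 1.0) & (pb == 0.0)) | ((pa == 0.0) & (pb == 1.0))
    truth_loci = pd.DataFrame({
        "superfamily": sfs, "feature_context": feats, "tip_type": tip_types,
        "fixed": truly_fixed, "ld_class": ld_class,
        "true_maf": np.minimum(p_all, 1 - p_all),
        "chrom": "chr1", "pos": tip_pos,
    }, index=pd.Index(loci, name="locus_id"))
    median_depth = pd.Series(med, index=individuals, name="median_depth")
    tip_positions = truth_loci[["chrom", "pos"]]
    return SimTipCohort(candidates, median_depth, pops, snp_positions,
                        snp_dosages, tip_positions, truth_genotypes, truth_loci)


def attach_cohort_metadata(gm, cohort: SimTipCohort) -> None:
    """Attach population labels, feature context, superfamily and positions
    from a simulated cohort to a called genotype matrix (in place)."""
    gm.pops = cohort.pops
    gm.features = cohort.truth_loci["feature_context"].reindex(gm.loci)
    gm.superfamilies = cohort.truth_loci["superfamily"].reindex(gm.loci)
    gm.positions = cohort.truth_loci[["chrom", "pos"]].reindex(gm.loci)


# ---------------------------------------------------------------------------
# divergence and count generators
# ---------------------------------------------------------------------------

def gen_divergences(cfg: SimConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> list[DivergenceRecord]:
    """Per-copy divergences: a recent burst (exponential below ``burst_max``)
    plus an older uniform component on ``old_component_range``."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    n = cfg.n_divergence_records
    sfs = _weighted_choice(rng, cfg.te_superfamily_weights, n)
    out = []
    lo, hi = cfg.old_component_range
    for i in range(n):
        if rng.random() < cfg.burst_fraction:
            k = float(rng.exponential(cfg.burst_scale))
            while k >= cfg.burst_max:
                k = float(rng.exponential(cfg.burst_scale))
        else:
            k = float(rng.uniform(lo, hi))
        out.append(DivergenceRecord(
            te_id=f"te_{i + 1:05d}", superfamily=str(sfs[i]),
            divergence=k, aligned_bp=int(rng.integers(200, 5001)),
        ))
    return out


def gen_counts(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Negative-binomial count matrix for 2 ecotypes x n_reps replicates with
    a planted DE fraction at ``effect_size``-fold (random direction).

    Returns ``(counts, groups, truth)``; truth has columns is_de, direction,
    true_log2fc."""
    rng = rng or np.random.default_rng(cfg.seed + 3)
    n = cfg.n_features
    samples = ([f"red_{i + 1}" for i in range(cfg.n_reps)]
               + [f"white_{i + 1}" for i in range(cfg.n_reps)])
    groups = pd.Series(["red"] * cfg.n_reps + ["white"] * cfg.n_reps,
                       index=samples, name="group")
    base = rng.lognormal(mean=np.log(cfg.expr_mean), sigma=cfg.expr_sigma, size=n)
    is_de = rng.random(n) < cfg.de_fraction
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    direction[~is_de] = 0.0
    mean_red = base
    mean_white = base * (cfg.effect_size ** direction)

    def nb(mean_vec):
        size = cfg.nb_dispersion
        p = size / (size + mean_vec)
        return rng.negative_binomial(size, p)

    cols = {}
    for s in samples[: cfg.n_reps]:
        cols[s] = nb(mean_red)
    for s in samples[cfg.n_reps:]:
        cols[s] = nb(mean_white)
    ids = [f"feat_{i + 1:05d}" for i in range(n)]
    counts = pd.DataFrame(cols, index=ids)
    truth = pd.DataFrame({
        "is_de": is_de, "direction": direction,
        "true_log2fc": direction * np.log2(cfg.effect_size),
    }, index=ids)
    return counts, groups, truth
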