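"""TE insertion polymorphism (TIP) population genetics.

Candidate TIP loci (from split-read detection, consumed here as a tidy
table of per-individual supporting reads and flank coverages) are filtered
into presence(1)/absence(0)/NA genotype calls; downstream statistics cover
the folded site-frequency spectrum stratified by genomic feature and
superfamily, fixed inter-population differences, PCA of the genotype
matrix, and a relative linkage-disequilibrium classifier that ranks each
TIP's LD with flanking SNPs against the local SNP-SNP background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

logger = logging.getLogger(__name__)

MAF_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
MAF_BIN_LABELS = ("0.0-0.1", "0.1-0.2", "0.2-0.3", "0.3-0.4", "0.4-0.5")


@dataclass
class GenotypeMatrix:
    """TIP presence/absence calls with per-individual and per-locus metadata.

    ``calls``: loci x individuals, values 0.0 / 1.0 / NaN.
    ``pops``: individual -> population label.
    ``features``: locus -> genomic feature context (CDS/intron/UTR/intergenic).
    ``superfamilies``: locus -> TE superfamily.
    ``positions``: locus -> chrom, pos (insertion point, internal coords).
    """

    calls: pd.DataFrame
    pops: Optional[pd.Series] = None
    features: Optional[pd.Series] = None
    superfamilies: Optional[pd.Series] = None
    positions: Optional[pd.DataFrame] = None

    @property
    def loci(self) -> pd.Index:
        return self.calls.index

    @property
    def individuals(self) -> pd.Index:
        return self.calls.columns


def call_genotypes(
    candidates: pd.DataFrame,
    median_depth: pd.Series,
    min_reads: int = 3,
    cov_consistent: float = 0.8,
    cov_low: float = 0.2,
) -> GenotypeMatrix:
    """Filter TIP candidates into a presence/absence/NA genotype matrix.

    ``candidates`` is a tidy table with one row per (locus, individual):
    columns locus_id, individual, supporting_reads, flank_up_cov,
    flank_down_cov, and optionally chrom/pos/superfamily/tip_type.

    A locus is retained only if at least one individual reaches
    ``min_reads`` supporting reads. Per individual the call is

    * presence (1) when supporting_reads >= min_reads;
    * absence (0) when supporting_reads < min_reads and both flank depths
      reach ``cov_consistent`` x that individual's genome-wide median depth
      (positive evidence that the reference state is fully covered);
    * NA otherwise (too little coverage to assert either state; flanks
      below ``cov_low`` x median are always insufficient).
    """
    req = {"locus_id", "individual", "supporting_reads", "flank_up_cov", "flank_down_cov"}
    missing = req - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")

    reads = candidates.pivot(index="locus_id", columns="individual",
                             values="supporting_reads")
    up = candidates.pivot(index="locus_id", columns="individual", values="flank_up_cov")
    dn = candidates.pivot(index="locus_id", columns="individual", values="flank_down_cov")
    med = median_depth.reindex(reads.columns)
    if med.isna().any():
        raise ValueError("median_depth missing for some individuals")

    keep = (reads >= min_reads).any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d loci with < %d supporting reads in every individual",
                    n_drop, min_reads)
    reads, up, dn = reads[keep], up[keep], dn[keep]

    presence = reads >= min_reads
    ref_ok = (up.ge(cov_consistent * med, axis=1)
              & dn.ge(cov_consistent * med, axis=1))
    calls = pd.DataFrame(np.nan, index=reads.index, columns=reads.columns)
    calls[presence] = 1.0
    calls[~presence & ref_ok] = 0.0

    all_na = calls.isna().all(axis=1)
    if all_na.any():
        logger.info("dropped %d all-NA loci", int(all_na.sum()))
        calls = calls[~all_na]

    meta_cols = [c for c in ("chrom", "pos", "superfamily", "tip_type")
                 if c in candidates.columns]
    sf = pos = None
    if meta_cols:
        meta = candidates.drop_duplicates("locus_id").set_index("locus_id")
        meta = meta.reindex(calls.index)
        if "superfamily" in meta_cols:
            sf = meta["superfamily"]
        if {"chrom", "pos"} <= set(meta_cols):
            pos = meta[["chrom", "pos"]]
    return GenotypeMatrix(calls=calls, superfamilies=sf, positions=pos)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def maf_spectrum(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus folded minor allele frequency over non-NA calls.

    Loci with fewer than two non-NA calls are excluded (logged); monomorphic
    loci (MAF = 0) are flagged so downstream statistics can drop them.
    Columns: maf, n_calls, monomorphic.
    """
    n_calls = gm.calls.notna().sum(axis=1)
    informative = n_calls >= 2
    n_skip = int((~informative).sum())
    if n_skip:
        logger.info("excluded %d loci with < 2 non-NA calls", n_skip)
    p = gm.calls[informative].mean(axis=1)
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame({
        "maf": maf,
        "n_calls": n_calls[informative],
        "monomorphic": maf == 0.0,
    })


def sfs_histogram(maf: pd.Series, drop_monomorphic: bool = True) -> pd.Series:
    """Folded SFS: counts of polymorphic loci in MAF bins (0,0.1]...(0.4,0.5].

    The first bin contains 0 < maf <= 0.1 when monomorphic loci are dropped
    (the default), else 0 <= maf <= 0.1.
    """
    vals = maf[maf > 0] if drop_monomorphic else maf
    cut = pd.cut(vals, bins=list(MAF_BIN_EDGES), labels=list(MAF_BIN_LABELS),
                 include_lowest=not drop_monomorphic)
    return cut.value_counts().reindex(list(MAF_BIN_LABELS), fill_value=0)


def sfs_crosstab(gm: GenotypeMatrix, by: str = "feature") -> pd.DataFrame:
    """MAF-bin x group counts (group = feature context or superfamily)."""
    spec = maf_spectrum(gm)
    spec = spec[~spec["monomorphic"]]
    if by == "feature":
        if gm.features is None:
            raise ValueError("genotype matrix has no feature contexts")
        groups = gm.features.reindex(spec.index)
    elif by == "superfamily":
        if gm.superfamilies is None:
            raise ValueError("genotype matrix has no superfamilies")
        groups = gm.superfamilies.reindex(spec.index)
    else:
        raise ValueError("by must be 'feature' or 'superfamily'")
    bins = pd.cut(spec["maf"], bins=list(MAF_BIN_EDGES), labels=list(MAF_BIN_LABELS))
    return pd.crosstab(bins, groups, dropna=False)


def fixed_differences(gm: GenotypeMatrix, popA: str, popB: str) -> list[str]:
    """Loci where all non-NA calls are 1 in one population and 0 in the other.

    Loci lacking a non-NA call in either population are not evaluated.
    """
    if gm.pops is None:
        raise ValueError("genotype matrix has no population labels")
    a_cols = gm.pops[gm.pops == popA].index
    b_cols = gm.pops[gm.pops == popB].index
    A = gm.calls[a_cols]
    B = gm.calls[b_cols]
    a_n = A.notna().sum(axis=1)
    b_n = B.notna().sum(axis=1)
    a_mean = A.mean(axis=1)
    b_mean = B.mean(axis=1)
    ok = (a_n >= 1) & (b_n >= 1)
    fixed = ok & (((a_mean == 1.0) & (b_mean == 0.0))
                  | ((a_mean == 0.0) & (b_mean == 1.0)))
    return list(gm.calls.index[fixed])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(gm: GenotypeMatrix, n_components: int = 2) -> pd.DataFrame:
    """Principal components of individuals from the TIP genotype matrix.

    Monomorphic loci are dropped, NA calls are imputed to the locus mean,
    locus columns are mean-centered, and components are sign-fixed so the
    largest-|loading| locus has a positive loading. Explained variance
    ratios are attached as ``result.attrs['explained_variance_ratio']``.
    """
    n_ind = gm.calls.shape[1]
    if n_ind < n_components:
        raise ValueError(f"{n_ind} individuals < {n_components} components")
    spec = maf_spectrum(gm)
    keep = spec.index[~spec["monomorphic"]]
    X = gm.calls.loc[keep].T.to_numpy(dtype=float)  # individuals x loci
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X = X - X.mean(axis=0)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    for j in range(n_components):
        load = model.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    out = pd.DataFrame(scores, index=gm.calls.columns,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    out.attrs["explained_variance_ratio"] = model.explained_variance_ratio_.tolist()
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over individuals
    with both values non-NA. NaN when either vector is monomorphic or fewer
    than two complete pairs remain."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = ~(np.isnan(x) | np.isnan(y))
    if m.sum() < 2:
        return float("nan")
    xv, yv = x[m], y[m]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise r^2 of a complete snps x individuals matrix;
    monomorphic rows yield NaN pairs which are dropped."""
    sd = dosages.std(axis=1)
    ok = sd > 0
    d = dosages[ok]
    if d.shape[0] < 2:
        return np.array([])
    c = np.corrcoef(d)
    iu = np.triu_indices(d.shape[0], k=1)
    return (c[iu] ** 2).astype(float)


@dataclass
class LDProfile:
    """LD of one TIP against its flanking SNP panel."""

    locus_id: str
    tip_snp_r2: np.ndarray
    snp_snp_r2: np.ndarray
    summary_r2: float
    quantile: float
    ld_class: str  # low | mid | high
    prop_high_tip: dict = field(default_factory=dict)   # threshold -> proportion
    prop_high_snp: dict = field(default_factory=dict)
    n_snps: int = 0


def ld_classify(
    tip_calls: pd.Series,
    tip_chrom: str,
    tip_pos: int,
    snp_positions: pd.DataFrame,
    snp_dosages: pd.DataFrame,
    n_flank: int = 300,
    hi: float = 0.4,
    stat: str = "max",
    locus_id: str = "tip",
) -> LDProfile:
    """Relative LD class of one TIP versus its flanking SNP background.

    The nearest ``n_flank`` SNPs upstream and downstream of the insertion
    point are selected (fewer at chromosome ends, logged). r^2 is the
    squared Pearson correlation of dosage vectors over individuals with
    both calls non-NA; monomorphic pairs are skipped. The TIP's summary
    statistic (max tip-SNP r^2 by default, mean optional) is placed in the
    empirical distribution of pairwise SNP-SNP r^2 from the same panel, and
    the resulting quantile q maps to terciles: low (q < 1/3),
    mid (1/3 <= q < 2/3), high (q >= 2/3). High-LD proportions are also
    reported at the ``hi`` threshold and at 0.2.
    """
    on_chrom = snp_positions[snp_positions["chrom"] == tip_chrom]
    up_ids = on_chrom.index[on_chrom["pos"] < tip_pos]
    dn_ids = on_chrom.index[on_chrom["pos"] >= tip_pos]
    up_sel = up_ids[np.argsort(tip_pos - on_chrom.loc[up_ids, "pos"])][:n_flank]
    dn_sel = dn_ids[np.argsort(on_chrom.loc[dn_ids, "pos"] - tip_pos)][:n_flank]
    sel = list(up_sel) + list(dn_sel)
    if len(up_sel) < n_flank or len(dn_sel) < n_flank:
        logger.info("%s: only %d upstream / %d downstream SNPs available",
                    locus_id, len(up_sel), len(dn_sel))
    panel = snp_dosages.loc[sel]
    ind = tip_calls.index.intersection(panel.columns)
    tip = tip_calls[ind].to_numpy(dtype=float)
    D = panel[ind].to_numpy(dtype=float)

    tip_r2 = np.array([r_squared(tip, D[i]) for i in range(D.shape[0])])
    tip_r2 = tip_r2[~np.isnan(tip_r2)]
    snp_r2 = _pairwise_r2(D)
    snp_r2 = snp_r2[~np.isnan(snp_r2)]

    if tip_r2.size == 0 or snp_r2.size == 0:
        return LDProfile(locus_id, tip_r2, snp_r2, float("nan"), float("nan"),
                         "low", {}, {}, len(sel))
    summary = float(tip_r2.max() if stat == "max" else tip_r2.mean())
    q = float(np.mean(snp_r2 <= summary))
    ld_class = "low" if q < 1 / 3 else ("mid" if q < 2 / 3 else "high")
    prop_tip = {thr: float(np.mean(tip_r2 > thr)) for thr in (hi, 0.2)}
    prop_snp = {thr: float(np.mean(snp_r2 > thr)) for thr in (hi, 0.2)}
    return LDProfile(locus_id, tip_r2, snp_r2, summary, q, ld_class,
                     prop_tip, prop_snp, len(sel))


def ld_classify_all(
    gm: GenotypeMatrix,
    snp_positions: pd.DataFrame,
    snp_dosages: pd.DataFrame,
    n_flank: int = 300,
    hi: float = 0.4,
    stat: str = "max",
) -> pd.DataFrame:
    """LD class per TIP locus (requires ``gm.positions``)."""
    if gm.positions is None:
        raise ValueError("genotype matrix has no locus positions")
    rows = []
    for locus in gm.loci:
        prof = ld_classify(
            gm.calls.loc[locus], str(gm.positions.loc[locus, "chrom"]),
            int(gm.positions.loc[locus, "pos"]), snp_positions, snp_dosages,
            n_flank=n_flank, hi=hi, stat=stat, locus_id=str(locus),
        )
        rows.append({
            "locus_id": locus, "summary_r2": prof.summary_r2,
            "quantile": prof.quantile, "ld_class": prof.ld_class,
            "prop_tip_high": prof.prop_high_tip.get(hi, float("nan")),
            "prop_snp_high": prof.prop_high_snp.get(hi, float("nan")),
            "n_snps": prof.n_snps,
        })
    return pd.DataFrame(rows).set_index("locus_id")
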