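"""Readers and writers for the external formats the pipeline touches.

All conversions between external conventions and the internal 0-based
half-open convention happen here and only here. GFF3 is 1-based inclusive;
RepeatMasker ``.out`` query coordinates are 1-based inclusive; BED and
chrom-sizes files are already 0-based half-open / plain lengths.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .models import GeneModel, GenomicInterval, SUPERFAMILIES, TECopy

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# ---------------------------------------------------------------------------
# repeat class/family string -> (te_class, order, superfamily)
# ---------------------------------------------------------------------------

_CLASS_PATTERNS: list[tuple[str, tuple[str, str, str]]] = [
    (r"^LTR/Gypsy", ("retrotransposon", "LTR", "Gypsy")),
    (r"^LTR/(Ty3|Gypsy)", ("retrotransposon", "LTR", "Gypsy")),
    (r"^LTR/(Copia|Ty1)", ("retrotransposon", "LTR", "Copia")),
    (r"^LTR", ("retrotransposon", "LTR", "Unknown")),
    (r"^LINE", ("retrotransposon", "LINE", "nLTR")),
    (r"^SINE", ("retrotransposon", "SINE", "nLTR")),
    (r"^(PLE|Penelope)", ("retrotransposon", "PLE", "nLTR")),
    (r"^DIRS", ("retrotransposon", "DIRS", "nLTR")),
    (r"^(DNA|TIR)/(Mutator|MuDR|MULE|DTM)", ("DNA", "TIR", "DTM")),
    (r"^(DNA|TIR)/(CACTA|EnSpm|CMC|DTC)", ("DNA", "TIR", "DTC")),
    (r"^(DNA|TIR)/(hAT|DTA)", ("DNA", "TIR", "DTA")),
    (r"^(DNA|TIR)/(PIF|Harbinger|Tourist|DTH)", ("DNA", "TIR", "DTH")),
    (r"^(DNA|TIR)/(Tc1|TcMar|Mariner|DTT)", ("DNA", "TIR", "DTT")),
    (r"^(RC|DNA)/Helitron", ("DNA", "Helitron", "Helitron")),
    (r"^Helitron", ("DNA", "Helitron", "Helitron")),
    (r"^MITE", ("DNA", "MITE", "MITE")),
]
_CLASS_PATTERNS = [(re.compile(p, re.IGNORECASE), v) for p, v in _CLASS_PATTERNS]


def parse_te_class(class_string: str) -> tuple[str, Optional[str], str]:
    """Map a RepeatMasker/EDTA class string to (te_class, order, superfamily).

    Unparseable strings fall into the "Unknown" sink (never fatal).
    """
    s = class_string.strip()
    for pat, (cls, order, sf) in _CLASS_PATTERNS:
        if pat.match(s):
            return cls, order, sf
    if s in SUPERFAMILIES:
        order = {"Gypsy": "LTR", "Copia": "LTR", "Helitron": "Helitron",
                 "MITE": "MITE", "nLTR": "LINE"}.get(s, "TIR")
        cls = "retrotransposon" if order in ("LTR", "LINE") else "DNA"
        return cls, order, s
    logger.debug("unparseable TE class string %r -> Unknown", class_string)
    return "unknown", None, "Unknown"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(col9: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for field in col9.strip().split(";"):
        field = field.strip()
        if not field:
            continue
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _parse_gff3_line(line: str, lineno: int):
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise ValueError(f"malformed GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
    chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError as e:
        raise ValueError(f"malformed GFF3 line {lineno}: non-integer coordinates") from e
    if end1 < start1:
        raise ValueError(f"malformed GFF3 line {lineno}: end {end1} < start {start1}")
    if strand not in ("+", "-", ".", "?"):
        strand = "."
    if strand == "?":
        strand = "."
    # 1-based inclusive -> 0-based half-open
    return chrom, ftype, start1 - 1, end1, strand, _parse_attributes(attrs)


_GENE_TYPES = {"gene"}
_TX_TYPES = {"mRNA", "transcript"}
_EXON_TYPES = {"exon"}
_CDS_TYPES = {"CDS"}
_UTR5_TYPES = {"five_prime_UTR", "5UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR", "three_prime_utr"}


def read_genes_gff3(path: PathLike, tss_bed: Optional[PathLike] = None) -> list[GeneModel]:
    """Read gene models from GFF3.

    Genes are assembled from the gene/mRNA/exon/CDS/UTR hierarchy; the first
    mRNA per gene (file order) is the representative transcript. Genes with
    no exon records get a single exon covering the gene span. When UTRs are
    absent but CDS is present, exon portions outside the CDS extent are
    assigned to the 5'/3' UTR strand-aware.

    An optional BED file of predicted TSS positions (name column = gene id)
    overrides the default 5'-end TSS per gene.
    """
    genes: dict[str, dict] = {}
    gene_order: list[str] = []
    tx_to_gene: dict[str, str] = {}
    gene_rep_tx: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            chrom, ftype, start, end, strand, attrs = _parse_gff3_line(line, lineno)
            if ftype in _GENE_TYPES:
                gid = attrs.get("ID", f"gene_{lineno}")
                genes[gid] = {
                    "interval": GenomicInterval(chrom, start, end, strand),
                    "exons": [], "cds": [], "utr5": [], "utr3": [],
                }
                gene_order.append(gid)
            elif ftype in _TX_TYPES:
                tid = attrs.get("ID", f"tx_{lineno}")
                parent = attrs.get("Parent")
                if parent in genes and parent not in gene_rep_tx:
                    gene_rep_tx[parent] = tid
                if parent is not None:
                    tx_to_gene[tid] = parent
            elif ftype in _EXON_TYPES | _CDS_TYPES | _UTR5_TYPES | _UTR3_TYPES:
                parent = attrs.get("Parent", "")
                for p in parent.split(","):
                    gid = tx_to_gene.get(p, p)
                    if gid not in genes:
                        continue
                    # only the representative transcript contributes
                    if p in tx_to_gene and gene_rep_tx.get(gid) != p:
                        continue
                    iv = GenomicInterval(chrom, start, end, strand)
                    if ftype in _EXON_TYPES:
                        genes[gid]["exons"].append(iv)
                    elif ftype in _CDS_TYPES:
                        genes[gid]["cds"].append(iv)
                    elif ftype in _UTR5_TYPES:
                        genes[gid]["utr5"].append(iv)
                    else:
                        genes[gid]["utr3"].append(iv)

    out: list[GeneModel] = []
    for gid in gene_order:
        rec = genes[gid]
        if not rec["exons"]:
            rec["exons"] = [rec["interval"]]
        if rec["cds"] and not rec["utr5"] and not rec["utr3"]:
            rec["utr5"], rec["utr3"] = _derive_utrs(
                rec["exons"], rec["cds"], rec["interval"].strand
            )
        out.append(GeneModel(id=gid, **rec))

    if tss_bed is not None:
        overrides = read_tss_bed(tss_bed)
        for g in out:
            if g.id in overrides:
                g.tss_override = overrides[g.id]
    return out


def _derive_utrs(exons, cds, strand):
    """Exon portions outside the CDS extent become UTRs (strand-aware)."""
    cds_lo = min(iv.start for iv in cds)
    cds_hi = max(iv.end for iv in cds)
    left, right = [], []
    for ex in exons:
        if ex.start < cds_lo:
            left.append(GenomicInterval(ex.chrom, ex.start, min(ex.end, cds_lo), ex.strand))
        if ex.end > cds_hi:
            right.append(GenomicInterval(ex.chrom, max(ex.start, cds_hi), ex.end, ex.strand))
    if strand == "-":
        return right, left
    return left, right


def read_tes_gff3(path: PathLike, max_divergence: float = 0.40) -> list[TECopy]:
    """Read TE copies from GFF3 (one feature row per copy).

    Superfamily is taken from a ``superfamily`` attribute when present, else
    parsed from a ``Classification`` attribute (EDTA style, e.g. "LTR/Gypsy").
    Rows whose divergence attribute exceeds ``max_divergence`` are dropped.
    """
    out: list[TECopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            chrom, ftype, start, end, strand, attrs = _parse_gff3_line(line, lineno)
            if ftype in _GENE_TYPES | _TX_TYPES | _EXON_TYPES | _CDS_TYPES:
                continue
            te_id = attrs.get("ID", f"te_{lineno}")
            if "superfamily" in attrs and attrs["superfamily"] in SUPERFAMILIES:
                sf = attrs["superfamily"]
                cls, order, _ = parse_te_class(attrs.get("Classification", sf))
            else:
                cls, order, sf = parse_te_class(attrs.get("Classification", ftype))
            div = attrs.get("divergence")
            divergence = float(div) if div is not None else None
            if divergence is not None and divergence > max_divergence:
                continue
            out.append(TECopy(
                id=te_id,
                interval=GenomicInterval(chrom, start, end, strand),
                te_class=cls, order=order, superfamily=sf,
                family=attrs.get("family"),
                intact=attrs.get("intact", "false").lower() in ("true", "1", "yes"),
                divergence=divergence,
            ))
    return out


def read_gff3(path: PathLike, feature_types: str = "genes", **kw):
    """Dispatching reader: ``feature_types`` is ``"genes"`` or ``"tes"``."""
    if feature_types == "genes":
        return read_genes_gff3(path, **kw)
    if feature_types == "tes":
        return read_tes_gff3(path, **kw)
    raise ValueError(f"feature_types must be 'genes' or 'tes', got {feature_types!r}")


def write_genes_gff3(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\ttelandscape\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.id}\n")
            tid = f"{g.id}.t1"
            fh.write(f"{iv.chrom}\ttelandscape\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={tid};Parent={g.id}\n")
            for ex in g.exons:
                fh.write(f"{iv.chrom}\ttelandscape\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\tParent={tid}\n")
            for c in g.cds:
                fh.write(f"{iv.chrom}\ttelandscape\tCDS\t{c.start + 1}\t{c.end}\t.\t{iv.strand}\t0\tParent={tid}\n")
            for u in g.utr5:
                fh.write(f"{iv.chrom}\ttelandscape\tfive_prime_UTR\t{u.start + 1}\t{u.end}\t.\t{iv.strand}\t.\tParent={tid}\n")
            for u in g.utr3:
                fh.write(f"{iv.chrom}\ttelandscape\tthree_prime_UTR\t{u.start + 1}\t{u.end}\t.\t{iv.strand}\t.\tParent={tid}\n")


def write_tes_gff3(tes: Sequence[TECopy], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tes:
            iv = t.interval
            attrs = [f"ID={t.id}", f"superfamily={t.superfamily}"]
            if t.family:
                attrs.append(f"family={t.family}")
            if t.intact:
                attrs.append("intact=true")
            if t.divergence is not None:
                attrs.append(f"divergence={t.divergence:.4f}")
            fh.write(
                f"{iv.chrom}\ttelandscape\tdispersed_repeat\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: PathLike, max_divergence: float = 0.40,
                          chain_by_id: bool = True) -> list[TECopy]:
    """Parse a RepeatMasker ``.out`` alignment table into TE copies.

    The standard layout has 3 header lines then whitespace-separated columns:
    score, %div, %del, %ins, query, qbegin, qend, qleft, strand, repeat,
    class/family, rbegin, rend, rleft, ID. Divergence = %div / 100; rows
    above ``max_divergence`` are dropped. Rows sharing an ID in the last
    column (same-chromosome fragments of one element split by the aligner)
    are chained into one copy spanning min(start)-max(end), with a
    length-weighted mean divergence.
    """
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    body = lines[3:] if len(lines) >= 3 else []
    for lineno, line in enumerate(body, 4):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 14:
            raise ValueError(f"malformed RepeatMasker line {lineno}: {len(f)} fields")
        div = float(f[1]) / 100.0
        chrom = f[4]
        start1, end1 = int(f[5]), int(f[6])
        if end1 < start1:
            raise ValueError(f"malformed RepeatMasker line {lineno}: end < start")
        strand = "+" if f[8] == "+" else "-"
        repeat_name, class_fam = f[9], f[10]
        rid = f[14] if len(f) > 14 else str(lineno)
        rows.append((chrom, start1 - 1, end1, strand, repeat_name, class_fam, div, rid))

    out: list[TECopy] = []
    if chain_by_id:
        groups: dict[tuple[str, str], list] = {}
        order: list[tuple[str, str]] = []
        for r in rows:
            key = (r[0], r[7])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(r)
        counter = 0
        for key in order:
            grp = groups[key]
            counter += 1
            chrom = grp[0][0]
            start = min(r[1] for r in grp)
            end = max(r[2] for r in grp)
            lens = [r[2] - r[1] for r in grp]
            div = sum(r[6] * l for r, l in zip(grp, lens)) / sum(lens)
            if div > max_divergence:
                continue
            cls, ord_, sf = parse_te_class(grp[0][5])
            if sf == "Unknown":
                logger.info("RepeatMasker class %r -> Unknown superfamily", grp[0][5])
            out.append(TECopy(
                id=f"rm_{counter}",
                interval=GenomicInterval(chrom, start, end, grp[0][3]),
                te_class=cls, order=ord_, superfamily=sf,
                family=grp[0][4], divergence=div,
            ))
    else:
        for i, r in enumerate(rows, 1):
            if r[6] > max_divergence:
                continue
            cls, ord_, sf = parse_te_class(r[5])
            out.append(TECopy(
                id=f"rm_{i}",
                interval=GenomicInterval(r[0], r[1], r[2], r[3]),
                te_class=cls, order=ord_, superfamily=sf,
                family=r[4], divergence=r[6],
            ))
    return out


# ---------------------------------------------------------------------------
# BED / chrom sizes / TSS
# ---------------------------------------------------------------------------

def write_bed(records: Iterable, path: PathLike) -> None:
    """Write intervals (GenomicInterval or objects with ``.interval``/``.id``)
    as BED (BED6 when a name or non-'.' strand is available)."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec if isinstance(rec, GenomicInterval) else rec.interval
            name = getattr(rec, "id", ".")
            if name == "." and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise ValueError(f"malformed BED line {lineno}")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    """Two-column TSV (chrom, length) or FASTA index; extra columns ignored."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"malformed chrom-sizes line {lineno}")
            length = int(f[1])
            if length <= 0:
                raise ValueError(f"non-positive chromosome length at line {lineno}")
            out[f[0]] = length
    return out


def write_chrom_sizes(sizes: dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_tss_bed(path: PathLike) -> dict[str, int]:
    """BED of predicted TSS positions; name column = gene id, TSS = start."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) >= 4:
                out[f[3]] = int(f[1])
    return out


# ---------------------------------------------------------------------------
# dosage matrices / simple VCF genotypes
# ---------------------------------------------------------------------------

def read_vcf_dosages(path: PathLike):
    """Read a (possibly minimal) VCF into SNP dosages.

    Returns ``(positions_df, dosage_df)`` where positions_df has columns
    chrom/pos (pos internal 0-based) indexed by variant id and dosage_df is
    variants x samples with values 0/1/2 (missing -> NaN). Only the GT
    subfield is consulted.
    """
    import numpy as np
    import pandas as pd

    ids, chroms, poss, rows = [], [], [], []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                continue
            fmt = f[8].split(":")
            try:
                gti = fmt.index("GT")
            except ValueError:
                continue
            dosages = []
            for s in f[9:]:
                gt = s.split(":")[gti].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(int(a) > 0 for a in alleles)))
            vid = f[2] if f[2] != "." else f"{f[0]}:{f[1]}"
            ids.append(vid)
            chroms.append(f[0])
            poss.append(int(f[1]) - 1)
            rows.append(dosages)
    positions = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    dosage = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    return positions, dosage


def write_vcf_dosages(positions, dosage, path: PathLike) -> None:
    """Write diploid GT-only VCF from a 0/1/2 dosage matrix (variants x samples)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dosage.columns) + "\n")
        for vid in dosage.index:
            chrom = positions.loc[vid, "chrom"]
            pos1 = int(positions.loc[vid, "pos"]) + 1
            gts = []
            for v in dosage.loc[vid]:
                gts.append("./." if v != v else gt_map[int(v)])
            fh.write(f"{chrom}\t{pos1}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
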