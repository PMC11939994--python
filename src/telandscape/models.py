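"""Core genomic data types.

Every coordinate inside the package is 0-based half-open (BED convention):
an interval [start, end) of length ``end - start``. Readers convert external
conventions (GFF3 is 1-based inclusive) at the boundary; writers convert back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-", ".")

#: Closed superfamily vocabulary. Parsing never produces a label outside this
#: set plus the "Unknown" sink.
SUPERFAMILIES = (
    "Gypsy",
    "Copia",
    "DTM",      # Mutator
    "DTC",      # CACTA
    "DTA",      # hAT
    "DTH",      # PIF-Harbinger
    "DTT",      # Tc1-Mariner
    "Helitron",
    "MITE",
    "nLTR",     # LINE/SINE/PLE/DIRS collapsed
    "Unknown",
)

TE_ORDERS = ("LTR", "LINE", "SINE", "PLE", "DIRS", "TIR", "Helitron", "MITE")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome / scaffold identifier (non-empty).
    start, end : int
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """A gene with its representative transcript structure.

    ``exons`` are sorted, non-overlapping intervals. ``cds``/``utr5``/``utr3``
    partition the exons (UTRs derived from CDS extent when not annotated).
    Introns are the gaps between consecutive exons. The transcription start
    site defaults to the 5' end of the gene span (strand-aware) and can be
    overridden per gene from an external TSS file.
    """

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    tss_override: Optional[int] = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.id}: overlapping exons")
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        self.utr5 = sorted(self.utr5, key=lambda iv: iv.start)
        self.utr3 = sorted(self.utr3, key=lambda iv: iv.start)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware TSS position (a single bp, internal coordinates)."""
        if self.tss_override is not None:
            return self.tss_override
        if self.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start, self.strand))
        return out

    def feature_segments(self) -> list[tuple[str, GenomicInterval]]:
        """Partition of the exon span into typed segments, in genomic order.

        Segment types are ``utr5``, ``cds``, ``utr3`` (within exons) and
        ``intron`` (between exons). When UTRs/CDS are not annotated, whole
        exons count as ``cds``.
        """
        typed: list[tuple[str, GenomicInterval]] = []
        if self.cds or self.utr5 or self.utr3:
            for kind, ivs in (("utr5", self.utr5), ("cds", self.cds), ("utr3", self.utr3)):
                typed.extend((kind, iv) for iv in ivs)
        else:
            typed.extend(("cds", iv) for iv in self.exons)
        typed.extend(("intron", iv) for iv in self.introns)
        typed.sort(key=lambda t: t[1].start)
        return typed


@dataclass
class TECopy:
    """One annotated transposable-element interval."""

    id: str
    interval: GenomicInterval
    te_class: str = "unknown"          # retrotransposon | DNA | unknown
    order: Optional[str] = None        # one of TE_ORDERS
    superfamily: str = "Unknown"
    family: Optional[str] = None
    intact: bool = False
    divergence: Optional[float] = None  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"superfamily {self.superfamily!r} outside vocabulary")
        if self.divergence is not None and not (0.0 <= self.divergence <= 1.0):
            raise ValueError(f"divergence {self.divergence} outside [0, 1]")


#: Positional relationship categories of a TE to its nearest gene.
CATEGORIES = (
    "promoter",
    "upstream",
    "downstream",
    "overlap5",
    "overlap3",
    "intron",
    "utr5",
    "utr3",
    "cds",
    "exon_intron",
    "unanchored",
)

#: Categories where the TE lies inside the gene body.
NESTED_CATEGORIES = ("intron", "utr5", "utr3", "cds", "exon_intron")

#: Categories carrying a distance to the gene.
DISTANCE_CATEGORIES = ("promoter", "upstream", "downstream")


@dataclass
class RelationshipRecord:
    """Category of one TE relative to its nearest gene."""

    te_id: str
    gene_id: Optional[str]
    category: str
    distance: Optional[int] = None
    spanned_features: list[tuple[str, int]] = field(default_factory=list)
    superfamily: str = "Unknown"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        has_dist = self.distance is not None
        if has_dist != (self.category in DISTANCE_CATEGORIES):
            raise ValueError(
                f"distance must be present iff category in {DISTANCE_CATEGORIES}"
            )
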