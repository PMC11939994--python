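# Methods

This note records the models, conventions, parameter choices and known
limitations behind `telandscape`, in the order a user meets them.

## Coordinates and vocabulary

All coordinates inside the package are 0-based half-open (BED-style);
readers convert at the boundary (GFF3 and RepeatMasker `.out` are 1-based
inclusive) and writers convert back, so interval arithmetic never carries
±1 bookkeeping. The TE superfamily vocabulary is closed — {Gypsy, Copia,
DTM, DTC, DTA, DTH, DTT, Helitron, MITE, nLTR} plus an "Unknown" sink —
and every class-string parser maps into it; unparseable strings are logged,
never fatal. RepeatMasker rows sharing an ID on the same chromosome are
chained into one copy spanning min(start)–max(end) with a length-weighted
mean divergence, mirroring common landscape-parsing practice; rows above
the 40 % divergence import filter are dropped. The representative
transcript of a gene is the first mRNA in file order; when UTRs are absent
but CDS present, exon portions outside the CDS extent become UTRs
strand-aware. The TSS defaults to the annotated 5′ gene end and can be
overridden per gene from a BED of predicted sites.

## TE–gene topology

Classification is a strict decision list. If the TE overlaps a gene body
(ties between genes: larger overlap, then smaller start, then id): crossing
the strand-aware 5′ boundary → `overlap5`; crossing the 3′ boundary →
`overlap3` (a TE engulfing a whole gene crosses both and resolves 5′-first —
a deliberate, orientation-biased tie-break); otherwise the TE is nested and
its overlap with every feature segment (5′UTR/CDS/3′UTR within exons,
introns between them) is integrated in transcription order — one segment
touched gives that segment's category, two or more give `exon_intron`.
Intergenic TEs go to the nearest gene by edge-to-edge gap (ties: smaller
start, then id), on the gene-strand-relative side; an upstream TE whose
gene-facing edge lies within the promoter window (default 1000 bp) of the
TSS is a `promoter` insertion. The proximity bin (default 5000 bp) is
closed: a TE at exactly 5 kb counts as near. For the nesting partition the
gene body is taken as the exon span; boundary-overlap checks use the gene
record's interval (these coincide in well-formed annotations).

The classifier is validated against a brute-force per-base-pair enumerator
on random small genomes (the test suite requires 100 % agreement on 1000
instances) and against a coordinate-mirroring antisymmetry check.

## TE islands

"TE content" of a window is the fraction of its bases covered by the union
of TE intervals — nested and fragmented copies never double-count. Windows
(default 500 kb, step 100 kb) start at 0; a terminal partial window covers
the remainder and is normalised by its true length; chromosomes shorter
than one window give a single full-length window. Islands are merges of
overlapping or abutting windows with coverage strictly greater than the
threshold (0.5); the merged region's TE fraction is recomputed exactly when
the TE set is supplied, else approximated by the mean window fraction.
Gene density uses a 2×2 table of gene counts (a gene is "inside" when its
midpoint is — avoiding double-counted boundary genes) versus kilobases of
sequence in/out of islands, with a two-sided Fisher exact test; degenerate
tables return p = 1 with a warning. Term enrichment is upper-tail
hypergeometric per term with Benjamini–Hochberg adjustment across terms;
terms without background genes are skipped.

## Divergence and age

`kimura2p` implements K = −½ ln((1 − 2P − Q)·√(1 − 2Q)) and raises outside
its domain (2P + Q ≥ 1 or 2Q ≥ 1: saturated alignments have no finite
distance). Insertion age is T = K_LTR/(2 μ), linear in K and 1/μ, with
μ = 1.3 × 10⁻⁸ substitutions/site/year as the default plant rate; ages are
reported in million years to 3 decimals (K = 0.026 ↦ 1.000 MYA). Age
landscapes bin aligned bp by divergence (bins [i·w, (i+1)·w), default
w = 0.01, last bin closed at the 0.40 ceiling); total mass is conserved and
re-binning with divisor widths folds exactly. Dating consumes LTR–LTR
divergence tables rather than detecting intact elements from sequence;
landscape divergences may be raw RepeatMasker percentages when true Kimura
values are unavailable, and callers should label which they supply.

## TIP genotypes and population genetics

A candidate locus survives only if some individual has ≥ 3 supporting
reads. Per individual: presence when reads ≥ 3; absence when reads < 3 *and*
both 100 bp flank depths reach 0.8× that individual's genome-wide median
(positive evidence the reference state is intact); otherwise NA. The 0.8
(consistent) and 0.2 (clearly-low) multipliers operationalise a qualitative
coverage-evidence rule and are configurable. Loci with fewer than two
non-NA calls are excluded from frequency statistics; monomorphic loci are
excluded from all downstream statistics. MAF is folded at 0.5 over non-NA
calls; spectra cross-tabulate by feature context and superfamily. A fixed
difference requires every non-NA call to be 1 in one population and 0 in
the other, with at least one informative call per population. PCA drops
monomorphic loci, imputes NA to the locus mean, mean-centres, and fixes
component signs so the largest-|loading| locus is positive.

LD: r² is the squared Pearson correlation of dosage vectors over
individuals complete in both (for phased binary data this equals the
classical D²/(p₁p₂q₁q₂), which the tests assert). Each TIP takes its
nearest 300 SNPs per side (fewer at ends, logged); its summary statistic is
the **maximum** TIP–SNP r² (the strongest tag; the mean is available), and
its class is the tercile of that statistic within the empirical pairwise
SNP–SNP r² distribution of the same 600-SNP panel: low (< 1/3),
mid (< 2/3), high (≥ 2/3). The published description of "ranked r² relative
to the median ranked r²" is ambiguous; the tercile rule was chosen because
exactly three classes are reported, and it is deliberately exposed as a
documented decision. High-LD proportions are also reported at the 0.4 and
0.2 thresholds.

## Expression

CPM scales each sample to 10⁶; the transcription flag defaults to full
breadth (reads spanning the entire feature), configurable because full
breadth is fragile at small scale. `naive_de` is a Welch test on
log₂(CPM+1) with BH adjustment — a deliberately simple, deterministic
engine for synthetic data and threshold bookkeeping, *not* a re-implementation
of negative-binomial DE models; externally computed stats tables feed
`de_filter` directly. The filter applies the printed inequalities exactly:
baseMean strictly > 10, |log₂FC| ≥ 2 non-strict, padj strictly < 0.05.
"Near" in the DE-TE × DE-gene intersection defaults to the same closed 5 kb
bin used for topology.

## The synthetic generators

The generators define the study conditions under which every property is
tested; their defaults are fixed and the tests do not tune them.

*Annotation*: 2 chromosomes × 1.5 Mb, 100 genes in regular slots (2–4
exons, 400–900 bp introns, ~200 bp UTRs), 2000 TEs placed by sampled
category — 45 % upstream / 42 % downstream / 10 % nested / 3 % overlap,
with nested subtypes in the proportions of a gene-dense compact genome and
intergenic distances up to 7 kb (promoters arise from upstream placements
≤ 1 kb). Slot geometry guarantees the intended gene is the nearest, so the
truth table scores the classifier without re-derivation. Superfamily
weights follow a Gypsy/Mutator-dominated genome.

*TIP cohort*: two populations of 9 and 11 individuals. Carrier read support
is Poisson(depth/2) at median depth 20 (the insertion haplotype carries
about half the reads); non-carriers get 0 reads or stray support ≤ 2, so
the ≥ 3-read rule is the discriminating filter; flank depths are means over
100 bp (Poisson(100·depth)/100), hence tight around the median; 2 % of
individual-locus observations drop to low coverage and plant NAs.
Non-fixed allele frequencies are Beta(0.5, 3) (a purifying-selection-like
folded SFS); a configurable fraction of loci are fixed between populations.
The SNP background is built from independent haplotype blocks (800 SNPs at
50 bp spacing): within a block each individual is homozygous for one of two
diverged haplotype groups, with 5 % per-site discordance — giving the
strong local SNP–SNP LD of a real flanking panel while no genome-wide axis
competes with the population split in PCA. "Tagged" TIPs copy the presence
pattern of their nearest SNP (true high relative LD); untagged TIPs are
drawn independently of the background (true low). The planted `fixed` flag
is computed from the realised genotypes, so coincidental perfect splits are
counted honestly.

*Divergences*: 70 % recent burst (exponential, scale 0.002, truncated below
0.01) + 30 % uniform on [0.04, 0.13] — a sharp zero peak plus an older
proliferation component.

*Counts*: 3 + 3 replicates, lognormal baseline means (median 100, σ = 1),
negative-binomial noise (size 50), 10 % DE at 4-fold in a random direction.
Power checks of the naive engine use an explicit low-noise configuration
(size 500, median 1000, σ = 0.5): with three replicates a Welch test has
~4 degrees of freedom, and near-complete power at 4-fold requires
well-measured features — a property of small-n designs, not of this
implementation.

What the generators do *not* emulate: sequence content (no bases are
simulated), TE fragmentation/nesting of annotations, isoform diversity,
LD decay within blocks, linked selection, mapping bias in read support, and
multi-mapping ambiguity in counts. Passing tests therefore demonstrate the
correctness of the computations under controlled conditions, not the
behaviour of upstream detectors on real data.

## Problem sizes

The test suite and the acceptance script run everything at deliberately
small scale — thousands of TEs, hundreds of TIP loci, 700–3200-SNP panels,
400-feature count matrices, 10–100 seeds per stochastic property — sizes at
which every property is measurable with tight Monte-Carlo error while the
whole suite stays fast and deterministic.

## Known limitations

Gene models keep one representative transcript; overlapping genes resolve
by largest overlap rather than reporting multiple relations; the island
fraction falls back to a window-mean approximation when TEs are not passed
to `call_islands`; `naive_de` underestimates dispersion-driven variance
relative to NB models and is unsuitable for real differential-expression
inference; the LD tercile rule is one defensible reading of an ambiguous
published description and alternative summaries (mean r², median split)
are exposed as options.
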