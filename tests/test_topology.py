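"""TE-gene classification against hand examples and the per-bp oracle."""

import numpy as np
import pandas as pd
import pytest

from telandscape.models import GeneModel, GenomicInterval, TECopy
from telandscape.topology import (
    TopologyParams,
    category_proportions,
    classify,
    classify_all,
    distance_profile,
    integrate_nested,
    relation_summary,
)

from .conftest import make_gene, random_layout, te
from .oracles import classify_oracle, spanned_oracle


class TestClassify:
    def test_te_inside_intron(self, two_exon_gene):
        rec = classify(te("chr1", 250, 260), [two_exon_gene])
        assert rec.category == "intron"
        assert rec.spanned_features == [("intron", 10)]

    def test_promoter_within_window(self, two_exon_gene):
        # TE ends 800 bp upstream of the TSS (gene start 100... use distant gene)
        g = make_gene("g", "chr1", [(5000, 5500), (6000, 6500)], "+")
        rec = classify(te("chr1", 4000, 4200), [g])
        assert rec.category == "promoter"
        assert rec.distance == 800

    def test_upstream_beyond_promoter_window(self):
        g = make_gene("g", "chr1", [(5000, 5500)], "+")
        rec = classify(te("chr1", 3000, 3200), [g])
        assert rec.category == "upstream"
        assert rec.distance == 1800

    def test_minus_strand_upstream_is_genomic_right(self):
        g = make_gene("g", "chr1", [(1000, 1500)], "-")
        rec = classify(te("chr1", 1700, 1800), [g])
        assert rec.category == "promoter"  # 200 bp from the minus-strand TSS
        rec2 = classify(te("chr1", 100, 200), [g])
        assert rec2.category == "downstream"

    def test_overlap5_and_overlap3(self):
        g = make_gene("g", "chr1", [(1000, 2000)], "+")
        assert classify(te("chr1", 900, 1100), [g]).category == "overlap5"
        assert classify(te("chr1", 1900, 2100), [g]).category == "overlap3"
        gm = make_gene("gm", "chr2", [(1000, 2000)], "-")
        assert classify(te("chr2", 1900, 2100), [gm]).category == "overlap5"

    def test_no_genes_on_chromosome_is_unanchored(self, two_exon_gene):
        rec = classify(te("chr9", 0, 100), [two_exon_gene])
        assert rec.category == "unanchored"
        assert rec.gene_id is None

    def test_empty_gene_list_unanchored(self):
        assert classify(te("chr1", 0, 10), []).category == "unanchored"

    def test_tss_override_moves_promoter_call(self):
        g = make_gene("g", "chr1", [(5000, 6000)], "+")
        g.tss_override = 5500
        # TE 300 bp before the gene edge but 800 bp before the overridden TSS
        rec = classify(te("chr1", 4500, 4700), [g])
        assert rec.category == "promoter"

    def test_oracle_equivalence_on_random_layouts(self, rng):
        """Sweep random small genomes: fast classifier == per-bp enumerator."""
        mismatches = 0
        n = 0
        for _ in range(60):
            genes = random_layout(rng)
            for _ in range(15):
                start = int(rng.integers(0, 11_500))
                length = int(rng.integers(1, 400))
                t = te("c", start, start + length)
                got = classify(t, genes).category
                exp = classify_oracle(t, genes)
                n += 1
                mismatches += got != exp
        assert n == 900
        assert mismatches == 0

    def test_strand_antisymmetry(self, rng):
        """Mirroring all coordinates while keeping strand labels flips every
        gene's orientation relative to its neighbourhood, so upstream and
        downstream counts swap exactly (and overlap5 <-> overlap3)."""
        L = 12_000
        genes = random_layout(rng, length=L)
        tes = []
        for i in range(300):
            s = int(rng.integers(0, L - 500))
            tes.append(te("c", s, s + int(rng.integers(1, 400)), f"t{i}"))

        def mirror_iv(iv):
            return GenomicInterval(iv.chrom, L - iv.end, L - iv.start, iv.strand)

        m_genes = []
        for g in genes:
            m_genes.append(GeneModel(
                id=g.id, interval=mirror_iv(g.interval),
                exons=[mirror_iv(e) for e in g.exons],
                cds=[mirror_iv(c) for c in g.cds],
                utr5=[mirror_iv(u) for u in g.utr5],
                utr3=[mirror_iv(u) for u in g.utr3],
            ))
        m_tes = [TECopy(id=t.id, interval=mirror_iv(t.interval),
                        superfamily=t.superfamily) for t in tes]

        # TEs spanning an entire gene cross both boundaries and resolve to
        # overlap5 by the 5'-precedence rule in either orientation; drop them
        keep = [t.id for t in tes
                if not any(t.interval.contains(g.interval) for g in genes)]

        def side_counts(recs):
            # promoter is the near-TSS slice of the upstream side
            s = pd.Series([r.category for r in recs
                           if r.te_id in set(keep)]).value_counts()
            return {
                "up_side": s.get("upstream", 0) + s.get("promoter", 0),
                "down_side": s.get("downstream", 0),
                "overlap5": s.get("overlap5", 0),
                "overlap3": s.get("overlap3", 0),
                "nested": sum(s.get(c, 0) for c in
                              ("intron", "utr5", "utr3", "cds", "exon_intron")),
            }

        fwd = side_counts(classify_all(tes, genes))
        rev = side_counts(classify_all(m_tes, m_genes))
        assert rev["up_side"] == fwd["down_side"]
        assert rev["down_side"] == fwd["up_side"]
        assert rev["overlap5"] == fwd["overlap3"]
        assert rev["overlap3"] == fwd["overlap5"]
        assert rev["nested"] == fwd["nested"]

    def test_partition_every_te_one_category(self, rng):
        genes = random_layout(rng)
        tes = [te("c", int(s), int(s) + 50, f"t{i}")
               for i, s in enumerate(rng.integers(0, 11_000, size=200))]
        recs = classify_all(tes, genes)
        assert len(recs) == 200
        assert all(r.category for r in recs)


class TestIntegrateNested:
    def test_te_spanning_exon_end_and_intron_start(self, two_exon_gene):
        t = te("chr1", 180, 230)  # 20 bp of exon1(cds) + 30 bp of intron
        spans = integrate_nested(t, two_exon_gene)
        assert spans == [("cds", 20), ("intron", 30)]
        assert sum(bp for _, bp in spans) == 50

    def test_te_identical_to_intron(self, two_exon_gene):
        t = te("chr1", 200, 300)
        assert integrate_nested(t, two_exon_gene) == [("intron", 100)]

    def test_te_covering_whole_gene_in_transcription_order(self):
        g = make_gene("g", "chr1", [(100, 200), (300, 400)], "-",
                      utr5_bp=30, utr3_bp=30)
        t = te("chr1", 50, 450)
        spans = integrate_nested(t, g)
        assert sum(bp for _, bp in spans) == 300  # gene length
        # minus strand: transcription order starts at the genomic right
        assert spans[0][0] == "utr5"
        assert spans[-1][0] == "utr3"

    def test_oracle_sums_on_random_nested_tes(self, rng):
        for _ in range(50):
            genes = random_layout(rng)
            g = genes[int(rng.integers(len(genes)))]
            lo = g.interval.start + int(rng.integers(0, g.interval.length - 1))
            hi = lo + int(rng.integers(1, g.interval.length))
            t = te("c", lo, min(hi, g.interval.end))
            spans = integrate_nested(t, g)
            exp = spanned_oracle(t, g)
            got = {}
            for k, bp in spans:
                got[k] = got.get(k, 0) + bp
            assert got == exp


class TestSummaries:
    def test_published_style_proportion_rounding(self):
        props = category_proportions({"upstream": 29_144}, total=63_665)
        assert props["upstream"] == 45.8

    def test_single_record_is_100_percent(self):
        from telandscape.models import RelationshipRecord
        rec = RelationshipRecord("t", "g", "upstream", distance=10,
                                 superfamily="Gypsy")
        mat = relation_summary([rec])
        assert mat.loc["upstream", "Gypsy"] == 1
        assert mat.loc["upstream", "Proportion_pct"] == 100.0

    def test_planted_fractions_recovered(self):
        """Synthetic genome with target category mix: summary proportions
        land within 0.5% of the targets at n = 20,000."""
        from telandscape.synthetic import SimConfig, gen_annotation
        from telandscape.topology import classify_all
        cfg = SimConfig(seed=11, n_tes=20_000, n_genes=200, n_chroms=2,
                        chrom_length=3_000_000)
        genes, tes, _, truth = gen_annotation(cfg)
        mat = relation_summary(classify_all(tes, genes))
        total = mat["Total"].drop("unanchored", errors="ignore").sum()
        up = mat.loc[["promoter", "upstream"], "Total"].sum() / total
        down = mat.loc["downstream", "Total"] / total
        assert up == pytest.approx(0.45, abs=0.01)
        assert down == pytest.approx(0.42, abs=0.01)

    def test_counts_sum_to_mapped_total(self, rng):
        genes = random_layout(rng)
        tes = [te("c", int(s), int(s) + 30, f"t{i}")
               for i, s in enumerate(rng.integers(0, 11_000, size=150))]
        mat = relation_summary(classify_all(tes, genes))
        assert mat["Total"].sum() == 150


class TestDistanceProfile:
    def _recs(self, distances):
        from telandscape.models import RelationshipRecord
        return [RelationshipRecord(f"t{i}", "g", "upstream", distance=d,
                                   superfamily="Gypsy")
                for i, d in enumerate(distances)]

    def test_bin_closed_at_5kb(self):
        prof = distance_profile(self._recs([5000, 5001]))
        assert prof.loc[("upstream", "Gypsy"), "within"] == 1
        assert prof.loc[("upstream", "Gypsy"), "beyond"] == 1

    def test_promoter_counts_on_upstream_side(self):
        from telandscape.models import RelationshipRecord
        recs = [RelationshipRecord("t", "g", "promoter", distance=500,
                                   superfamily="DTM")]
        prof = distance_profile(recs)
        assert prof.loc[("upstream", "DTM"), "within"] == 1

    def test_known_distance_cdf_bin_counts(self, rng):
        """Uniform(0, 10 kb) distances: P(within 5 kb) = 0.5001, counts match
        the binomial expectation within a 4-sigma band."""
        n = 4000
        dists = rng.integers(0, 10_001, size=n)
        prof = distance_profile(self._recs(list(dists)))
        within = prof.loc[("upstream", "Gypsy"), "within"]
        p = 5001 / 10001
        sd = np.sqrt(n * p * (1 - p))
        assert abs(within - n * p) < 4 * sd
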