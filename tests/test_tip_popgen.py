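"""TIP genotype calling, allele-frequency statistics, PCA and LD classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from telandscape.synthetic import SimConfig, attach_cohort_metadata, gen_tip_cohort
from telandscape.tip_popgen import (
    GenotypeMatrix,
    call_genotypes,
    fixed_differences,
    ld_classify,
    maf_spectrum,
    pca,
    r_squared,
    sfs_crosstab,
    sfs_histogram,
)

from .oracles import r2_haplotype_formula


def _cands(rows):
    return pd.DataFrame(rows, columns=[
        "locus_id", "individual", "supporting_reads",
        "flank_up_cov", "flank_down_cov",
    ])


MED = pd.Series({"i1": 20.0, "i2": 20.0, "i3": 20.0})


class TestCallGenotypes:
    def test_all_carriers_kept_and_called_present(self):
        rows = [("L1", f"i{k}", 5, 20.0, 20.0) for k in (1, 2, 3)]
        gm = call_genotypes(_cands(rows), MED)
        assert gm.calls.loc["L1"].tolist() == [1.0, 1.0, 1.0]

    def test_locus_below_min_reads_everywhere_dropped(self):
        rows = [("L1", f"i{k}", 2, 20.0, 20.0) for k in (1, 2, 3)]
        gm = call_genotypes(_cands(rows), MED)
        assert "L1" not in gm.calls.index

    def test_absence_needs_consistent_flanks(self):
        rows = [
            ("L1", "i1", 5, 20.0, 20.0),   # presence
            ("L1", "i2", 0, 20.0, 20.0),   # absence: both flanks >= 0.8 x median
            ("L1", "i3", 0, 20.0, 10.0),   # NA: downstream flank too low
        ]
        gm = call_genotypes(_cands(rows), MED)
        row = gm.calls.loc["L1"]
        assert row["i1"] == 1.0
        assert row["i2"] == 0.0
        assert np.isnan(row["i3"])

    def test_deterministic_and_column_permutation(self):
        rows = [("L1", "i1", 5, 20.0, 20.0), ("L1", "i2", 0, 20.0, 20.0),
                ("L1", "i3", 1, 20.0, 20.0)]
        a = call_genotypes(_cands(rows), MED).calls
        b = call_genotypes(_cands(list(reversed(rows))), MED).calls
        pd.testing.assert_frame_equal(a, b)

    def test_simulator_concordance(self):
        """Default simulator: >= 98% of non-NA calls match the planted
        genotypes; the misses sit at read-count extremes."""
        cfg = SimConfig(seed=3, n_tips=300, n_snps=700)
        co = gen_tip_cohort(cfg)
        gm = call_genotypes(co.candidates, co.median_depth)
        truth = co.truth_genotypes.reindex(gm.loci)
        both = gm.calls.notna() & truth.notna()
        conc = (gm.calls[both] == truth[both]).sum().sum() / both.sum().sum()
        assert conc >= 0.98


class TestMafSpectrum:
    def _gm(self, rows, inds=None):
        inds = inds or [f"i{k}" for k in range(1, len(rows[0]) + 1)]
        calls = pd.DataFrame(rows, columns=inds,
                             index=[f"L{j}" for j in range(len(rows))],
                             dtype=float)
        return GenotypeMatrix(calls=calls)

    def test_monomorphic_locus_flagged(self):
        spec = maf_spectrum(self._gm([[1, 1, 1, 1]]))
        assert spec.loc["L0", "maf"] == 0.0
        assert bool(spec.loc["L0", "monomorphic"])
        assert sfs_histogram(spec["maf"]).sum() == 0

    def test_hand_counted_maf_with_na(self):
        spec = maf_spectrum(self._gm([[1, 0, 0, 0, np.nan]],
                                     inds=list("abcde")))
        assert spec.loc["L0", "maf"] == pytest.approx(0.25)
        assert spec.loc["L0", "n_calls"] == 4

    def test_too_few_calls_excluded(self):
        spec = maf_spectrum(self._gm([[1, np.nan, np.nan]]))
        assert spec.empty

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=2, max_size=30))
    def test_maf_folding_symmetry(self, g):
        gm1 = self._gm([g], inds=[f"s{i}" for i in range(len(g))])
        gm2 = self._gm([[1 - x for x in g]],
                       inds=[f"s{i}" for i in range(len(g))])
        m1 = maf_spectrum(gm1)["maf"].iloc[0]
        m2 = maf_spectrum(gm2)["maf"].iloc[0]
        assert m1 == pytest.approx(m2)

    def test_beta_planted_sfs_decreasing(self):
        """Beta(0.5, 3) allele frequencies give a folded SFS that decreases
        across the five MAF bins, echoing purifying selection."""
        cfg = SimConfig(seed=9, n_tips=800, n_snps=700,
                        fixed_diff_fraction=0.0, ld_tagged_fraction=0.0)
        co = gen_tip_cohort(cfg)
        gm = call_genotypes(co.candidates, co.median_depth)
        attach_cohort_metadata(gm, co)
        hist = sfs_histogram(maf_spectrum(gm)["maf"])
        assert hist.iloc[0] > hist.iloc[-1]
        diffs = np.diff(hist.to_numpy())
        assert (diffs <= 0).mean() >= 0.75  # monotone up to binomial noise

    def test_crosstab_by_feature_covers_all_polymorphic_loci(self):
        cfg = SimConfig(seed=10, n_tips=200, n_snps=700)
        co = gen_tip_cohort(cfg)
        gm = call_genotypes(co.candidates, co.median_depth)
        attach_cohort_metadata(gm, co)
        spec = maf_spectrum(gm)
        tab = sfs_crosstab(gm, by="feature")
        assert tab.to_numpy().sum() == (~spec["monomorphic"]).sum()


class TestFixedDifferences:
    def _gm(self, a_calls, b_calls):
        n_a, n_b = len(a_calls), len(b_calls)
        inds = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
        calls = pd.DataFrame([a_calls + b_calls], columns=inds, index=["L"],
                             dtype=float)
        pops = pd.Series(["A"] * n_a + ["B"] * n_b, index=inds)
        return GenotypeMatrix(calls=calls, pops=pops)

    def test_clean_fixed_difference(self):
        assert fixed_differences(self._gm([1, 1, 1], [0, 0, 0]), "A", "B") == ["L"]

    def test_na_calls_ignored(self):
        gm = self._gm([1, 1, np.nan], [0, 0, 0])
        assert fixed_differences(gm, "A", "B") == ["L"]

    def test_polymorphic_population_not_fixed(self):
        assert fixed_differences(self._gm([1, 0, 1], [0, 0, 0]), "A", "B") == []

    def test_exact_recovery_with_noise_off(self):
        """With stray reads and dropout disabled and ample depth, the fixed
        loci found are exactly the planted set."""
        cfg = SimConfig(seed=21, n_tips=200, n_snps=700,
                        fixed_diff_fraction=0.15, noise_read_rate=0.0,
                        na_rate=0.0, depth_mean=40.0)
        co = gen_tip_cohort(cfg)
        gm = call_genotypes(co.candidates, co.median_depth)
        attach_cohort_metadata(gm, co)
        found = set(fixed_differences(gm, "HD", "YC"))
        planted = set(co.truth_loci.index[co.truth_loci["fixed"]])
        assert found == planted


class TestPCA:
    def test_identical_individuals_identical_coordinates(self, rng):
        calls = pd.DataFrame(rng.integers(0, 2, size=(30, 4)).astype(float),
                             columns=list("abcd"))
        calls["b"] = calls["a"]
        gm = GenotypeMatrix(calls=calls)
        coords = pca(gm)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_variance_ordering_nonincreasing(self, rng):
        calls = pd.DataFrame(rng.integers(0, 2, size=(50, 8)).astype(float),
                             columns=[f"s{i}" for i in range(8)])
        coords = pca(GenotypeMatrix(calls=calls), n_components=3)
        evr = coords.attrs["explained_variance_ratio"]
        assert all(a >= b for a, b in zip(evr, evr[1:]))

    def test_too_few_individuals_rejected(self):
        calls = pd.DataFrame([[1.0], [0.0]], columns=["only"],
                             index=["L1", "L2"])
        with pytest.raises(ValueError):
            pca(GenotypeMatrix(calls=calls), n_components=2)

    def test_two_population_separation(self):
        """20% planted fixed differences: PC1 separates the populations with
        no overlap for the vast majority of seeds."""
        sep = 0
        n_seed = 30
        for seed in range(n_seed):
            cfg = SimConfig(seed=seed, n_tips=120, fixed_diff_fraction=0.2)
            co = gen_tip_cohort(cfg)
            gm = call_genotypes(co.candidates, co.median_depth)
            attach_cohort_metadata(gm, co)
            coords = pca(gm)
            hd = coords.loc[gm.pops == "HD", "PC1"]
            yc = coords.loc[gm.pops == "YC", "PC1"]
            sep += (hd.max() < yc.min()) or (yc.max() < hd.min())
        assert sep / n_seed >= 0.95


class TestLD:
    def test_r2_identical_vectors_is_one(self):
        x = np.array([0, 1, 1, 0, 1], float)
        assert r_squared(x, x) == pytest.approx(1.0)

    def test_r2_haplotype_formula_equivalence(self, rng):
        """For phased binary data, squared Pearson correlation equals the
        classical D^2/(pA pa pB pb) haplotype formula."""
        for _ in range(50):
            n = int(rng.integers(8, 40))
            x = rng.integers(0, 2, size=n).astype(float)
            y = rng.integers(0, 2, size=n).astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            assert r_squared(x, y) == pytest.approx(
                r2_haplotype_formula(x, y), rel=1e-10)

    def test_eight_haplotype_hand_example(self):
        # x: 1 1 1 1 0 0 0 0 ; y: 1 1 1 0 1 0 0 0
        # pA = pB = 1/2, pAB = 3/8, D = 1/8, r^2 = (1/64)/(1/16) = 1/4
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0], float)
        assert r_squared(x, y) == pytest.approx(0.25)
        assert r2_haplotype_formula(x, y) == pytest.approx(0.25)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 2)),
                    min_size=5, max_size=40))
    def test_r2_symmetric_bounded_and_encoding_invariant(self, pairs):
        x = np.array([p[0] for p in pairs], float)
        y = np.array([p[1] for p in pairs], float)
        r2 = r_squared(x, y)
        if np.isnan(r2):
            return
        assert 0.0 <= r2 <= 1.0 + 1e-12
        assert r_squared(y, x) == pytest.approx(r2)
        assert r_squared(1 - x, y) == pytest.approx(r2)  # allele swap
        assert r_squared(x, 2 - y) == pytest.approx(r2)

    def test_tip_identical_to_snp_scores_one(self):
        cfg = SimConfig(seed=4, n_tips=10, n_snps=700)
        co = gen_tip_cohort(cfg)
        snp = co.snp_dosages.iloc[350]
        prof = ld_classify(
            (snp >= 1).astype(float), "chr1",
            int(co.snp_positions.iloc[350]["pos"]),
            co.snp_positions, co.snp_dosages, n_flank=300)
        assert prof.summary_r2 == pytest.approx(1.0)
        assert prof.ld_class == "high"

    def test_planted_ld_classes_recovered_across_seeds(self):
        """Tagged (haplotype-riding) vs untagged TIPs: the relative tercile
        classifier recovers high/low in >= 90% of seeds."""
        ok = 0
        n_seed = 25
        for seed in range(n_seed):
            cfg = SimConfig(seed=seed, n_tips=40, n_snps=700)
            co = gen_tip_cohort(cfg)
            gm = call_genotypes(co.candidates, co.median_depth)
            attach_cohort_metadata(gm, co)
            from telandscape.tip_popgen import ld_classify_all
            ld = ld_classify_all(gm, co.snp_positions, co.snp_dosages,
                                 n_flank=300)
            truth = co.truth_loci["ld_class"].reindex(ld.index)
            hi = (ld["ld_class"][truth == "high"] == "high").mean()
            lo = (ld["ld_class"][truth == "low"] == "low").mean()
            ok += (hi >= 0.9) and (lo >= 0.9)
        assert ok / n_seed >= 0.9

    def test_monomorphic_snps_skipped(self):
        inds = [f"i{k}" for k in range(6)]
        pos = pd.DataFrame({"chrom": ["c"] * 3, "pos": [10, 20, 30]},
                           index=["s1", "s2", "s3"])
        dos = pd.DataFrame([[1, 1, 1, 1, 1, 1],
                            [0, 1, 2, 0, 1, 2],
                            [2, 2, 0, 0, 1, 1]], index=["s1", "s2", "s3"],
                           columns=inds, dtype=float)
        tip = pd.Series([0, 1, 1, 0, 1, 0], index=inds, dtype=float)
        prof = ld_classify(tip, "c", 20, pos, dos, n_flank=2)
        assert len(prof.tip_snp_r2) == 2  # monomorphic s1 dropped
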