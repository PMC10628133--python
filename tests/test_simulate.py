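"""Generative model: covariates, expected maps, sampling, mixing, alleles."""

import numpy as np
import pytest

import hicdeconv as hd
from hicdeconv import scenarios as sc
from hicdeconv.genome import DerivedChromosome, Karyotype, Segment, make_bins
from hicdeconv.simulate import covariate_factor
from hicdeconv.sv import classify_pattern


class TestCovariates:
    def test_deterministic_given_seed(self, small_bins):
        a = hd.simulate_covariates(small_bins, seed=7)
        b = hd.simulate_covariates(small_bins, seed=7)
        assert np.array_equal(a.gc, b.gc)
        assert np.array_equal(a.compartment, b.compartment)

    def test_ranges(self, covariates):
        assert covariates.gc.min() >= 0.3 and covariates.gc.max() <= 0.6
        assert covariates.mappability.min() >= 0.5
        assert covariates.mappability.max() <= 1.0
        assert (covariates.cut_sites >= 0).all()

    def test_compartment_block_length(self):
        bins = make_bins({"chr1": 500_000_000}, 50_000)
        cov = hd.simulate_covariates(bins, seed=1, compartment_block_bins=20)
        runs = np.diff(np.flatnonzero(np.diff(cov.compartment) != 0))
        assert abs(runs.mean() - 20) / 20 < 0.10


class TestRenderExpectedMap:
    def test_uniform_covariates_power_law(self):
        bins = make_bins({"chr1": 5_000_000}, 50_000)
        k = Karyotype.diploid({"chr1": 5_000_000})
        params = hd.SimulationParams(compartment_strength=0.0)
        m = hd.render_expected_map([(k, 1.0)], bins, None, params)
        assert np.allclose(np.diag(m.counts), np.diag(m.counts)[0])
        row = m.counts[0, 1:]
        d = np.arange(1, len(row) + 1)
        expected = 2 * params.cis_scale * (d + 1.0) ** -1 + params.trans_scale * 4
        assert np.allclose(row, expected)

    def test_mixture_diagonal_dilution(self, small_sizes, small_bins):
        """50/50 diploid / chr5-monosomy: chr5 diagonal at 75% of diploid."""
        diploid = sc.diploid_karyotype(small_sizes)
        ders = [
            DerivedChromosome((Segment(c, 0, s),), 1 if c == "chr5" else 2)
            for c, s in small_sizes.items()
        ]
        mono = Karyotype(ders)
        params = hd.SimulationParams(compartment_strength=0.0)
        mix = hd.render_expected_map(
            [(diploid, 0.5), (mono, 0.5)], small_bins, None, params
        )
        pure = hd.render_expected_map([(diploid, 1.0)], small_bins, None, params)
        chr5 = small_bins.chrom_slice("chr5")
        ratio = np.diag(mix.counts)[chr5] / np.diag(pure.counts)[chr5]
        assert np.allclose(ratio, 0.75)

    def test_superposition_exact(
        self, small_bins, covariates, params, diploid, aneuploid
    ):
        mix = hd.render_expected_map(
            [(diploid, 0.3), (aneuploid, 0.7)], small_bins, covariates, params
        )
        a = hd.render_expected_map([(diploid, 1.0)], small_bins, covariates, params)
        b = hd.render_expected_map([(aneuploid, 1.0)], small_bins, covariates, params)
        assert np.allclose(
            mix.counts, 0.3 * a.counts + 0.7 * b.counts, rtol=1e-12, atol=1e-12
        )

    def test_weights_must_sum_to_one(self, small_bins, diploid):
        with pytest.raises(ValueError):
            hd.render_expected_map([(diploid, 0.5)], small_bins)

    @pytest.mark.parametrize(
        "strand_a, strand_b, expected_class",
        [("+", "+", "P1-NE"), ("-", "+", "P1-SE"), ("+", "-", "P1-NW")],
    )
    def test_fusion_corner_orientation(self, strand_a, strand_b, expected_class):
        """Junction enrichment sits in the quadrant set by segment strands."""
        sizes = {"chrA": 10_000_000, "chrB": 10_000_000}
        bins = make_bins(sizes, 50_000)
        half = 5_000_000
        seg_a = (
            Segment("chrA", 0, half, strand_a)
            if strand_a == "+"
            else Segment("chrA", half, sizes["chrA"], "-")
        )
        seg_b = (
            Segment("chrB", half, sizes["chrB"], strand_b)
            if strand_b == "+"
            else Segment("chrB", 0, half, "-")
        )
        ders = [DerivedChromosome((seg_a, seg_b),)]
        for c, s in sizes.items():
            ders.append(DerivedChromosome((Segment(c, 0, s),), 2))
        params = hd.SimulationParams(compartment_strength=0.0)
        m = hd.render_expected_map([(Karyotype(ders), 1.0)], bins, None, params)
        sa, sb = bins.chrom_slice("chrA"), bins.chrom_slice("chrB")
        block = m.counts[sa, sb]
        focal = np.unravel_index(np.argmax(block), block.shape)
        label, _ = classify_pattern(block, focal)
        assert label == expected_class

    def test_reciprocal_is_bowtie_nonreciprocal_single_corner(self, small_sizes):
        bins = sc.toy_bins(0.2)
        params = hd.SimulationParams(compartment_strength=0.0)
        recip = sc.reciprocal_karyotype(small_sizes)
        m = hd.render_expected_map([(recip, 1.0)], bins, None, params)
        sa, sb = bins.chrom_slice("chr3"), bins.chrom_slice("chr4")
        block = m.counts[sa, sb]
        focal = np.unravel_index(np.argmax(block), block.shape)
        label, _ = classify_pattern(block, focal)
        assert label.startswith("P2")
        fused = sc.fusion_karyotype(small_sizes)
        m1 = hd.render_expected_map([(fused, 1.0)], bins, None, params)
        b1 = m1.counts[bins.chrom_slice("chr1"), bins.chrom_slice("chr2")]
        focal1 = np.unravel_index(np.argmax(b1), b1.shape)
        label1, _ = classify_pattern(b1, focal1)
        assert label1.startswith("P1")


class TestSampleReads:
    def test_deterministic(self, expected_diploid):
        a = hd.sample_reads(expected_diploid, 1e5, seed=5)
        b = hd.sample_reads(expected_diploid, 1e5, seed=5)
        assert np.array_equal(a.counts, b.counts)

    def test_zero_expected_gives_zero_counts(self, small_bins):
        counts = np.zeros((small_bins.n_bins, small_bins.n_bins))
        counts[0, 0] = 5.0
        m = hd.ContactMap(small_bins, counts)
        s = hd.sample_reads(m, 1e4, seed=1)
        assert s.counts[1:, 1:].sum() == 0

    def test_total_depth_calibrated(self, expected_diploid):
        """E[total] = read_depth; totals within 3 sigma of Poisson."""
        totals = [
            hd.sample_reads(expected_diploid, 1e5, seed=s).total_reads
            for s in range(30)
        ]
        z = (np.mean(totals) - 1e5) / (np.sqrt(1e5) / np.sqrt(30))
        assert abs(z) < 3

    def test_overdispersion_increases_variance(self):
        """With a flat expectation, NB counts have Var ~ mu + 0.1 mu^2."""
        bins = make_bins({"chr1": 50_000_000}, 50_000)
        k = Karyotype.diploid({"chr1": 50_000_000})
        params = hd.SimulationParams(compartment_strength=0.0)
        em = hd.render_expected_map([(k, 1.0)], bins, None, params)
        depth = 50 * em.total_reads / (2 * params.cis_scale + params.trans_scale)
        diag_p = np.diag(hd.sample_reads(em, depth, seed=1).counts)
        diag_nb = np.diag(hd.sample_reads(em, depth, seed=1, dispersion=0.1).counts)
        mu = diag_p.mean()
        assert diag_p.var() < 2 * mu
        assert diag_nb.var() > mu + 0.05 * mu**2


class TestMixMaps:
    def test_degenerate_weight(self, diploid_reads, aneuploid_reads):
        out = hd.mix_maps([diploid_reads, aneuploid_reads], [1.0, 0.0])
        assert np.allclose(out.counts, diploid_reads.counts)

    def test_order_symmetric(self, diploid_reads, aneuploid_reads):
        a = hd.mix_maps([diploid_reads, aneuploid_reads], [0.3, 0.7],
                        target_total=1e6)
        b = hd.mix_maps([aneuploid_reads, diploid_reads], [0.7, 0.3],
                        target_total=1e6)
        assert np.allclose(a.counts, b.counts)

    def test_diagonal_linearity(self, diploid_reads, aneuploid_reads):
        mixed = hd.mix_maps([diploid_reads, aneuploid_reads], [0.4, 0.6],
                            target_total=1e6)
        da = hd.extract_diagonal(hd.depth_normalize(diploid_reads, 1e6)).values
        db = hd.extract_diagonal(hd.depth_normalize(aneuploid_reads, 1e6)).values
        assert np.allclose(hd.extract_diagonal(mixed).values, 0.4 * da + 0.6 * db)

    def test_equal_total_mixing_is_mean(self, diploid_reads, aneuploid_reads):
        t = 1e6
        a = hd.depth_normalize(diploid_reads, t)
        b = hd.depth_normalize(aneuploid_reads, t)
        mix = hd.mix_maps([a, b], [0.5, 0.5], target_total=t)
        assert np.allclose(mix.counts, (a.counts + b.counts) / 2)


class TestAlleleCounts:
    def test_normal_diploid_centered_at_half(self, small_bins, diploid):
        t = hd.simulate_allele_counts([(diploid, 1.0)], small_bins, 2000, 50, seed=3)
        frac = t.alt_count / (t.ref_count + t.alt_count)
        assert abs(frac.mean() - 0.5) < 0.01

    def test_trisomy_dilution_formula(self, small_sizes, small_bins, diploid):
        """f = 0.56 trisomy: mean alt fraction at (0.56*2+0.44)/(0.56*3+0.88)."""
        ders = []
        for c, s in small_sizes.items():
            for h in (0, 1):
                ders.append(DerivedChromosome((Segment(c, 0, s),), 1, h))
        ders.append(DerivedChromosome((Segment("chr1", 0, small_sizes["chr1"]),), 1, 0))
        tri = Karyotype(ders)
        t = hd.simulate_allele_counts(
            [(tri, 0.56), (diploid, 0.44)], small_bins, 6000, 200, seed=4
        )
        on1 = t[t.chrom == "chr1"]
        frac = on1.alt_count / (on1.ref_count + on1.alt_count)
        hi = frac[frac > 0.5].mean()
        lo = frac[frac < 0.5].mean()
        assert hi == pytest.approx(0.609, abs=0.02)
        assert lo == pytest.approx(0.391, abs=0.02)

    def test_cnloh_dilution(self, small_sizes, small_bins, diploid):
        """f = 0.63 copy-neutral LOH: peaks at 0.815 / 0.185."""
        ders = []
        for c, s in small_sizes.items():
            if c == "chr2":
                ders.append(DerivedChromosome((Segment(c, 0, s),), 2, 0))
            else:
                for h in (0, 1):
                    ders.append(DerivedChromosome((Segment(c, 0, s),), 1, h))
        loh = Karyotype(ders)
        t = hd.simulate_allele_counts(
            [(loh, 0.63), (diploid, 0.37)], small_bins, 6000, 200, seed=5
        )
        on2 = t[t.chrom == "chr2"]
        frac = on2.alt_count / (on2.ref_count + on2.alt_count)
        assert frac[frac > 0.5].mean() == pytest.approx(0.815, abs=0.02)
        assert frac[frac < 0.5].mean() == pytest.approx(0.185, abs=0.02)


class TestCovariateFactor:
    def test_geometric_mean_one(self, covariates, params):
        g = covariate_factor(covariates, params)
        assert np.exp(np.mean(np.log(g))) == pytest.approx(1.0)
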