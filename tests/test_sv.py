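"""Structural-variant detection: patterns, calibration, FDR, assignment."""

import numpy as np
import pytest

import hicdeconv as hd
from hicdeconv import scenarios as sc
from hicdeconv.purity import (
    ChangePoint,
    CopyNumberProfile,
    CopyNumberSegment,
    MixtureDecomposition,
    PopulationFit,
    decompose,
)
from hicdeconv.sv import (
    classify_pattern,
    detect_type1,
    detect_type2,
    fdr_control,
)


def _block_with(quadrants, size=21, focal=(10, 10), level=10.0):
    """Synthetic block with the named quadrants filled."""
    b = np.full((size, size), 0.1)
    i, j = focal
    fills = {
        "NW": (slice(0, i), slice(0, j)),
        "NE": (slice(0, i), slice(j + 1, size)),
        "SW": (slice(i + 1, size), slice(0, j)),
        "SE": (slice(i + 1, size), slice(j + 1, size)),
    }
    for q in quadrants:
        b[fills[q]] = level
    b[i, j] = level * 2
    return b


class TestClassifyPattern:
    @pytest.mark.parametrize("quad", ["NE", "NW", "SE", "SW"])
    def test_single_quadrant(self, quad):
        label, margin = classify_pattern(_block_with([quad]), (10, 10))
        assert label == f"P1-{quad}"
        assert margin > 0.2

    @pytest.mark.parametrize(
        "quads, expected", [(["NW", "SE"], "P2-main"), (["NE", "SW"], "P2-anti")]
    )
    def test_bowtie(self, quads, expected):
        label, _ = classify_pattern(_block_with(quads), (10, 10))
        assert label == expected

    def test_no_dominance_ambiguous(self):
        label, _ = classify_pattern(np.ones((21, 21)), (10, 10))
        assert label == "ambiguous"

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(np.empty((0, 0)), (0, 0))


class TestFdrControl:
    def test_hand_computed_bh(self):
        q, sig = fdr_control(np.array([0.001, 0.5, 0.9]), q=0.1)
        assert list(sig) == [True, False, False]
        assert q[0] == pytest.approx(0.003)

    def test_all_ones_nothing_significant(self):
        _, sig = fdr_control(np.ones(5), q=0.1)
        assert not sig.any()

    def test_q_values_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q, _ = fdr_control(p, q=0.1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


@pytest.fixture(scope="module")
def fusion_sample():
    """Half-scale genome: one type-1 fusion and one reciprocal, purity 0.5."""
    sizes = sc.toy_chrom_sizes(0.5)
    bins = sc.toy_bins(0.5)
    cov = hd.simulate_covariates(bins, seed=3)
    params = hd.SimulationParams()
    normal = sc.diploid_karyotype(sizes)
    fused = sc.fusion_karyotype(sizes)
    recip = sc.reciprocal_karyotype(sizes)
    em = hd.render_expected_map(
        [(fused, 0.25), (recip, 0.25), (normal, 0.5)], bins, cov, params
    )
    smp = hd.sample_reads(em, 1e7, seed=9)
    ref = hd.sample_reads(
        hd.render_expected_map([(normal, 1.0)], bins, cov, params), 1e7, seed=10
    )
    model = hd.fit_correction(hd.extract_diagonal(ref), cov)
    corr = hd.apply_correction(hd.extract_diagonal(smp), cov, model)
    deco = decompose(corr, seed=5)
    truth = {
        "t1": (
            bins.locus_to_bin("chr1", int(sizes["chr1"] * 0.6)),
            bins.locus_to_bin("chr2", int(sizes["chr2"] * 0.4)),
        ),
        "t2": (
            bins.locus_to_bin("chr3", int(sizes["chr3"] * 0.6)),
            bins.locus_to_bin("chr4", int(sizes["chr4"] * 0.4)),
        ),
    }
    return bins, smp, deco, truth


class TestDetectType1:
    def test_fusion_found_with_anchors_and_class(self, fusion_sample):
        bins, smp, deco, truth = fusion_sample
        calls = detect_type1(smp, deco, seed=1)
        inter = [c for c in calls if {c.chrom_a, c.chrom_b} == {"chr1", "chr2"}]
        assert len(inter) == 1
        c = inter[0]
        assert abs(c.bin_a - truth["t1"][0]) <= 2
        assert abs(c.bin_b - truth["t1"][1]) <= 2
        assert c.pattern_class == "P1-NE"

    def test_copy_number_assigned_from_coincident_step(self, fusion_sample):
        bins, smp, deco, truth = fusion_sample
        calls = detect_type1(smp, deco, seed=1)
        c = [c for c in calls if {c.chrom_a, c.chrom_b} == {"chr1", "chr2"}][0]
        assert c.assigned_population == deco.populations[0].label
        assert c.assigned_copy_number == 1

    def test_copy_change_without_fusion_not_called(
        self, diploid_reads, aneuploid_reads, covariates, reference_model
    ):
        """Arm gains/losses alone produce change points but no junction."""
        mix = hd.mix_maps([aneuploid_reads, diploid_reads], [0.5, 0.5])
        corr = hd.apply_correction(
            hd.extract_diagonal(mix), covariates, reference_model
        )
        deco = decompose(corr, seed=5)
        assert deco.change_points()
        calls = detect_type1(mix, deco, seed=1)
        assert calls == []


class TestDetectType2:
    def test_reciprocal_found_as_bowtie(self, fusion_sample):
        bins, smp, deco, truth = fusion_sample
        calls = detect_type2(smp, seed=2)
        on34 = [c for c in calls if {c.chrom_a, c.chrom_b} == {"chr3", "chr4"}]
        assert len(on34) == 1
        c = on34[0]
        assert c.pattern_class in ("P2-main", "P2-anti")
        assert abs(c.bin_a - truth["t2"][0]) <= 2
        assert abs(c.bin_b - truth["t2"][1]) <= 2

    def test_no_coincident_copy_change_at_reciprocal(self, fusion_sample):
        bins, smp, deco, truth = fusion_sample
        cps = [cp.bin for _, cp in deco.change_points()]
        assert all(abs(b - truth["t2"][0]) > 5 for b in cps)
        assert all(abs(b - truth["t2"][1]) > 5 for b in cps)

    def test_null_map_yields_no_calls(self, diploid_reads):
        calls = detect_type2(diploid_reads, seed=4)
        assert calls == []

    def test_compartment_checkerboard_rejected(self, small_sizes):
        """Strong A/B structure without any fusion must not trigger calls."""
        bins = sc.toy_bins(0.2)
        cov = hd.simulate_covariates(bins, seed=8, compartment_block_bins=15)
        params = hd.SimulationParams(compartment_strength=0.6)
        em = hd.render_expected_map(
            [(sc.diploid_karyotype(small_sizes), 1.0)], bins, cov, params
        )
        smp = hd.sample_reads(em, 2e6, seed=12)
        calls = detect_type2(smp, seed=4)
        assert calls == []

    def test_parameter_validation(self, diploid_reads):
        with pytest.raises(ValueError):
            detect_type2(diploid_reads, q0=0.5)
        with pytest.raises(ValueError):
            detect_type2(diploid_reads, min_component_size=2)


class TestNullCalibration:
    def test_type1_null_pvalues_stochastically_uniform_or_larger(
        self, small_bins, covariates, params, diploid
    ):
        """On fusion-free maps with injected anchors, candidate p-values
        must not concentrate at small values (one-sided KS check)."""
        em = hd.render_expected_map([(diploid, 1.0)], small_bins, covariates, params)
        pvals = []
        for seed in range(12):
            smp = hd.sample_reads(em, 2e6, seed=200 + seed)
            # inject artificial change points at fixed positions
            profile = CopyNumberProfile(
                segments=[], change_points=[
                    ChangePoint(bin=small_bins.chrom_slice(c).start + 60, delta_n=1)
                    for c in ("chr1", "chr2", "chr3")
                ],
            )
            fit = PopulationFit(
                fraction=0.5, profile=profile, discrepancy=0.0,
                improvement=1.0, f_grid=np.array([0.5]), d_curve=np.array([0.0]),
            )
            deco = MixtureDecomposition([fit], scale=1.0, discrepancy=0.0)
            calls = detect_type1(smp, deco, fdr=1.1, seed=seed)
            pvals.extend(c.p_value for c in calls)
        p = np.sort(pvals)
        ecdf = np.arange(1, len(p) + 1) / len(p)
        d_plus = float(np.max(ecdf - p))
        # ECDF may not exceed the uniform by more than the KS 1% band
        assert d_plus < 1.63 / np.sqrt(len(p))
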