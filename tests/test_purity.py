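"""Joint purity / copy-number inference: scale, scan, peeling, confidence."""

import numpy as np
import pytest

import hicdeconv as hd
from hicdeconv import scenarios as sc
from hicdeconv.contacts import DiagonalTrack
from hicdeconv.purity import (
    bootstrap_purity_ci,
    decompose,
    estimate_mode_scale,
    infer_single_population,
    peel_population,
    score_change_points,
)


def _track(bins, values, mask=None):
    if mask is None:
        mask = np.ones(bins.n_bins, bool)
    return DiagonalTrack(bins, np.asarray(values, float), mask)


@pytest.fixture
def noiseless_two_level(small_bins):
    """2.0 everywhere except chr5 = 1.5 and chr8 = 2.5."""
    vals = np.full(small_bins.n_bins, 2.0)
    vals[small_bins.chrom_slice("chr5")] = 1.5
    vals[small_bins.chrom_slice("chr8")] = 2.5
    return _track(small_bins, vals)


class TestModeScale:
    def test_tight_cluster(self, small_bins, rng):
        vals = 10.0 + 0.01 * rng.standard_normal(small_bins.n_bins)
        C = estimate_mode_scale(_track(small_bins, vals))
        assert C == pytest.approx(5.0, rel=0.01)

    def test_mode_resists_minority_aberration(self, small_bins, rng):
        vals = 10.0 + 0.05 * rng.standard_normal(small_bins.n_bins)
        chr5 = small_bins.chrom_slice("chr5")
        vals[chr5] = 5.0 + 0.05 * rng.standard_normal(chr5.stop - chr5.start)
        C = estimate_mode_scale(_track(small_bins, vals))
        assert C == pytest.approx(5.0, rel=0.02)

    def test_scale_equivariance(self, small_bins, rng):
        vals = 10.0 + 0.01 * rng.standard_normal(small_bins.n_bins)
        a = estimate_mode_scale(_track(small_bins, vals))
        b = estimate_mode_scale(_track(small_bins, 2 * vals))
        assert b == pytest.approx(2 * a, rel=1e-6)

    def test_balanced_bimodal_raises(self, small_bins, rng):
        half = small_bins.n_bins // 2
        vals = np.concatenate(
            [
                4.0 + 0.02 * rng.standard_normal(half),
                8.0 + 0.02 * rng.standard_normal(small_bins.n_bins - half),
            ]
        )
        with pytest.raises(ValueError, match="mode_copy_number"):
            estimate_mode_scale(_track(small_bins, vals))


class TestExactRecovery:
    def test_noiseless_two_level(self, small_bins, noiseless_two_level):
        fit = infer_single_population(noiseless_two_level, C=1.0)
        assert fit.fraction == pytest.approx(0.5, abs=1e-3)
        cn = fit.profile.cn_track(small_bins.n_bins)
        assert set(cn[small_bins.chrom_slice("chr5")]) == {1}
        assert set(cn[small_bins.chrom_slice("chr8")]) == {3}
        assert fit.discrepancy < 1e-4

    def test_brute_force_grid_agreement(self, small_bins, noiseless_two_level):
        """Exhaustive (f, n) enumeration finds the same optimum."""
        y = noiseless_two_level.values
        best = None
        for f in np.arange(0.05, 1.001, 0.01):
            for n5 in range(9):
                for n8 in range(9):
                    model = np.full_like(y, 2.0)
                    model[small_bins.chrom_slice("chr5")] = 2 + f * (n5 - 2)
                    model[small_bins.chrom_slice("chr8")] = 2 + f * (n8 - 2)
                    cost = np.abs(y - model).sum() + 1e-3 * (
                        abs(n5 - 2) + abs(n8 - 2)
                    )
                    if best is None or cost < best[0]:
                        best = (cost, f, n5, n8)
        _, f_star, n5_star, n8_star = best
        fit = infer_single_population(noiseless_two_level, C=1.0)
        assert fit.fraction == pytest.approx(f_star, abs=1e-3)
        cn = fit.profile.cn_track(small_bins.n_bins)
        assert cn[small_bins.chrom_slice("chr5")][0] == n5_star
        assert cn[small_bins.chrom_slice("chr8")][0] == n8_star

    def test_parsimony_tiebreak(self, small_bins):
        """Level 1.5 alone: (f=0.5, n=1) beats the degenerate (0.25, n=0)."""
        vals = np.full(small_bins.n_bins, 2.0)
        vals[small_bins.chrom_slice("chr5")] = 1.5
        fit = infer_single_population(_track(small_bins, vals), C=1.0)
        assert fit.fraction == pytest.approx(0.5, abs=1e-3)
        assert set(fit.profile.cn_track(small_bins.n_bins)[small_bins.chrom_slice("chr5")]) == {1}

    def test_scale_invariance_of_decomposition(self, small_bins, noiseless_two_level):
        a = decompose(noiseless_two_level, seed=1)
        scaled = _track(small_bins, noiseless_two_level.values * 13.0)
        b = decompose(scaled, seed=1)
        assert a.fractions == b.fractions
        assert b.scale == pytest.approx(13.0 * a.scale, rel=1e-3)


class TestDecomposeOnSimulations:
    def test_single_population_mixture(
        self, diploid_reads, aneuploid_reads, covariates, reference_model, aneuploid,
        small_bins,
    ):
        mix = hd.mix_maps([aneuploid_reads, diploid_reads], [0.48, 0.52])
        corr = hd.apply_correction(
            hd.extract_diagonal(mix), covariates, reference_model
        )
        deco = decompose(corr, seed=5)
        assert len(deco.fractions) == 1
        assert deco.fractions[0] == pytest.approx(0.48, abs=0.03)
        cn = deco.populations[0].profile.cn_track(small_bins.n_bins)
        truth = aneuploid.cn_track(small_bins)
        assert (cn == truth).mean() > 0.9

    def test_pure_diploid_reports_no_population(
        self, diploid_reads, covariates, reference_model
    ):
        corr = hd.apply_correction(
            hd.extract_diagonal(diploid_reads), covariates, reference_model
        )
        deco = decompose(corr, seed=7)
        assert deco.fractions == []

    def test_peeling_removes_fitted_structure(self, small_bins, noiseless_two_level):
        fit = infer_single_population(noiseless_two_level, C=1.0)
        residual = peel_population(
            noiseless_two_level.values.copy(), fit, small_bins.n_bins
        )
        assert np.allclose(residual, 2.0, atol=1e-6)

    def test_peeling_order_insensitive_for_disjoint_profiles(self, small_bins):
        """Two noiseless populations with disjoint aberrations: the final
        residual is flat regardless of which is peeled first."""
        y = np.full(small_bins.n_bins, 2.0)
        y[small_bins.chrom_slice("chr5")] -= 0.6   # pop A: n=1 at f=0.6
        y[small_bins.chrom_slice("chr2")] += 0.2   # pop B: n=3 at f=0.2
        deco = decompose(_track(small_bins, y), C=1.0, seed=3)
        assert sorted(deco.fractions, reverse=True) == deco.fractions
        assert deco.fractions[0] == pytest.approx(0.6, abs=0.01)
        assert deco.fractions[1] == pytest.approx(0.2, abs=0.01)


class TestChangePointConfidence:
    def test_clear_step_high_confidence(self, small_bins, rng):
        y = 2.0 + 0.02 * rng.standard_normal(small_bins.n_bins)
        chr5 = small_bins.chrom_slice("chr5")
        mid = (chr5.start + chr5.stop) // 2
        y[mid : chr5.stop] -= 0.5  # arm-level step inside the chromosome
        track = _track(small_bins, y)
        deco = decompose(track, C=1.0, seed=2)
        cps = [cp for _, cp in deco.change_points() if not cp.flagged]
        assert cps
        assert all(cp.confidence >= 0.99 for cp in cps)

    def test_boundary_refined_to_bin(self, small_bins, rng):
        y = 2.0 + 0.05 * rng.standard_normal(small_bins.n_bins)
        chr3 = small_bins.chrom_slice("chr3")
        step_bin = chr3.start + 73  # off the window grid on purpose
        y[step_bin : chr3.stop] -= 0.5
        deco = decompose(_track(small_bins, y), C=1.0, seed=2)
        cps = [cp.bin for _, cp in deco.change_points()]
        assert any(abs(b - step_bin) <= 1 for b in cps)

    def test_spurious_boundary_confidence_uniformish(self, small_bins, rng):
        """Scoring an injected no-step boundary yields unremarkable
        confidence values, not systematic near-1 scores."""
        from hicdeconv.purity import ChangePoint, CopyNumberProfile, CopyNumberSegment

        confs = []
        for seed in range(15):
            r = np.random.default_rng(seed)
            y = 2.0 + 0.1 * r.standard_normal(small_bins.n_bins)
            chr1 = small_bins.chrom_slice("chr1")
            mid = (chr1.start + chr1.stop) // 2
            profile = CopyNumberProfile(
                segments=[
                    CopyNumberSegment("chr1", chr1.start, mid, 2),
                    CopyNumberSegment("chr1", mid, chr1.stop, 3),
                ],
                change_points=[ChangePoint(bin=mid, delta_n=1)],
            )
            score_change_points(
                profile, _track(small_bins, y), C=1.0, fraction=0.5, seed=seed
            )
            confs.append(profile.change_points[0].confidence)
        confs = np.asarray(confs)
        assert 0.2 < confs.mean() < 0.8
        assert confs.min() < 0.5 < confs.max()

    def test_short_segment_flagged(self, small_bins, rng):
        from hicdeconv.purity import ChangePoint, CopyNumberProfile, CopyNumberSegment

        profile = CopyNumberProfile(
            segments=[
                CopyNumberSegment("chr1", 0, 3, 2),
                CopyNumberSegment("chr1", 3, 100, 3),
            ],
            change_points=[ChangePoint(bin=3, delta_n=1)],
        )
        y = 2.0 + 0.01 * rng.standard_normal(small_bins.n_bins)
        score_change_points(profile, _track(small_bins, y), C=1.0, fraction=0.5)
        cp = profile.change_points[0]
        assert cp.flagged and np.isnan(cp.confidence)


class TestBootstrapCI:
    def test_noiseless_ci_is_tight_and_contains_estimate(
        self, small_bins, noiseless_two_level
    ):
        deco = decompose(noiseless_two_level, C=1.0, seed=4)
        cis = bootstrap_purity_ci(noiseless_two_level, deco, B=60, seed=9)
        (lo, hi), = cis
        assert lo <= deco.fractions[0] <= hi
        assert hi - lo < 0.01

    def test_ci_covers_truth_on_noisy_simulation(self, small_bins, rng):
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            y = 2.0 + 0.15 * r.standard_normal(small_bins.n_bins)
            y[small_bins.chrom_slice("chr5")] -= 0.5
            y[small_bins.chrom_slice("chr2")] += 0.5
            track = _track(small_bins, y)
            deco = decompose(track, C=1.0, seed=seed)
            if not deco.fractions:
                continue
            cis = bootstrap_purity_ci(track, deco, B=60, seed=seed)
            lo, hi = cis[0]
            if lo - 0.01 <= 0.5 <= hi + 0.01:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_few_replicates_warns(self, small_bins, noiseless_two_level):
        deco = decompose(noiseless_two_level, C=1.0, seed=4)
        with pytest.warns(UserWarning, match="replicates"):
            bootstrap_purity_ci(noiseless_two_level, deco, B=10, seed=1)
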