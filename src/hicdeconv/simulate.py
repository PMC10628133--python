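"""Karyotype-driven synthetic contact maps, covariates, and cell mixtures.

The generative model mirrors the structure of real proximity-ligation data:

* cis contacts between loci at separation ``d`` bins on the same molecule
  occur at rate ``p0 * (d + 1) ** -alpha`` (power-law distance decay);
* fusion junctions on derived chromosomes therefore produce the familiar
  off-diagonal enrichment blocks, with orientation set by segment strands;
* a genome-wide background between any two bins at rate
  ``beta0 * cn_i * cn_j`` (copy-number-proportional trans contacts);
* an A/B checkerboard modulation ``1 + kappa * s_i * s_j`` with
  ``s in {+1, -1}``;
* a per-bin multiplicative covariate factor ``g_i`` (GC, mappability,
  cut-site density, compartment), entering as ``g_i * g_j``;
* diagonal entries exactly proportional to ``cn_i`` times the covariate
  factor, which is the signal copy-number inference consumes.

Counts are sampled Poisson (optionally over-dispersed negative-binomial via
a gamma mixture) as a declared idealization: real Hi-C counts are not well
described by any parametric family, and the inference modules therefore
never assume the sampling law, only the simulator uses it.

Mixtures of cell populations are convex combinations of depth-normalized
maps, the in-silico analog of mixing reads from two libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMap, depth_normalize
from .genome import GenomeBins, Karyotype

__all__ = [
    "SimulationParams",
    "CovariateTrack",
    "simulate_covariates",
    "covariate_factor",
    "render_expected_map",
    "sample_reads",
    "mix_maps",
    "simulate_allele_counts",
]


@dataclass
class SimulationParams:
    """Knobs of the generative contact-map model.

    decay_exponent
        Power-law exponent alpha of cis distance decay; 1.0 is the canonical
        fractal-globule-like value.
    cis_scale
        Expected cis counts (arbitrary units) at distance 0 per molecule copy.
    trans_scale
        Background rate per copy pair; ~2e-4 of cis_scale keeps the trans
        fraction of reads near 15%, typical of clean libraries.
    compartment_strength
        Checkerboard amplitude kappa in [0, 1).
    covariate_coefficients
        Log-linear per-bin effect sizes for gc, mappability, cut_sites and an
        A-compartment multiplier.
    """

    decay_exponent: float = 1.0
    cis_scale: float = 1.0
    trans_scale: float = 2e-4
    compartment_strength: float = 0.15
    covariate_coefficients: dict = field(
        default_factory=lambda: {
            "gc": 3.0,
            "mappability": 1.5,
            "cut_sites": 0.04,
            "compartment": 0.25,
        }
    )

    def __post_init__(self) -> None:
        if self.cis_scale <= 0 or self.trans_scale <= 0:
            raise ValueError("cis_scale and trans_scale must be positive")
        if not (0 <= self.compartment_strength < 1):
            raise ValueError("compartment_strength must be in [0, 1)")


@dataclass
class CovariateTrack:
    """Per-bin genomic covariates feeding the correction model."""

    gc: np.ndarray           # fraction in [0, 1]
    mappability: np.ndarray  # in [0, 1]
    cut_sites: np.ndarray    # nonnegative counts
    compartment: np.ndarray  # +1 = "A", -1 = "B"

    def __post_init__(self) -> None:
        n = len(self.gc)
        for name in ("mappability", "cut_sites", "compartment"):
            if len(getattr(self, name)) != n:
                raise ValueError("covariate track lengths differ")

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.compartment > 0, "A", "B")


def simulate_covariates(
    bins: GenomeBins,
    seed: int,
    gc_range: tuple[float, float] = (0.3, 0.6),
    mappability_range: tuple[float, float] = (0.5, 1.0),
    cut_site_mean: float = 10.0,
    compartment_block_bins: int = 20,
) -> CovariateTrack:
    """Smooth (AR(1)) GC and mappability, Poisson cut sites, A/B blocks."""
    rng = np.random.default_rng(seed)
    n = bins.n_bins

    def smooth_in_range(lo: float, hi: float, phi: float = 0.95) -> np.ndarray:
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + np.sqrt(1 - phi**2) * eps[i]
        return lo + (hi - lo) * (0.5 + 0.5 * np.tanh(x / 2.0))

    gc = smooth_in_range(*gc_range)
    mappability = smooth_in_range(*mappability_range)
    cut_sites = rng.poisson(cut_site_mean, size=n).astype(np.float64)

    compartment = np.empty(n, dtype=np.int8)
    label = 1
    i = 0
    while i < n:
        run = max(1, int(rng.poisson(compartment_block_bins)))
        compartment[i : i + run] = label
        label = -label
        i += run
    return CovariateTrack(gc, mappability, cut_sites, compartment)


def covariate_factor(cov: CovariateTrack, params: SimulationParams) -> np.ndarray:
    """Per-bin multiplicative factor g_i, normalized to geometric mean 1."""
    c = params.covariate_coefficients
    log_g = (
        c.get("gc", 0.0) * cov.gc
        + c.get("mappability", 0.0) * cov.mappability
        + c.get("cut_sites", 0.0) * cov.cut_sites
        + c.get("compartment", 0.0) * (cov.compartment > 0)
    )
    log_g -= log_g.mean()
    return np.exp(log_g)


def render_expected_map(
    populations: list[tuple[Karyotype, float]],
    bins: GenomeBins,
    covariates: CovariateTrack | None = None,
    params: SimulationParams | None = None,
) -> ContactMap:
    """Expected-value contact map of a convex mixture of populations.

    Superposition holds exactly: the render of a mixture equals the weighted
    sum of single-population renders.
    """
    params = params or SimulationParams()
    weights = np.array([w for _, w in populations], dtype=np.float64)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("population weights must be >= 0 and sum to 1")

    n = bins.n_bins
    if covariates is not None:
        g = covariate_factor(covariates, params)
        s = covariates.compartment.astype(np.float64)
    else:
        g = np.ones(n)
        s = np.ones(n)

    kappa = params.compartment_strength
    p0, b0, alpha = params.cis_scale, params.trans_scale, params.decay_exponent

    total = np.zeros((n, n), dtype=np.float64)
    for karyotype, w in populations:
        if w == 0:
            continue
        cn = karyotype.cn_track(bins).astype(np.float64)
        m = b0 * np.outer(cn, cn)
        for der in karyotype.derived_chromosomes:
            order = der.bin_order(bins)
            L = len(order)
            if L == 0:
                continue
            u = np.arange(L)
            t = der.count * p0 * (np.abs(u[:, None] - u[None, :]) + 1.0) ** (-alpha)
            if len(np.unique(order)) == L:
                m[np.ix_(order, order)] += t
            else:  # molecule revisits a bin: accumulate
                flat = (order[:, None] * n + order[None, :]).ravel()
                np.add.at(m.ravel(), flat, t.ravel())
        # diagonal exactly proportional to copy number (self-contacts)
        np.fill_diagonal(m, (p0 + b0) * cn)
        total += w * m

    total *= 1.0 + kappa * np.outer(s, s)
    total *= np.outer(g, g)
    return ContactMap(bins, total)


def sample_reads(
    expected: ContactMap,
    read_depth: float,
    seed: int,
    dispersion: float | None = None,
    intercell_rate: float = 0.0,
) -> ContactMap:
    """Sample integer counts with E[total] = read_depth.

    Upper-triangle entries are independent Poisson; with ``dispersion`` r a
    gamma multiplier of mean 1 and variance r makes them negative-binomial
    (Var = mu + r * mu^2).  ``intercell_rate`` diverts that fraction of reads
    into a uniform background, emulating spurious intercellular ligation.
    """
    if read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = np.random.default_rng(seed)
    lam = np.triu(expected.counts)
    total = lam.sum()
    if total <= 0:
        raise ValueError("expected map has zero total")
    lam = lam * (read_depth * (1.0 - intercell_rate) / total)
    if intercell_rate > 0:
        n = expected.bins.n_bins
        n_pairs = n * (n + 1) / 2
        noise = np.triu(np.full((n, n), read_depth * intercell_rate / n_pairs))
        lam = lam + noise
    if dispersion is not None and dispersion > 0:
        mult = rng.gamma(shape=1.0 / dispersion, scale=dispersion, size=lam.shape)
        lam = np.where(lam > 0, lam * mult, 0.0)
    upper = rng.poisson(lam).astype(np.float64)
    counts = upper + np.triu(upper, k=1).T
    return ContactMap(expected.bins, counts)


def mix_maps(
    maps: list[ContactMap],
    weights: list[float],
    target_total: float | None = None,
) -> ContactMap:
    """Depth-normalize maps to a common total, then combine convexly."""
    if len(maps) != len(weights):
        raise ValueError("need one weight per map")
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be >= 0 and sum to 1")
    bins = maps[0].bins
    for m in maps[1:]:
        if m.bins != bins:
            raise ValueError("maps are on different bins")
    if target_total is None:
        target_total = maps[0].total_reads
    out = np.zeros_like(maps[0].counts)
    for m, wi in zip(maps, w):
        if wi > 0:
            out += wi * depth_normalize(m, target_total).counts
    return ContactMap(bins, out)


def simulate_allele_counts(
    populations: list[tuple[Karyotype, float]],
    bins: GenomeBins,
    n_snps: int,
    depth: float,
    seed: int,
    panel_af_range: tuple[float, float] = (0.4, 0.6),
) -> pd.DataFrame:
    """Allele counts at nominally inherited heterozygous SNPs.

    Every SNP is heterozygous in the germline, with the alternate allele on
    one of the two parental haplotypes.  The expected alternate fraction at
    a SNP is the haplotype-dosage dilution

        q = sum_pop f * (alt-hap copies) / sum_pop f * (total copies),

    and observed counts are Binomial(site depth, q) with Poisson site depth.
    Population fractions must sum to 1 (include the normal population).
    """
    fracs = np.array([f for _, f in populations], dtype=np.float64)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("population fractions must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)

    hap_tracks = [k.haplotype_cn_tracks(bins) for k, _ in populations]

    # place SNPs uniformly over genomic bp
    sizes = np.array([bins.chrom_sizes[c] for c in bins.chrom_order], dtype=np.float64)
    chrom_idx = rng.choice(len(sizes), size=n_snps, p=sizes / sizes.sum())
    pos = (rng.random(n_snps) * sizes[chrom_idx]).astype(np.int64)
    alt_hap = rng.integers(0, 2, size=n_snps)

    bin_of = np.array(
        [
            bins.locus_to_bin(bins.chrom_order[c], p)
            for c, p in zip(chrom_idx, pos)
        ]
    )
    num = np.zeros(n_snps)
    den = np.zeros(n_snps)
    for (hap0, hap1), f in zip(hap_tracks, fracs):
        alt_copies = np.where(alt_hap == 0, hap0[bin_of], hap1[bin_of])
        num += f * alt_copies
        den += f * (hap0[bin_of] + hap1[bin_of])
    q = np.divide(num, den, out=np.zeros(n_snps), where=den > 0)

    site_depth = rng.poisson(depth, size=n_snps)
    site_depth = np.where(den > 0, site_depth, 0)
    alt = rng.binomial(site_depth, q)
    ref = site_depth - alt
    panel_af = rng.uniform(*panel_af_range, size=n_snps)

    df = pd.DataFrame(
        {
            "chrom": [bins.chrom_order[c] for c in chrom_idx],
            "pos": pos,
            "ref_count": ref,
            "alt_count": alt,
            "panel_af": panel_af,
        }
    )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
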