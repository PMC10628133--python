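"""Joint inference of tumor purity and absolute copy numbers.

Mixes an aneuploid and a diploid library at a 33% cancer read share and
recovers the fraction plus the integer profile, with 95% bootstrap CIs.
"""
import hicdeconv as hd
from hicdeconv import scenarios as sc

sizes = sc.toy_chrom_sizes(0.3)
bins = sc.toy_bins(0.3)
cov = hd.simulate_covariates(bins, seed=1)
params = hd.SimulationParams()
normal = sc.diploid_karyotype(sizes)
cancer = sc.aneuploid_karyotype(sizes)
rn = hd.sample_reads(hd.render_expected_map([(normal, 1.0)], bins, cov, params), 3e6, 1)
rc = hd.sample_reads(hd.render_expected_map([(cancer, 1.0)], bins, cov, params), 3e6, 2)
mixture = hd.mix_maps([rc, rn], [0.33, 0.67])

model = hd.fit_correction(hd.extract_diagonal(rn), cov)
corrected = hd.apply_correction(hd.extract_diagonal(mixture), cov, model)
deco = hd.decompose(corrected, seed=5, compute_ci=True)

pop = deco.populations[0]
lo, hi = deco.f_confidence_intervals[0]
print(f"inferred cancer fraction: {pop.fraction:.3f}  (truth 0.330, 95% CI {lo:.3f}-{hi:.3f})")
print("aberrant segments (chrom, Mb span, copies):")
for seg in pop.profile.segments:
    if seg.cn != 2:
        _, s, _ = bins.bin_to_interval(seg.start_bin)
        _, _, e = bins.bin_to_interval(seg.end_bin - 1)
        print(f"  {seg.chrom:>5}  {s/1e6:6.1f}-{e/1e6:6.1f}  n={seg.cn}")
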