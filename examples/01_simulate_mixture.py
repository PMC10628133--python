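"""Render a karyotype-driven contact map and sample a sequencing library.

Builds a ~60 Mb toy genome, renders the expected map of a 50/50 mixture of
a diploid and a seven-aberration aneuploid genome, samples 2e6 read pairs,
and prints what the diagonal looks like on a normal vs a monosomic
chromosome.
"""
import numpy as np
import hicdeconv as hd
from hicdeconv import scenarios as sc

sizes = sc.toy_chrom_sizes(0.2)
bins = sc.toy_bins(0.2)
cov = hd.simulate_covariates(bins, seed=1)
params = hd.SimulationParams()
normal = sc.diploid_karyotype(sizes)
cancer = sc.aneuploid_karyotype(sizes)

expected = hd.render_expected_map([(cancer, 0.5), (normal, 0.5)], bins, cov, params)
reads = hd.sample_reads(expected, 2e6, seed=2)
diag = hd.extract_diagonal(reads)

chr3 = bins.chrom_slice("chr3")   # diploid in both populations
chr7 = bins.chrom_slice("chr7")   # monosomic in the cancer genome
print(f"total read pairs sampled: {reads.total_reads:,.0f}")
print(f"mean diagonal, chr3 (cn 2+2): {diag.values[chr3].mean():8.1f}")
print(f"mean diagonal, chr7 (cn 2+1): {diag.values[chr7].mean():8.1f}")
print("the chr7/chr3 ratio ~0.75 is the copy-number dilution of a 50% mixture")
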