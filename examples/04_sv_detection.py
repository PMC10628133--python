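"""Detect a copy-number-coupled fusion and a reciprocal translocation.

Simulates a 50% tumor carrying der(chr1::chr2) (type-1, changes copy
number at its anchors) and t(chr3;chr4) (type-2, copy-neutral bow-tie).
"""
import hicdeconv as hd
from hicdeconv import scenarios as sc
from hicdeconv.sv import detect_type1, detect_type2

sizes = sc.toy_chrom_sizes(0.5)
bins = sc.toy_bins(0.5)
cov = hd.simulate_covariates(bins, seed=3)
params = hd.SimulationParams()
normal = sc.diploid_karyotype(sizes)
mixture = hd.render_expected_map(
    [(sc.fusion_karyotype(sizes), 0.25),
     (sc.reciprocal_karyotype(sizes), 0.25),
     (normal, 0.5)], bins, cov, params)
sample = hd.sample_reads(mixture, 1e7, seed=9)
ref = hd.sample_reads(hd.render_expected_map([(normal, 1.0)], bins, cov, params), 1e7, 10)
model = hd.fit_correction(hd.extract_diagonal(ref), cov)
corrected = hd.apply_correction(hd.extract_diagonal(sample), cov, model)
deco = hd.decompose(corrected, seed=5)

for call in detect_type1(sample, deco, seed=1) + detect_type2(sample, seed=2):
    _, pa, _ = bins.bin_to_interval(call.bin_a)
    _, pb, _ = bins.bin_to_interval(call.bin_b)
    cn = f" cn={call.assigned_copy_number}" if call.assigned_copy_number else ""
    print(f"{call.sv_type}: {call.chrom_a}:{pa/1e6:.2f}Mb x "
          f"{call.chrom_b}:{pb/1e6:.2f}Mb  {call.pattern_class}  "
          f"q={call.q_value:.1e}{cn}")
print("type-1 carries the population and |delta n| of its coincident copy step;")
print("type-2 is copy-neutral, so no copy number is assigned")
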