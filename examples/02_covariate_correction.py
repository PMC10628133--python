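"""Fit the compartment-specific covariate model and correct a diagonal.

The raw on-diagonal track varies with GC, mappability, cut-site density
and compartment; the corrected track is proportional to copy number.
"""
import numpy as np
import hicdeconv as hd
from hicdeconv import scenarios as sc

bins = sc.toy_bins(0.2)
cov = hd.simulate_covariates(bins, seed=1)
params = hd.SimulationParams()
normal = sc.diploid_karyotype(sc.toy_chrom_sizes(0.2))
reads = hd.sample_reads(
    hd.render_expected_map([(normal, 1.0)], bins, cov, params), 2e6, seed=3)

raw = hd.extract_diagonal(reads)
model = hd.fit_correction(raw, cov)
corrected = hd.apply_correction(raw, cov, model)

cv = lambda x: x.std() / x.mean()
print(f"variance explained by covariates: {model.fit_r2:.1%}")
print(f"coefficient of variation, raw:       {cv(raw.values[corrected.mask]):.3f}")
print(f"coefficient of variation, corrected: {cv(corrected.values[corrected.mask]):.3f}")
print("on a copy-number-uniform genome the corrected track should be nearly flat")
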