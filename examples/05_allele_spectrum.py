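"""Corroborate copy number with regional allele-frequency spectra.

A 56% tumor with a trisomy shows peaks at the diluted 2:1 haplotype
ratio; copy-neutral LOH at 63% purity shows peaks near 0.185/0.815.
"""
import numpy as np
import hicdeconv as hd
from hicdeconv import scenarios as sc
from hicdeconv.allele import (WindowSpectrum, classify_window_state,
                              predicted_peaks, select_informative_snps)
from hicdeconv.genome import DerivedChromosome, Karyotype, Segment

sizes = sc.toy_chrom_sizes(0.2)
bins = sc.toy_bins(0.2)
normal = sc.diploid_karyotype(sizes)
ders = [DerivedChromosome((Segment(c, 0, s),), 1, h)
        for c, s in sizes.items() for h in (0, 1)]
ders.append(DerivedChromosome((Segment("chr1", 0, sizes["chr1"]),), 1, 0))
trisomy = Karyotype(ders)

table = hd.simulate_allele_counts([(trisomy, 0.56), (normal, 0.44)],
                                  bins, 8000, 200, seed=4)
table = select_informative_snps(table)
on1 = table[table.chrom == "chr1"]
frac = (on1.alt_count / (on1.ref_count + on1.alt_count)).to_numpy()
spectrum = WindowSpectrum("chr1", 0, sizes["chr1"], frac)
state, cfg, dist = classify_window_state(spectrum, f=0.56, n=3)
print(f"predicted peaks for (2,1) at f=0.56: {predicted_peaks(0.56, 2, 1)}")
print(f"observed peaks on chr1:              {np.round(spectrum.peaks, 3)}")
print(f"classified state: {state}  (haplotypes {cfg}, EMD {dist:.3f})")
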