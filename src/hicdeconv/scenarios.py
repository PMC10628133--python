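"""Canonical synthetic study conditions used by tests and examples.

The toy genome is ~300 Mb over eight chromosomes at 50 kb bins (6,000
bins), large enough for arm-level events and small enough for a laptop.
The aneuploid karyotype carries seven arm-level copy-number aberrations
(four gains, three losses, nearly balanced so mean ploidy stays ~2) — the
dosage complexity of a karyotypically unstable carcinoma line.  Fusion
karyotypes add a copy-number-coupled non-reciprocal fusion and a
copy-neutral reciprocal translocation on top of arm events.
"""

from __future__ import annotations

import numpy as np

from .genome import DerivedChromosome, GenomeBins, Karyotype, Segment, make_bins

__all__ = [
    "toy_chrom_sizes",
    "toy_bins",
    "diploid_karyotype",
    "aneuploid_karyotype",
    "fusion_karyotype",
    "reciprocal_karyotype",
]

BIN_SIZE = 50_000

_TOY_SIZES = {
    "chr1": 50_000_000,
    "chr2": 45_000_000,
    "chr3": 40_000_000,
    "chr4": 38_000_000,
    "chr5": 35_000_000,
    "chr6": 32_000_000,
    "chr7": 30_000_000,
    "chr8": 30_000_000,
}


def toy_chrom_sizes(scale: float = 1.0) -> dict[str, int]:
    """~300 Mb eight-chromosome toy genome, optionally scaled down."""
    return {c: int(round(s * scale)) for c, s in _TOY_SIZES.items()}


def toy_bins(scale: float = 1.0, bin_size: int = BIN_SIZE) -> GenomeBins:
    return make_bins(toy_chrom_sizes(scale), bin_size)


def diploid_karyotype(chrom_sizes: dict[str, int]) -> Karyotype:
    return Karyotype.diploid(chrom_sizes, label="normal")


def _whole(chrom: str, sizes, haplotype: int, count: int = 1) -> DerivedChromosome:
    return DerivedChromosome(
        (Segment(chrom, 0, sizes[chrom]),), count=count, haplotype=haplotype
    )


def aneuploid_karyotype(chrom_sizes: dict[str, int] | None = None) -> Karyotype:
    """Seven arm-level aberrations on the toy genome (gains ~= losses).

    Relative to diploid: +1q of chr1, -p of chr2, +q of chr4, -q of chr5,
    +p of chr6, monosomy chr7, +p of chr8.  Centromeres are placed at half
    (chr1, chr2) or at the stated arm boundaries.
    """
    sizes = chrom_sizes or toy_chrom_sizes()

    def frac(chrom, x):
        return int(sizes[chrom] * x)

    ders: list[DerivedChromosome] = []
    # intact homolog pairs where no event touches the chromosome
    for c in ("chr3",):
        ders += [_whole(c, sizes, 0), _whole(c, sizes, 1)]
    # chr1: both homologs intact + extra copy of 1q (hap 0)
    ders += [
        _whole("chr1", sizes, 0),
        _whole("chr1", sizes, 1),
        DerivedChromosome(
            (Segment("chr1", frac("chr1", 0.5), sizes["chr1"]),), 1, 0
        ),
    ]
    # chr2: hap 1 lost its p arm
    ders += [
        _whole("chr2", sizes, 0),
        DerivedChromosome(
            (Segment("chr2", frac("chr2", 0.5), sizes["chr2"]),), 1, 1
        ),
    ]
    # chr4: extra 4q (hap 1)
    ders += [
        _whole("chr4", sizes, 0),
        _whole("chr4", sizes, 1),
        DerivedChromosome(
            (Segment("chr4", frac("chr4", 0.5), sizes["chr4"]),), 1, 1
        ),
    ]
    # chr5: hap 0 lost its q arm
    ders += [
        DerivedChromosome((Segment("chr5", 0, frac("chr5", 0.5)),), 1, 0),
        _whole("chr5", sizes, 1),
    ]
    # chr6: extra 6p (hap 0)
    ders += [
        _whole("chr6", sizes, 0),
        _whole("chr6", sizes, 1),
        DerivedChromosome((Segment("chr6", 0, frac("chr6", 0.5)),), 1, 0),
    ]
    # chr7: monosomy (hap 1 lost)
    ders += [_whole("chr7", sizes, 0)]
    # chr8: extra 8p (hap 1)
    ders += [
        _whole("chr8", sizes, 0),
        _whole("chr8", sizes, 1),
        DerivedChromosome((Segment("chr8", 0, frac("chr8", 0.5)),), 1, 1),
    ]
    return Karyotype(ders, population_label="aneuploid")


def second_aneuploid_karyotype(chrom_sizes: dict[str, int] | None = None) -> Karyotype:
    """Five arm-level aberrations disjoint from :func:`aneuploid_karyotype`.

    Relative to diploid: -p of chr1, +q of chr2, -p of chr3, +p of chr5,
    -q of chr6.  Used as the minor subpopulation in two-population
    peeling studies.
    """
    sizes = chrom_sizes or toy_chrom_sizes()

    def frac(chrom, x):
        return int(sizes[chrom] * x)

    ders: list[DerivedChromosome] = []
    for c in ("chr4", "chr7", "chr8"):
        ders += [_whole(c, sizes, 0), _whole(c, sizes, 1)]
    # chr1: hap 1 lost its p arm
    ders += [
        _whole("chr1", sizes, 0),
        DerivedChromosome((Segment("chr1", frac("chr1", 0.5), sizes["chr1"]),), 1, 1),
    ]
    # chr2: extra 2q (hap 0)
    ders += [
        _whole("chr2", sizes, 0),
        _whole("chr2", sizes, 1),
        DerivedChromosome((Segment("chr2", frac("chr2", 0.5), sizes["chr2"]),), 1, 0),
    ]
    # chr3: hap 0 lost its p arm
    ders += [
        DerivedChromosome((Segment("chr3", frac("chr3", 0.5), sizes["chr3"]),), 1, 0),
        _whole("chr3", sizes, 1),
    ]
    # chr5: extra 5p (hap 1)
    ders += [
        _whole("chr5", sizes, 0),
        _whole("chr5", sizes, 1),
        DerivedChromosome((Segment("chr5", 0, frac("chr5", 0.5)),), 1, 1),
    ]
    # chr6: hap 1 lost its q arm
    ders += [
        _whole("chr6", sizes, 0),
        DerivedChromosome((Segment("chr6", 0, frac("chr6", 0.5)),), 1, 1),
    ]
    return Karyotype(ders, population_label="aneuploid_B")


def fusion_karyotype(
    chrom_sizes: dict[str, int] | None = None,
    break_a: float = 0.6,
    break_b: float = 0.4,
) -> Karyotype:
    """Non-reciprocal (type-1) fusion: der(chr1::chr2) replaces one chr1
    and one chr2 homolog, so chr1 distal-q and chr2 proximal-p drop to one
    copy with change points exactly at the junction coordinates."""
    sizes = chrom_sizes or toy_chrom_sizes()
    ba = int(sizes["chr1"] * break_a)
    bb = int(sizes["chr2"] * break_b)
    ders = [
        _whole("chr1", sizes, 0),
        _whole("chr2", sizes, 0),
        DerivedChromosome(
            (Segment("chr1", 0, ba), Segment("chr2", bb, sizes["chr2"])), 1, 1
        ),
    ]
    for c in list(sizes)[2:]:
        ders += [_whole(c, sizes, 0), _whole(c, sizes, 1)]
    return Karyotype(ders, population_label="fusion")


def reciprocal_karyotype(
    chrom_sizes: dict[str, int] | None = None,
    break_a: float = 0.6,
    break_b: float = 0.4,
    chroms: tuple[str, str] = ("chr3", "chr4"),
) -> Karyotype:
    """Copy-neutral reciprocal translocation t(A;B): both derivative
    chromosomes retained, copy number everywhere 2 (type-2 bow-tie)."""
    sizes = chrom_sizes or toy_chrom_sizes()
    ca, cb = chroms
    ba = int(sizes[ca] * break_a)
    bb = int(sizes[cb] * break_b)
    ders = [
        _whole(ca, sizes, 0),
        _whole(cb, sizes, 0),
        DerivedChromosome(
            (Segment(ca, 0, ba), Segment(cb, bb, sizes[cb])), 1, 1
        ),
        DerivedChromosome(
            (Segment(cb, 0, bb), Segment(ca, ba, sizes[ca])), 1, 1
        ),
    ]
    for c in sizes:
        if c not in chroms:
            ders += [_whole(c, sizes, 0), _whole(c, sizes, 1)]
    return Karyotype(ders, population_label="reciprocal")
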