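"""Genome binning, coordinate conversion, and karyotype representation.

All coordinates in the package are 0-based, half-open, matching the
BED/bedGraph convention.  A genome is partitioned into fixed-width bins of
``bin_size`` bp; the last bin of each chromosome may be shorter in bp but
still counts as one bin (it is flagged so model-fitting code can exclude it).

A :class:`Karyotype` describes the genome of one cell population as a bag of
derived chromosome molecules.  Each :class:`DerivedChromosome` is an ordered
list of reference segments (possibly from different chromosomes, possibly
inverted) present in ``count`` copies; adjacent segments are fused.  The
per-bin absolute copy number of a population is obtained by summing, over
molecules, how often each reference bin occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeBins",
    "Segment",
    "DerivedChromosome",
    "Karyotype",
    "make_bins",
    "read_chrom_sizes",
]


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width binning of a reference genome.

    Parameters
    ----------
    chrom_order
        Chromosome names in genome order.
    chrom_sizes
        Mapping chromosome -> length in bp.
    bin_size
        Bin width ``w`` in bp.
    """

    chrom_order: tuple[str, ...]
    chrom_sizes: dict[str, int]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(set(self.chrom_order)) != len(self.chrom_order):
            raise ValueError("duplicate chromosome name")
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive size {size}")
        object.__setattr__(self, "chrom_order", tuple(self.chrom_order))

    # ---- derived layout -------------------------------------------------
    @property
    def n_bins_per_chrom(self) -> dict[str, int]:
        w = self.bin_size
        return {c: -(-self.chrom_sizes[c] // w) for c in self.chrom_order}

    @property
    def bin_offsets(self) -> dict[str, int]:
        out: dict[str, int] = {}
        acc = 0
        for c in self.chrom_order:
            out[c] = acc
            acc += self.n_bins_per_chrom[c]
        return out

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_per_chrom.values())

    def chrom_index(self) -> np.ndarray:
        """Per-bin index into ``chrom_order``."""
        idx = np.empty(self.n_bins, dtype=np.int32)
        for k, c in enumerate(self.chrom_order):
            o = self.bin_offsets[c]
            idx[o : o + self.n_bins_per_chrom[c]] = k
        return idx

    def partial_bin_mask(self) -> np.ndarray:
        """True for last-of-chromosome bins that are shorter than bin_size."""
        m = np.zeros(self.n_bins, dtype=bool)
        for c in self.chrom_order:
            if self.chrom_sizes[c] % self.bin_size != 0:
                m[self.bin_offsets[c] + self.n_bins_per_chrom[c] - 1] = True
        return m

    def chrom_slice(self, chrom: str) -> slice:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        o = self.bin_offsets[chrom]
        return slice(o, o + self.n_bins_per_chrom[chrom])

    # ---- coordinate conversion ------------------------------------------
    def locus_to_bin(self, chrom: str, pos: int) -> int:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(f"position {pos} out of range for {chrom}")
        return self.bin_offsets[chrom] + pos // self.bin_size

    def bin_to_interval(self, bin_index: int) -> tuple[str, int, int]:
        """Half-open bp interval ``(chrom, start, end)`` of a global bin."""
        if not (0 <= bin_index < self.n_bins):
            raise ValueError(f"bin index {bin_index} out of range")
        for c in self.chrom_order:
            o = self.bin_offsets[c]
            n = self.n_bins_per_chrom[c]
            if bin_index < o + n:
                k = bin_index - o
                return c, k * self.bin_size, (k + 1) * self.bin_size
        raise AssertionError("unreachable")


def make_bins(chrom_sizes: dict[str, int], bin_size: int) -> GenomeBins:
    """Bin a genome at fixed width; chromosome order follows dict order."""
    return GenomeBins(tuple(chrom_sizes), dict(chrom_sizes), int(bin_size))


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, size = line.split("\t")[:2]
            if name in sizes:
                raise ValueError(f"duplicate chromosome name {name!r}")
            sizes[name] = int(size)
    return sizes


@dataclass(frozen=True)
class Segment:
    """Reference segment ``chrom:[start, end)`` on strand ``+`` or ``-``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate segment {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "Segment":
        chrom, span, strand = text.strip().rsplit(":", 2)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass(frozen=True)
class DerivedChromosome:
    """One (possibly fused) chromosome molecule present in ``count`` copies.

    ``haplotype`` tags which parental homolog the molecule descends from
    (0 or 1); it only matters for allele-frequency simulation.
    """

    segments: tuple[Segment, ...]
    count: int = 1
    haplotype: int = 0

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise ValueError("derived chromosome needs >= 1 segment")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        object.__setattr__(self, "segments", tuple(self.segments))

    def bin_order(self, bins: GenomeBins) -> np.ndarray:
        """Global bin indices along the molecule, honoring orientation.

        A bin is included if the majority of its bp lies inside the segment
        (exact half rounds down, i.e. the bin is excluded).
        """
        parts = []
        for seg in self.segments:
            if seg.chrom not in bins.chrom_sizes:
                raise KeyError(f"unknown chromosome {seg.chrom!r}")
            if seg.end > bins.chrom_sizes[seg.chrom]:
                raise ValueError(f"segment {seg} extends past chromosome end")
            w = bins.bin_size
            o = bins.bin_offsets[seg.chrom]
            first = seg.start // w
            last = (seg.end - 1) // w
            idx = np.arange(first, last + 1)
            b_start = idx * w
            b_end = np.minimum((idx + 1) * w, bins.chrom_sizes[seg.chrom])
            overlap = np.minimum(b_end, seg.end) - np.maximum(b_start, seg.start)
            keep = overlap * 2 > (b_end - b_start)
            part = (o + idx[keep]).astype(np.int64)
            if seg.strand == "-":
                part = part[::-1]
            parts.append(part)
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(parts)


@dataclass
class Karyotype:
    """Genome of one cell population as a list of derived chromosomes."""

    derived_chromosomes: list[DerivedChromosome]
    population_label: str = "pop"

    def cn_track(self, bins: GenomeBins) -> np.ndarray:
        """Per-bin integer copy number.

        A bin split by a segment boundary takes the copy number of the
        majority of its bp; an exact half rounds toward the lower copy
        number.
        """
        w = bins.bin_size
        bp = np.zeros(bins.n_bins, dtype=np.float64)
        for der in self.derived_chromosomes:
            for seg in der.segments:
                if seg.chrom not in bins.chrom_sizes:
                    raise KeyError(f"unknown chromosome {seg.chrom!r}")
                if seg.end > bins.chrom_sizes[seg.chrom]:
                    raise ValueError(f"segment {seg} extends past chromosome end")
                o = bins.bin_offsets[seg.chrom]
                first = seg.start // w
                last = (seg.end - 1) // w
                idx = np.arange(first, last + 1)
                b_start = idx * w
                b_end = np.minimum((idx + 1) * w, bins.chrom_sizes[seg.chrom])
                overlap = np.minimum(b_end, seg.end) - np.maximum(b_start, seg.start)
                bp[o + idx] += der.count * overlap / (b_end - b_start)
        # majority rule with half rounding down
        cn = np.ceil(bp - 0.5).astype(np.int64)
        return np.maximum(cn, 0)

    def haplotype_cn_tracks(self, bins: GenomeBins) -> tuple[np.ndarray, np.ndarray]:
        """Copy-number tracks of the two parental haplotypes (hap0, hap1)."""
        tracks = []
        for h in (0, 1):
            sub = Karyotype(
                [d for d in self.derived_chromosomes if d.haplotype == h],
                self.population_label,
            )
            if sub.derived_chromosomes:
                tracks.append(sub.cn_track(bins))
            else:
                tracks.append(np.zeros(bins.n_bins, dtype=np.int64))
        return tracks[0], tracks[1]

    @classmethod
    def diploid(cls, chrom_sizes: dict[str, int], label: str = "normal") -> "Karyotype":
        """Two intact copies of every reference chromosome, one per haplotype."""
        ders = []
        for c, size in chrom_sizes.items():
            for h in (0, 1):
                ders.append(
                    DerivedChromosome((Segment(c, 0, size),), count=1, haplotype=h)
                )
        return cls(ders, label)

    # ---- text serialization ---------------------------------------------
    # One derived chromosome per line:
    #   <count>\t<haplotype>\t<seg>;<seg>;...      seg = chrom:start-end:strand
    def to_text(self) -> str:
        lines = [f"# karyotype: {self.population_label}"]
        for der in self.derived_chromosomes:
            segs = ";".join(str(s) for s in der.segments)
            lines.append(f"{der.count}\t{der.haplotype}\t{segs}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Karyotype":
        label = "pop"
        ders = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "karyotype:" in line:
                    label = line.split("karyotype:", 1)[1].strip()
                continue
            count, hap, segs = line.split("\t")
            segments = tuple(Segment.parse(s) for s in segs.split(";"))
            ders.append(DerivedChromosome(segments, int(count), int(hap)))
        return cls(ders, label)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read(cls, path) -> "Karyotype":
        with open(path) as fh:
            return cls.from_text(fh.read())
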