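"""Binned contact matrices and the on-diagonal intensity track.

A :class:`ContactMap` holds a symmetric, nonnegative count matrix over the
global bins of a :class:`~hicdeconv.genome.GenomeBins`.  Matrices are stored
dense (toy and desk-scale genomes stay well below 10^4 bins); the on-disk
interchange format is a human-readable sparse triplet TSV with header
``#bin_i<TAB>bin_j<TAB>count`` over global bin indices.

No ICE/KR balancing is ever applied: downstream copy-number inference models
raw counts through its own covariate correction, and matrix balancing would
erase exactly the copy-number signal it relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeBins

__all__ = [
    "ContactMap",
    "DiagonalTrack",
    "read_contact_map",
    "write_contact_map",
    "depth_normalize",
    "extract_diagonal",
    "trans_block",
    "write_bedgraph",
    "read_bedgraph",
]

#: minimum separation (bp) for same-chromosome "off-diagonal" analysis;
#: closer pairs are swamped by cis distance decay.
MIN_CIS_SEPARATION_BP = 10_000_000


@dataclass
class ContactMap:
    """Symmetric binned contact-count matrix."""

    bins: GenomeBins
    counts: np.ndarray  # (n_bins, n_bins) float, symmetric, >= 0

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if np.any(self.counts < 0):
            raise ValueError("negative contact counts")

    @property
    def total_reads(self) -> float:
        """Sum of upper triangle plus diagonal (each read pair counted once)."""
        return float(np.triu(self.counts).sum())

    def check_symmetric(self, rtol: float = 1e-9) -> None:
        if not np.allclose(self.counts, self.counts.T, rtol=rtol):
            raise ValueError("contact matrix is not symmetric")


@dataclass
class DiagonalTrack:
    """Per-bin on-diagonal intensity with a usable-bin mask."""

    bins: GenomeBins
    values: np.ndarray
    mask: np.ndarray  # True = usable

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        if len(self.values) != n or len(self.mask) != n:
            raise ValueError("track length does not match bin count")

    def usable_values(self) -> np.ndarray:
        return self.values[self.mask]


# ---------------------------------------------------------------------------
# sparse triplet TSV
# ---------------------------------------------------------------------------

def read_contact_map(path, bins: GenomeBins, format: str = "tsv_triplet") -> ContactMap:
    """Read a contact map; triplets are mirrored and duplicates summed."""
    if format != "tsv_triplet":
        raise ValueError(f"unsupported format {format!r} (only 'tsv_triplet')")
    n = bins.n_bins
    counts = np.zeros((n, n), dtype=np.float64)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i_s, j_s, c_s = line.split("\t")
            i, j, c = int(i_s), int(j_s), float(c_s)
            if c < 0:
                raise ValueError(f"negative count {c} at ({i}, {j})")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bin index ({i}, {j}) outside 0..{n - 1}")
            counts[i, j] += c
            if i != j:
                counts[j, i] += c
    return ContactMap(bins, counts)


def write_contact_map(cmap: ContactMap, path) -> None:
    """Write the upper triangle (incl. diagonal) as sparse triplet TSV."""
    iu, ju = np.nonzero(np.triu(cmap.counts))
    with open(path, "w") as fh:
        fh.write("#bin_i\tbin_j\tcount\n")
        for i, j in zip(iu, ju):
            c = cmap.counts[i, j]
            if c == int(c):
                fh.write(f"{i}\t{j}\t{int(c)}\n")
            else:
                fh.write(f"{i}\t{j}\t{float(c)!r}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def depth_normalize(cmap: ContactMap, target_total: float) -> ContactMap:
    """Scale all entries so the total read count equals ``target_total``."""
    total = cmap.total_reads
    if total <= 0:
        raise ValueError("cannot depth-normalize a map with zero total")
    return ContactMap(cmap.bins, cmap.counts * (target_total / total))


def extract_diagonal(cmap: ContactMap, band_halfwidth: int = 0) -> DiagonalTrack:
    """On-diagonal intensity: self-contact count, optionally band-summed.

    ``value[i]`` sums ``counts[i, i+d]`` for ``|d| <= band_halfwidth``
    restricted to i's chromosome.  Partial chromosome-end bins are masked.
    """
    if band_halfwidth < 0:
        raise ValueError("band_halfwidth must be >= 0")
    bins = cmap.bins
    n = bins.n_bins
    values = np.array(np.diag(cmap.counts), dtype=np.float64)
    if band_halfwidth > 0:
        chrom_idx = bins.chrom_index()
        for d in range(1, band_halfwidth + 1):
            off = np.diag(cmap.counts, k=d)
            same = chrom_idx[:-d] == chrom_idx[d:]
            values[:-d][same] += off[same]  # counts[i, i+d]
            values[d:][same] += off[same]  # counts[i, i-d]
    mask = ~bins.partial_bin_mask()
    return DiagonalTrack(bins, values, mask)


def trans_block(
    cmap: ContactMap,
    chrom_a: str,
    chrom_b: str,
    min_cis_separation_bp: int = MIN_CIS_SEPARATION_BP,
):
    """Off-diagonal block between two chromosomes.

    Returns ``(block, row_bins, col_bins, valid)`` where ``block`` is a view
    of the counts submatrix, ``row_bins``/``col_bins`` are the global bin
    indices of its axes, and ``valid`` marks entries usable for off-diagonal
    analysis.  For ``chrom_a == chrom_b`` the near-diagonal band within
    ``min_cis_separation_bp`` is marked invalid.
    """
    sa = cmap.bins.chrom_slice(chrom_a)
    sb = cmap.bins.chrom_slice(chrom_b)
    block = cmap.counts[sa, sb]
    row_bins = np.arange(sa.start, sa.stop)
    col_bins = np.arange(sb.start, sb.stop)
    if chrom_a == chrom_b:
        sep_bins = max(1, min_cis_separation_bp // cmap.bins.bin_size)
        d = np.abs(row_bins[:, None] - col_bins[None, :])
        valid = d >= sep_bins
    else:
        valid = np.ones(block.shape, dtype=bool)
    return block, row_bins, col_bins, valid


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: DiagonalTrack, path, masked_value: str = "skip") -> None:
    """Export a per-bin track as bedGraph; masked bins are skipped."""
    bins = track.bins
    with open(path, "w") as fh:
        for i in range(bins.n_bins):
            if masked_value == "skip" and not track.mask[i]:
                continue
            chrom, start, end = bins.bin_to_interval(i)
            end = min(end, bins.chrom_sizes[chrom])
            fh.write(f"{chrom}\t{start}\t{end}\t{float(track.values[i])!r}\n")


def read_bedgraph(path, bins: GenomeBins, default: float = np.nan) -> np.ndarray:
    """Read a bedGraph into a per-bin array (value of the covering interval).

    Intervals are assigned to every bin whose start lies inside them; bins
    not covered get ``default``.
    """
    values = np.full(bins.n_bins, default, dtype=np.float64)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, val = line.split("\t")[:4]
            if chrom not in bins.chrom_sizes:
                continue
            start_i, end_i = int(start), int(end)
            first = bins.locus_to_bin(chrom, start_i)
            last = bins.locus_to_bin(chrom, min(end_i, bins.chrom_sizes[chrom]) - 1)
            for b in range(first, last + 1):
                _, bs, _ = bins.bin_to_interval(b)
                if start_i <= bs < end_i or (b == first):
                    values[b] = float(val)
    return values
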