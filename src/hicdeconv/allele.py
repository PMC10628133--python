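"""Regional allele-frequency spectra and haplotype copy-number states.

Nominally inherited heterozygous variants (reference-panel allele frequency
in a closed band around 0.5) carry one parental haplotype each.  In a pure
tumor with ``a`` copies of the variant haplotype and ``b`` of the other,
their alternate-allele fractions peak at ``a / (a + b)``; diluted by a
normal fraction ``1 - f`` of diploid cells the peak moves to

    q(f, a, b) = (f * a + (1 - f)) / (f * (a + b) + 2 * (1 - f)).

Classic signatures: balanced diploid -> one peak at 0.5; pure-tumor trisomy
(2:1) -> peaks at 1/3 and 2/3; copy-neutral LOH (2:0) -> peaks at 0 and 1,
each pulled toward 0.5 by dilution.  Windows (default 500 kb) are
classified by matching observed spectrum peaks against the predicted peak
sets of all haplotype configurations ``(a, b)`` with ``a + b = n``, where
``n`` and ``f`` come from the copy-number/purity decomposition; spectra
thus independently corroborate the contact-map copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .genome import GenomeBins

__all__ = [
    "WindowSpectrum",
    "read_allele_table",
    "select_informative_snps",
    "compute_window_spectra",
    "predicted_peaks",
    "classify_window_state",
]

D_MIN = 8          # minimum read depth per site
MIN_SITES = 10     # windows with fewer usable sites are uninformative
WINDOW_BP = 500_000
HIST_BINS = 25


@dataclass
class WindowSpectrum:
    chrom: str
    start: int
    end: int
    alt_fractions: np.ndarray
    histogram: np.ndarray = field(default=None)
    peaks: np.ndarray = field(default=None)
    informative: bool = True

    def __post_init__(self):
        if self.histogram is None:
            self.histogram, _ = np.histogram(
                self.alt_fractions, bins=HIST_BINS, range=(0.0, 1.0)
            )
        if self.peaks is None:
            self.peaks = _spectrum_peaks(self.alt_fractions)
        self.informative = len(self.alt_fractions) >= MIN_SITES


def _spectrum_peaks(fractions: np.ndarray, bw: float = 0.04) -> np.ndarray:
    """Peak locations of the alt-fraction density (KDE maxima in [0, 1])."""
    if len(fractions) < 2 or np.ptp(fractions) < 1e-12:
        return np.array([np.mean(fractions)]) if len(fractions) else np.array([])
    # reflect at 0 and 1 so boundary peaks (LOH) are not suppressed
    data = np.concatenate([fractions, -fractions, 2.0 - fractions])
    kde = stats.gaussian_kde(data, bw_method=bw / max(np.std(data), 1e-9))
    grid = np.linspace(0.0, 1.0, 201)
    dens = kde(grid)
    idx, _ = find_peaks(dens, height=0.1 * dens.max())
    peaks = grid[idx]
    if len(peaks) == 0:
        peaks = grid[[int(np.argmax(dens))]]
    # keep boundary modes
    if dens[0] > dens[1] and dens[0] >= 0.1 * dens.max():
        peaks = np.concatenate([[0.0], peaks])
    if dens[-1] > dens[-2] and dens[-1] >= 0.1 * dens.max():
        peaks = np.concatenate([peaks, [1.0]])
    return np.unique(np.round(peaks, 4))


def read_allele_table(path) -> pd.DataFrame:
    """TSV with columns chrom, pos, ref_count, alt_count, panel_af."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "ref_count", "alt_count", "panel_af"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allele table missing columns {sorted(missing)}")
    return df


def select_informative_snps(
    table: pd.DataFrame,
    af_band: tuple[float, float] = (0.4, 0.6),
    d_min: int = D_MIN,
) -> pd.DataFrame:
    """Keep sites with panel AF inside the closed band and depth >= d_min."""
    depth = table["ref_count"] + table["alt_count"]
    keep = (
        (table["panel_af"] >= af_band[0])
        & (table["panel_af"] <= af_band[1])
        & (depth >= d_min)
    )
    return table[keep].reset_index(drop=True)


def compute_window_spectra(
    table: pd.DataFrame,
    bins: GenomeBins,
    window_bp: int = WINDOW_BP,
) -> list[WindowSpectrum]:
    """Alt-fraction spectrum per fixed genomic window."""
    spectra = []
    depth = table["ref_count"] + table["alt_count"]
    frac = np.divide(
        table["alt_count"], depth, out=np.zeros(len(table)), where=depth > 0
    )
    win = (table["pos"] // window_bp).to_numpy()
    for chrom in bins.chrom_order:
        sel = table["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        for w in np.unique(win[sel]):
            in_w = sel & (win == w)
            start = int(w) * window_bp
            end = min(start + window_bp, bins.chrom_sizes[chrom])
            spectra.append(
                WindowSpectrum(chrom, start, end, np.asarray(frac[in_w]))
            )
    return spectra


def predicted_peaks(f: float, a: int, b: int) -> np.ndarray:
    """Expected alt-fraction peaks for a (a, b) haplotype configuration
    at cancer fraction f against a diploid heterozygous background."""
    if a < 0 or b < 0:
        raise ValueError("haplotype copies must be >= 0")
    n = a + b
    den = f * n + 2.0 * (1.0 - f)
    if den <= 0:
        return np.array([])
    q = (f * a + (1.0 - f)) / den
    return np.unique(np.round([q, 1.0 - q], 6))


def _peak_set_distance(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Earth-mover distance between peak sets as uniform point masses."""
    if len(observed) == 0 or len(predicted) == 0:
        return np.inf
    return float(stats.wasserstein_distance(observed, predicted))


def classify_window_state(
    spectrum: WindowSpectrum,
    f: float,
    n: int,
    distance_threshold: float = 0.08,
) -> tuple[str, tuple[int, int] | None, float]:
    """Best-matching haplotype configuration for a window.

    Enumerates unordered configurations (a, b), a >= b, a + b = n, compares
    predicted and observed peak sets by earth-mover distance, and maps the
    winner to a state label.  Returns (state, (a, b) or None, distance).
    """
    if not spectrum.informative:
        return "uninformative", None, np.inf
    if n == 0:
        return "hemizygous-null", None, 0.0
    best = None
    for a in range((n + 1) // 2, n + 1):
        b = n - a
        d = _peak_set_distance(spectrum.peaks, predicted_peaks(f, a, b))
        if best is None or d < best[1]:
            best = ((a, b), d)
    (a, b), dist = best
    if dist > distance_threshold:
        return "uninformative", None, dist
    if a == b:
        return "balanced", (a, b), dist
    if b == 0 and n == 2:
        return "CN-LOH", (a, b), dist
    if b == 0 and n == 1:
        return "hemizygous", (a, b), dist
    return f"imbalanced({a}:{b})", (a, b), dist
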