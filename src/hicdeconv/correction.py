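"""Compartment-specific covariate correction of on-diagonal intensities.

The on-diagonal intensity of a contact map is modeled multiplicatively as

    reads_i ~ (absolute copy number)_i * correction(GC_i, mappability_i,
                                                    cut_sites_i, compartment_i)

with the corrector a simple per-compartment linear model of the covariates.
The multiplicative form becomes additive on log intensities, so the model is
fitted by ordinary least squares on log intensity within each compartment
(with an intercept, which keeps predicted correction factors positive).
Fitting uses a copy-number-uniform source: either an external reference map
produced by the same experimental protocol, or, failing that, bins of the
sample itself that are likely diploid (central inter-quantile band of the
intensity distribution).

Dividing raw intensities by the fitted correction yields a track
proportional to copy number, the input to purity / copy-number inference.
Everything downstream is scale-free, so the absolute level of the corrected
track carries no meaning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import DiagonalTrack
from .simulate import CovariateTrack

__all__ = [
    "CorrectionModel",
    "fit_correction",
    "select_diploid_like_bins",
    "apply_correction",
]

#: bins below this mappability carry no usable signal and are masked
MAPPABILITY_MIN = 0.5
#: compartments with fewer usable bins fall back to the pooled fit
MIN_BINS_PER_COMPARTMENT = 30

_POOLED = "__pooled__"


@dataclass
class CorrectionModel:
    """Per-compartment log-linear coefficients mapping covariates to
    expected diploid intensity.

    ``coefficients[label] = (intercept, b_gc, b_mappability, b_cut_sites)``
    on the log-intensity scale.
    """

    coefficients: dict[str, tuple[float, float, float, float]]
    fit_r2: float
    reference_source: str = "internal_diploid_bins"
    pooled: tuple[float, float, float, float] | None = None

    def predict(self, covariates: CovariateTrack) -> np.ndarray:
        """Predicted correction factor (expected diploid-scale intensity)."""
        labels = covariates.labels
        out = np.empty(len(labels), dtype=np.float64)
        X = np.column_stack(
            [covariates.gc, covariates.mappability, covariates.cut_sites]
        )
        for lab in np.unique(labels):
            beta = self.coefficients.get(lab, self.pooled)
            if beta is None:
                raise ValueError(f"no coefficients for compartment {lab!r}")
            sel = labels == lab
            out[sel] = beta[0] + X[sel] @ np.asarray(beta[1:])
        return np.exp(out)

    # -- text serialization ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": {k: list(v) for k, v in self.coefficients.items()},
                "fit_r2": self.fit_r2,
                "reference_source": self.reference_source,
                "pooled": list(self.pooled) if self.pooled else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrectionModel":
        d = json.loads(text)
        return cls(
            coefficients={k: tuple(v) for k, v in d["coefficients"].items()},
            fit_r2=d["fit_r2"],
            reference_source=d["reference_source"],
            pooled=tuple(d["pooled"]) if d.get("pooled") else None,
        )


def _usable(diagonal: DiagonalTrack, covariates: CovariateTrack) -> np.ndarray:
    return (
        diagonal.mask
        & (covariates.mappability >= MAPPABILITY_MIN)
        & (covariates.cut_sites > 0)
        & (diagonal.values > 0)
        & np.isfinite(diagonal.values)
    )


def fit_correction(
    diagonal: DiagonalTrack,
    covariates: CovariateTrack,
    reference_source: str = "external_reference_map",
) -> CorrectionModel:
    """Least-squares fit of log intensity on covariates per compartment.

    The diagonal must come from a (presumed) copy-number-uniform source.
    Compartments with fewer than 30 usable bins fall back to the pooled
    compartment-free fit (with a warning).
    """
    usable = _usable(diagonal, covariates)
    if usable.sum() < 8:
        raise ValueError("too few usable bins to fit the correction model")
    y = np.log(diagonal.values[usable])
    X = np.column_stack(
        [
            np.ones(usable.sum()),
            covariates.gc[usable],
            covariates.mappability[usable],
            covariates.cut_sites[usable],
        ]
    )
    labels = covariates.labels[usable]

    pooled_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coeffs: dict[str, tuple] = {}
    pred = np.empty_like(y)
    for lab in np.unique(labels):
        sel = labels == lab
        if sel.sum() < MIN_BINS_PER_COMPARTMENT:
            warnings.warn(
                f"compartment {lab!r} has only {int(sel.sum())} usable bins; "
                "falling back to the pooled fit",
                stacklevel=2,
            )
            beta = pooled_beta
        else:
            beta, *_ = np.linalg.lstsq(X[sel], y[sel], rcond=None)
        coeffs[str(lab)] = tuple(float(b) for b in beta)
        pred[sel] = X[sel] @ beta

    # variance explained, reported on the linear (intensity) scale
    lin = diagonal.values[usable]
    resid = lin - np.exp(pred)
    ss_tot = float(np.sum((lin - lin.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CorrectionModel(
        coefficients=coeffs,
        fit_r2=r2,
        reference_source=reference_source,
        pooled=tuple(float(b) for b in pooled_beta),
    )


def select_diploid_like_bins(
    diagonal: DiagonalTrack,
    quantile_band: tuple[float, float] = (0.25, 0.75),
) -> np.ndarray:
    """Mask of bins whose intensity lies in the central inter-quantile band.

    The band is computed over all unmasked bins genome-wide, so chromosomes
    sitting at an aberrant level (e.g. a monosomy occupying a minority of
    the genome) fall largely outside it.  If all intensities are equal the
    band degenerates to the whole set.
    """
    vals = diagonal.values
    usable = diagonal.mask & np.isfinite(vals)
    lo, hi = np.quantile(vals[usable], quantile_band)
    return usable & (vals >= lo) & (vals <= hi)


def fit_correction_internal(
    diagonal: DiagonalTrack, covariates: CovariateTrack
) -> CorrectionModel:
    """Fit on the sample's own diploid-like bins (no reference map)."""
    keep = select_diploid_like_bins(diagonal)
    sub = DiagonalTrack(diagonal.bins, diagonal.values, keep & diagonal.mask)
    return fit_correction(sub, covariates, reference_source="internal_diploid_bins")


def apply_correction(
    diagonal: DiagonalTrack,
    covariates: CovariateTrack,
    model: CorrectionModel,
) -> DiagonalTrack:
    """Divide raw intensities by the predicted correction factor.

    Bins with mappability below threshold, zero cut sites, or non-positive
    predicted correction are masked.
    """
    factor = model.predict(covariates)
    ok = _usable(diagonal, covariates) & (factor > 0)
    values = np.full(len(factor), np.nan)
    values[ok] = diagonal.values[ok] / factor[ok]
    return DiagonalTrack(diagonal.bins, values, ok)
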