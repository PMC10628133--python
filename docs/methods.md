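# Methods

This note documents the models, estimators and numerical choices behind
`hicdeconv`, and what the synthetic study conditions do and do not probe.

## Problem and model

A chromatin-contact (Hi-C / Fix-C) library prepared from a tumor sample is
a mixture of reads from genetically distinct cell populations.  Because
spurious inter-cellular ligation is negligible, the binned contact matrix
of a mixture is, in expectation, the read-weighted superposition of the
per-population matrices.  Two consequences drive everything here:

1. **On-diagonal intensities carry dosage.**  The self-contact count of a
   50 kb bin is proportional to the bin's absolute copy number times a
   bin-specific technical factor.  After dividing out that factor, the
   corrected track of a mixture with cancer fractions `f_p` and integer
   per-population copy numbers `n_{p,i}` satisfies

       corrected_i / C  ≈  2 + Σ_p f_p (n_{p,i} − 2)

   with one unknown scale `C` (intensity per copy).
2. **Off-diagonal blocks carry junctions.**  A fusion joining loci from
   two chromosomes places cis-decay signal into the corresponding
   inter-chromosomal block: one enriched quadrant per non-reciprocal
   junction (four orientations, `P1-NE/NW/SE/SW`), or an opposing-quadrant
   "bow-tie" for a reciprocal, copy-neutral translocation (`P2-main`,
   `P2-anti`).

Identifiability requires three working assumptions: the most common copy
number of the mixture is known (default 2; it fixes `C` via the main mode
of the corrected intensities); profiles are as close to diploid as the
data allows; and the number of populations is the smallest statistically
compatible with the data.  Without these, e.g. uniform diploid and uniform
triploid genomes, or a 50/50 mixture with a triploid chromosome versus a
75/25 mixture with a tetraploid one, are indistinguishable.

## Covariate correction

Raw diagonal intensities are modeled multiplicatively as copy number times
a corrector that is linear in GC content, mappability and restriction-site
count, with separate coefficients and intercept per A/B compartment.  The
printed linear form has no explicit intercept; one is required for a
usable fit and is always included.  Fitting is ordinary least squares on
log intensity (the multiplicative model is additive in logs, and the
exponentiated prediction is automatically positive); the variance
explained is reported on the linear scale.  Training data come from a
copy-number-uniform source: an external reference map from the same
protocol when available, otherwise the sample's own "diploid-like" bins —
the central 25th–75th percentile band of the intensity distribution taken
genome-wide (a genome-wide band is what lets an arm or chromosome sitting
at an aberrant level fall outside it; toy genomes carry no centromere
annotation, so chromosome arms are not modeled).  Bins with mappability
below 0.5, zero cut sites, or a partial chromosome-end bin are masked
throughout.  Compartments with fewer than 30 usable bins fall back to the
pooled fit with a warning.  No ICE/KR balancing is ever applied — matrix
balancing would flatten exactly the dosage signal being estimated.

## Scale estimation

`C` is initialized from the highest mode of a Gaussian KDE (Silverman
bandwidth) of the corrected values, refined by bounded scalar optimization
of the density, then re-anchored on the *mean* of the modal cluster: the
inference consumes window means, and for skewed noise the density mode
sits visibly below the cluster mean.  A near-tie between two modes (within
1%) raises an error asking for an explicit `mode_copy_number`.  A residual
multiplicative error in `C` is additionally treated as a nuisance
parameter re-estimated inside the fraction scan (below), so the final
result does not depend on the initialization being exact.

## Joint fraction / copy-number inference

The estimator combines a coarse global scan with a fine segment-level
polish:

* **Window scan.**  Overlapping windows (default 40 bins = 2 Mb, 50%
  overlap) summarize the corrected track by their *means* — means, not
  medians, because only the mean of a weighted sum of noise variables is
  linear in the mixing weights; a median-based center shifts nonlinearly
  with the weight under skewed counts and displaces the levels.  For each
  candidate fraction `f` on a grid (0.05–1.00, step 0.02), each window
  takes the integer `n ∈ [0, 8]` minimizing a Huber cost (scale: 1.4826 ×
  MAD of within-window residuals, floored at 1% of the diploid level so
  noiseless input keeps an informative cost surface) between the window
  mean and the level `c (2 + f (n − 2))`, with the nuisance scale `c`
  re-fitted per `f` by Huber-weighted least squares.
* **Noise-floor penalty.**  Each unit of `|n − 2|` costs one squared
  standard error of the window mean.  Under pure noise the best aberrant
  level can absorb about half a squared SE per window, so noise-chasing
  into a fine comb of levels at small `f` is strictly unprofitable, while
  a real deviation wins once it exceeds ~1.4 window SEs.  The
  half-fraction harmonic — which mimics the data with doubled `|n − 2|` —
  pays twice the penalty of the true fraction.  A small global parsimony
  term (10⁻³ × mean `|n − 2|`) breaks exact ties the same way.
* **Change-point backbone.**  Boundaries come from a fraction-independent
  recursive mean-shift (binary) segmentation with standardized two-sample
  tests (threshold 3 SDs; generous on purpose — spurious splits are healed
  by relabeling, missed boundaries cannot be recovered).  Segments are
  then labeled from their own means (which pool enough bins to decide
  cleanly and avoid the winner's-curse fragmentation of window-level
  labeling), and the fraction is polished by a robust size-weighted
  regression of segment mean on `(n − 2)`, iterated with relabeling and
  capped at 0.04 per step so the polish walks within its basin.  Final
  boundaries are refined to the bin grid by a local CUSUM, which peaks at
  the true step with drift half the step height per bin.
* **Basin lookahead.**  When several populations overlay, the single-pass
  discrepancy can be nearly the same for the true dominant fraction and a
  compromise fraction.  Up to three near-degenerate minima of the
  discrepancy curve are therefore carried forward; each candidate is
  peeled, one further population is fitted to its residual, and the
  candidate whose explanation terminates in the flattest, most
  parsimonious residual wins (near-ties go to the candidate that explains
  the most on its own).
* **Peeling and model selection.**  The accepted population's contribution
  `f (n_i − 2)` is subtracted and the procedure repeated (default at most
  3 populations).  A new population is accepted only if its objective
  improvement exceeds the 95th percentile of improvements obtained on
  block-bootstrap replicates (1 Mb blocks) of the *fit residuals*
  re-centered on the flat diploid level — the null of "no further
  structure".  Resampling the raw residual would preserve aberrant levels
  inside each block and make true signal indistinguishable from its own
  null, so the noise, not the signal, is what gets resampled.

Change points receive an empirical confidence `1 − p`, where `p` ranks the
observed flanking-median difference among differences at random no-step
positions inside the two flanking segments; segments shorter than 5 bins
are flagged with undefined confidence.  Fractions receive 95% bootstrap
CIs from within-segment block resampling (blocks of 20 bins, capped at
half the segment) with profiles held fixed and fractions refit by
coordinate descent; intervals are widened if needed to contain the point
estimate, and fewer than 50 replicates triggers a warning.

## Rearrangement detection

**Type-1** (copy-number-coupled) candidates are all pairs of inferred
change points on distinct chromosomes (or ≥ 10 Mb apart in cis).  The
2W × 2W block around each pair (W = 40 bins) is first divided by the outer
product of the mixture's per-bin dosages `2 + Σ f_p (n_{p,i} − 2)` —
otherwise the copy-number *product* structure of the background, which by
construction steps exactly at the candidate anchors, mimics a junction.
Two statistics are computed: the maximum quadrant mean over the block mean
and an edge contrast across the anchor row and column.  Each is calibrated
against its empirical distribution over translated anchors along the same
row and column bands (self-excluding ± W bins), the two empirical p-values
are combined by Fisher's method, and Benjamini–Hochberg controls the FDR
(default 0.1) across candidates.  Blocks truncated by chromosome ends are
shrunk symmetrically and flagged low-confidence.

**Type-2** (reciprocal, copy-neutral) detection is a global scan: each
inter-chromosomal block is thresholded at the 0.999 quantile of its
nonzero entries, 8-connected components above threshold (≥ 4 pixels) are
ranked by summed intensity, and each component's focal (maximum) point is
scored by local concentration (radius 10 vs 30 bins), focal enrichment
over row/column *means* (medians are zero in sparse desk-scale trans
blocks), and the rank correlation of intensity with distance from the
focal point (negative for a true junction; this is what rejects
compartment checkerboards).  All three are translation-calibrated, Fisher
combined, BH controlled; only components whose quadrant pattern is a
genuine bow-tie (both quadrants of one opposing pair above both of the
other) are reported as type-2, and nearby components of one junction are
deduplicated.  Significant type-1 calls with an anchor within ± 2 bins of
a change point inherit that population and `|Δn|` as the event's copy
number; ties between populations go to the higher change-point confidence
and are flagged.

The magnitude of off-diagonal signal is deliberately not modeled — only
presence/absence patterns are scored — and breakpoints are reported at bin
(50 kb) resolution.

## Allele-frequency spectra

Nominally inherited heterozygous variants (panel allele frequency in the
closed band [0.40, 0.60], site depth ≥ 8) yield per-window (500 kb)
alternate-fraction spectra.  With `a` copies of the variant haplotype and
`b` of the other at cancer fraction `f`, peaks sit at

    q = (f a + (1 − f)) / (f (a + b) + 2 (1 − f))       and 1 − q.

Windows are classified by enumerating all unordered `(a, b)` with
`a + b = n` (from the contact-map decomposition) and minimizing the
earth-mover distance between predicted and observed peak sets (KDE maxima
with reflection at 0 and 1 so LOH boundary peaks survive); distances above
0.08 give "uninformative", `n = 0` gives "hemizygous-null".  The depth
threshold of 8 keeps the binomial peak width below ~0.18.  No matched
normal is used; the panel-AF band is what excludes somatic variants.

## Simulator

The generator renders expected maps from karyotypes (ordered reference
segments with strand and copy count per derived chromosome): cis contacts
within a molecule decay as `p0 (d + 1)^(−α)` (α = 1 by default, the
canonical decay; fusion junctions thereby produce all six off-diagonal
patterns with orientation set by segment strands), background between any
two bins is `β0 · cn_i · cn_j` (β0/p0 = 2×10⁻⁴ keeps the trans read share
near 15%), an A/B checkerboard enters as `1 + κ s_i s_j` (κ = 0.15), a
multiplicative per-bin covariate factor enters as `g_i g_j`, and diagonal
entries are exactly proportional to `cn_i × g_i²`.  Covariate tracks are
AR(1)-smooth GC (0.3–0.6) and mappability (0.5–1.0), Poisson cut sites
(mean 10), and alternating A/B blocks (mean 20 bins).  Counts are Poisson,
optionally over-dispersed by a gamma multiplier (negative-binomial,
`Var = μ + r μ²`); real Fix-C counts follow no parametric family, so the
sampling law is a declared idealization that the inference never assumes.
Optional uniform intercellular background (default off; 0.3% mirrors the
empirical cross-species ligation bound).  Superposition of expected maps
is exact by construction, and all sampling is seeded.

The standard study conditions are a ~300 Mb eight-chromosome toy genome at
50 kb bins; an aneuploid karyotype with seven arm-level events whose gains
and losses nearly balance (mean ploidy 2.02), so read-weight mixing and
cell-fraction purity agree to < 0.5 pp, as in read-mixture validations of
real karyotypically unstable lines; and a disjoint five-event second
population for peeling studies.  What the simulator does *not* emulate —
TAD/loop fine structure, fragment-level biases, replication timing,
translocation-specific contact magnitudes, alignment artifacts — bounds
what passing tests show about real data: they validate the estimators
under the stated generative model, not the upstream measurement process.

## Numerical choices and limitations

* Coordinates are 0-based half-open; bins are fixed-width, the last bin of
  each chromosome may be short and is excluded from fitting.  A bin split
  by a segment boundary takes the copy number of the majority of its bp,
  exact halves rounding down.
* All stochastic steps take explicit seeds; pipeline outputs are
  byte-reproducible under a fixed config and record config hash, seeds and
  version.
* Problem sizes in the validation suite (60–300 Mb genomes, 10⁶–2×10⁷
  reads, 25–60 bootstrap replicates) were chosen as the smallest at which
  the estimators' asymptotics visibly hold.
* Subclonal (non-integer) states, whole-genome doubling beyond the mode
  assumption, sub-bin breakpoints, phasing, and somatic point mutations
  are out of scope.  The greedy peel is approximate for many populations
  (the exact problem is combinatorial); behavior beyond three populations
  is unvalidated.  Fractions below 0.05 are declared undetectable rather
  than guessed.
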