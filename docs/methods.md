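# Methods

This note documents the models, conventions and design choices behind
`lungqct`, in the spirit of the methods documentation of statsmodels or
lifelines: what is computed, under which assumptions, and what the
synthetic validation does and does not show.

## Imaging model and calibration

A CT series is read as a single 3-D attenuation volume `voxels[z, y, x]`
in Hounsfield units, slices sorted by spatial position along the slice
normal (instance numbers and file names are unreliable across vendors).
Stored pixels are converted with the per-slice rescale slope/intercept.
Values below −1024 HU are clamped to −1024 on load: air defines the bottom
of the analysis range, and anything below it is scanner padding that would
otherwise leak into the segmentation band.  Slice-gap uniformity is
enforced within 10% of the median gap; overlapping reconstructions are not
deduplicated (all slices enter the histogram, which is documented
behaviour rather than a hidden choice).  Only axial single-frame CT
storage is supported; enhanced multi-frame objects are rejected with a
clear message to keep the reader small and auditable.

## Segmentation

Parenchyma is defined as the attenuation band [−1024, −200] HU.  Region
growing from a seed with an inclusion predicate that depends only on the
voxel's own HU fills exactly the band-connected component containing the
seed, so the implementation labels the thresholded volume once
(6-connectivity; diagonal leaks through the mediastinum are a known
failure mode of wider stencils at thin-slice resolution) and then applies
the growing logic declaratively:

1. components with any voxel on the in-plane image border are exterior
   air (room air at ≈ −1000 HU is inside the band) and are discarded;
2. a component qualifies as lung only if it contains a confidently
   aerated seed voxel at ≤ −500 HU — this reproduces automatic seeding
   without user clicks;
3. the two largest qualifying components are kept (one when the lungs
   connect across the carina); size ties break toward the more negative
   mean HU, then the smaller label, so output is deterministic.

A result below a configurable minimum volume (default 500 ml, meant for
human-scale scans; phantoms pass a smaller value) warns rather than
errors, because small-volume masks are often legitimate on cropped or
scaled data.  Optional airway removal drops *separate* components that are
tubular (per-slice area < 3 cm² over ≥ 5 contiguous slices) and near the
in-plane midline.  It is off by default: phantoms carry no airways, the
criterion cannot separate an airway fused with the lung component, and
including or excluding central airway air measurably shifts MLD and
kurtosis — so it is an explicit, reported config toggle.

## Histogram indexes

All five indexes are functions of the multiset of masked HU values; no
binning enters any computed number (bin width affects plots only).
Moments are population moments (divide by n).  Kurtosis uses the excess
convention (Gaussian → 0), the dominant convention in the CT-densitometry
literature; Pearson (Gaussian → 3) is selectable.  No small-sample bias
correction is applied: with the ~10⁵–10⁶ voxels of a segmented lung the
correction is orders of magnitude below measurement noise.  A zero-variance
mask yields NaN skewness/kurtosis with a warning, never a silent 0.

Band membership uses closed intervals: HAA% counts [−600, −250] HU, FA%
counts [−1024, −700] HU, and a voxel exactly on a boundary belongs to its
band.  The gap (−700, −600) HU belongs to neither band, exactly as the
windowing scheme implies; no attempt is made to close it.  MLD is computed
over the same [−1024, −200] segmentation band that defines the mask, which
couples MLD to the segmentation window; this coupling is inherent to the
method and is stated rather than worked around.

## Survival statistics

*Cox models* are fitted by lifelines' partial-likelihood Newton-Raphson
with the Efron tie approximation — the best-behaved default with tied
event days, and the reason exact agreement with Breslow-tie software is
not expected.  Convergence tolerances are tightened (‖δ‖ < 1e−12) so
coefficients match an independent brute-force maximization of the written
partial likelihood to better than 1e−6 on small fixtures.  Confidence
intervals are Wald intervals on the log-hazard scale, exponentiated for
reporting.  `AIC = 2k − 2·log PL` is recomputed in-package and models are
compared only when fitted to the identical cohort/time/event data (the
fit stores a cohort fingerprint and the ranking refuses mixed inputs).

*ROC cut-offs.* The AUC is the Mann-Whitney probability that a deceased
subject's value lies on the predicted-death side of a survivor's; its
p-value uses the normal approximation to the rank-sum null with tie
correction.  The operating threshold is the observed value maximizing
Youden J, with deterministic tie-breaking: higher sensitivity first
(favouring detection of deaths), then the smaller threshold.  Direction
conventions are fixed per index — low kurtosis/skewness predict death,
high MLD/HAA%/FA% predict death — with automatic orientation (AUC ≥ 0.5)
for unknown variables.

*Kaplan-Meier / log-rank* use the product-limit estimator and two-group
log-rank test (lifelines), validated exactly against hand-computed
fixtures.  A stratification with zero events raises rather than returning
an undefined test.

*Visit comparison.* Baseline vs ~12-month values are compared per variable
by the unpaired rank-sum test — the method of record for this contrast in
the cohorts this package emulates — with a clearly labelled signed-rank
(paired) option as an extension.  The interval difference is the follow-up
median minus the baseline median.  Holm's step-down correction is applied
over exactly the family of variables in the requested table (default:
kurtosis, skewness, MLD, HAA%, FA%, FVC%, DLCO%, GAP).  The significance
level throughout is 0.05.

## Synthetic ground truth

The phantom generator emulates the attenuation structure the pipeline
measures: two ellipsoidal lungs (baseline N(−850, σ) HU) inside an
elliptic-cylinder body at 0 HU, exterior air at −1000 HU, optional
additive Gaussian noise, values clamped to the plausible CT range.
Fibrosis occupies the outermost `fibrosis_fraction` of each lung's voxels
ranked by normalized ellipsoid radius — a contiguous subpleural shell
mimicking the peripheral predominance of usual interstitial pneumonia —
with attenuation uniform on [−600, −250] HU by default.  Expected indexes
are computed directly from the values the generator placed inside the
ground-truth mask, giving an oracle for the whole
segment-then-measure path.  The default grid is 60×128×128 voxels at
2×1×1 mm (≈10⁶ voxels), chosen so a full phantom → segmentation → indexes
cycle runs in about a second while the lungs remain several hundred
voxels across.

What the phantom does *not* model: airway trees, vessels, cardiac motion,
reconstruction-kernel texture, incomplete inspiration.  Passing phantom
tests therefore demonstrates correctness of the algorithmic chain
(calibration, connectivity, band arithmetic), not robustness to clinical
image quality.

The cohort generator draws covariates from marginal distributions at the
scale of a typical IPF cohort at diagnosis (e.g. skewness ≈ N(1.28,
0.33²), MLD ≈ N(−771, 47²), FVC% ≈ N(84, 16²)), all loaded on a single
latent severity factor (loading 0.7, signed per variable) so the indexes
are mutually rank-correlated the way fibrotic burden couples them in real
scans.  Survival times follow a Weibull proportional-hazards model,
`S(t|x) = exp(−(t/λ)^k · exp(β·(x − μ)))`, with shape k = 1.5 (visibly
non-exponential curves), scale λ = 1300 days (median survival ≈ 2.8 years
at the covariate mean, in the 3–5 year range typical of IPF), and default
effect β = −1.0 per unit of skewness.  Censoring is an independent
Uniform(0, 3650 days) draw, yielding ≈30% censoring.  Percent-predicted
values are clipped to (0, 200), band percentages to [0, 100], and GAP
points rounded to the 0–8 scale — so the extreme tails of the marginals
are mildly truncated relative to their nominal Gaussians.

## Numerical and degenerate-input choices

- All randomness flows through explicit `numpy.random.default_rng` seeds;
  no global state is touched, and equal specs give bit-identical outputs.
- DICOM storage is uint16 with intercept −1024, so a write/load round
  trip is exact to the ±0.5 HU integer quantization.
- Empty strata, zero-event cohorts, constant covariates, single-voxel
  masks and all-censored stratifications raise informative errors;
  zero-variance histograms and sub-minimum lung volumes warn.
- The CSV layer never imputes: missing stays missing, and summary
  percentages use non-missing denominators.

## Validation design and problem sizes

The acceptance script and test suite validate each claim at a size chosen
to make the check sharp but cheap: moment arithmetic on 10⁵ truncated-
Gaussian samples against an independently written direct-moment
computation (agreement to 1e−9) and the analytic truncated-normal moments
(within 3 SE); segmentation Dice ≥ 0.99 on the default ≈10⁶-voxel phantom
at 0 and 20 HU noise; end-to-end HAA% recovery within 0.5 percentage
points at 30% fibrosis; Cox coefficient recovery as the mean over 100
simulated cohorts of n = 500 under true log-HR −1.0 (bias ≤ 0.1, CI
coverage 90–99%); Youden cut-offs identical to an exhaustive scan on
1,000 random datasets; Kaplan-Meier and log-rank values equal to
hand-computed small fixtures.

## Known limitations

- The segmentation has no vessel or lobe awareness and guarantees nothing
  about left/right separation; fused lungs are returned as one component.
- Airway removal cannot excise airways connected to the parenchyma
  component.
- The AUC p-value is the rank-sum normal approximation; DeLong-style
  variance estimation is not implemented.
- The hazard model used for simulation is proportional by construction;
  no diagnostics for non-proportionality are provided beyond what
  lifelines offers externally.
- GAP points are consumed as an input column, never computed from raw
  physiology.
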