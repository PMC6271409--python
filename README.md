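# lungqct

Quantitative CT densitometry of the lung, and its use as a prognostic
marker in fibrosing interstitial lung disease.

Visual grading of thin-section chest CT in idiopathic pulmonary fibrosis
(IPF) is slow and suffers from substantial inter-observer variability.
`lungqct` implements the standard histogram-based alternative: segment the
lung parenchyma automatically, summarize its attenuation histogram with a
handful of scalar indexes, and evaluate those indexes as predictors of
survival.  The package is aimed at imaging researchers and
pulmonology/radiology groups who want a reproducible, scriptable version
of this workflow, plus synthetic phantoms and simulated cohorts to test
every stage without patient data.

## What it computes

**Segmentation.** Lung parenchyma is grown through the closed attenuation
band [−1024, −200] HU under 6-connectivity, starting from automatic
low-attenuation seeds; components touching the in-plane border (room air)
are discarded and the two largest seeded components are kept.  Optional
removal of trachea-like structures is available but off by default.

**Histogram indexes.** With `x` the masked voxel HU values, `μ = mean(x)`
and `m_k = mean((x − μ)^k)`:

- mean lung density `MLD = μ` (HU)
- skewness `= m₃ / m₂^{3/2}`
- kurtosis `= m₄ / m₂² − 3` (excess convention; Pearson available)
- `HAA% = 100 · #{x ∈ [−600, −250]} / n` (high attenuation areas)
- `FA% = 100 · #{x ∈ [−1024, −700]} / n` (fibrotic-areas windowing)

Fibrosis replaces aerated parenchyma, so it raises MLD, HAA% and FA% and
flattens/symmetrizes the histogram, lowering kurtosis and skewness.

**Survival workflow.** Univariate and multivariate Cox
proportional-hazards models (Efron ties, Wald CIs) with
`AIC = 2k − 2·log PL` to rank competing indexes; ROC analysis against the
vital-status flag with the cut-off maximizing Youden `J = sensitivity +
specificity − 1`; Kaplan-Meier curves for the two strata at each cut-off
with a log-rank test; baseline vs ~12-month comparison by rank-sum test
with Holm correction; Spearman correlations between indexes.

**Synthetic ground truth.** `generate_phantom` builds thoracic phantoms
(ellipsoidal lungs ≈ −850 HU in a soft-tissue body, subpleural fibrotic
shell in the ground-glass band) with exact masks and expected indexes;
`generate_cohort` simulates cohorts under a Weibull proportional-hazards
model with chosen log hazard ratios and independent censoring.

## Worked example

```python
from lungqct import (segment_lungs, compute_indexes, fit_cox,
                     roc_cutoff, km_by_cutoff, rank_by_aic)
from lungqct.synthetic import PhantomSpec, CohortSpec, generate_phantom, generate_cohort

# one scan: phantom with a 25% fibrotic shell and 20 HU of noise
res = generate_phantom(PhantomSpec(seed=1, fibrosis_fraction=0.25, noise_sd_hu=20.0))
mask = segment_lungs(res.volume, min_volume_ml=100)
print(compute_indexes(res.volume, mask).as_dict())
# {'kurtosis': 0.223, 'skewness': 1.364, 'mld': -743.75,
#  'haa_pct': 23.85, 'fa_pct': 75.0, 'lung_volume_ml': 327.45, ...}

# a cohort: true log-HR -1.0 per unit of skewness
recs = generate_cohort(CohortSpec(seed=1, n=300))
fit = fit_cox(recs, ["skewness"])
print(fit.table.round(4))
#           coefficient  hazard_ratio  standard_error  p_value  ci95_low  ci95_high
# skewness      -1.1985        0.3017          0.2219      0.0    0.1953     0.466

cut = roc_cutoff(recs, "skewness")       # cut-off 1.32, AUC 0.587 (p = 0.016)
km = km_by_cutoff(recs, "skewness", cut.threshold, cut.direction)
print(km.logrank_p)                      # 3.4e-08: low skewness dies earlier
```

The fitted hazard ratio 0.30 (CI 0.20–0.47) recovers the simulated effect
(true HR e⁻¹ ≈ 0.37); stratifying at the Youden cut-off separates the
Kaplan-Meier curves decisively.  Ranking the five indexes by AIC
(`rank_by_aic`) puts skewness first on this cohort, as expected when it
drives the hazard.

## Command line

```sh
lungqct phantom -o ph --seed 9                 # DICOM series + mask + expected JSON
lungqct extract ph/dicom -o indexes.csv        # per-scan index table
lungqct cohort-sim -o cohort.csv --seed 4      # simulated cohort CSV
lungqct analyze cohort.csv -o report           # Cox/AIC/ROC/KM/visits bundle
```

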