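# Methods

## Scope

`xciskew` implements an analysis pipeline for age-acquired skewing of
X-chromosome inactivation (XCI) in blood, as measured by the HUMARA
(human androgen receptor) methylation-sensitive fragment-analysis assay
in a twin cohort. It covers four stages — quantification, cohort-level
classification, cross-sectional/intra-twin association testing, and
prospective survival analysis — plus a synthetic-data generator that
emulates the assay and the cohort structure so every stage is testable
without access-controlled data.

## Quantifying XCI from peak data

Each sample contributes triplicate mock-digest and *HpaII*-digest peak
pairs (allele fragment size in bp, peak height in RFU) and one *MspI*
digestion-efficiency control. Per replicate,

    Rm = mock allele-1 height / mock allele-2 height
    Rh = HpaII allele-1 height / HpaII allele-2 height
    Rn = Rh / Rm
    XCI% = 100 · Rn / (Rn + 1)

Allele 1 is by convention the shorter fragment; because the folded value
is direction-free, any fixed convention is equivalent. Dividing Rh by Rm
cancels allele-specific amplification bias (shorter fragments amplify
preferentially), which is the property the assay relies on.

Numerical conventions:

- Heights below a detection floor (default 50 RFU) are clamped to the
  floor, except that a single undetected *HpaII* allele with the other
  allele detected reads as complete skew (exactly 0 or 100). Both
  *HpaII* alleles undetected is a digestion/amplification failure.
- A sample's XCI is the arithmetic mean of the replicate values; the QC
  statistic is the replicate coefficient of variation, sample SD (n−1)
  divided by the mean, with exclusion above 0.15. The CV is taken on the
  replicate XCI percentages (the per-replicate summary computed first);
  taking it on Rn instead would be a defensible alternative.
- Folding maps XCI% to max(x, 100−x) ∈ [50, 100]; the parental direction
  of skew is uninformative.
- QC status precedence: `assay_fail` (no mock amplification in ≥2
  replicates, or <2 usable replicate ratios) > `homozygous_uninformative`
  (allele separation < 3 bp — one CAG unit — in any mock replicate) >
  `digestion_fail` (*MspI* residual above 10% of the mean mock height) >
  `cv_fail` > `pass`. An absent *MspI* lane passes the digestion check
  with a logged warning. Homozygous single peaks are encoded as equal
  allele sizes, so informativeness is decided downstream of parsing.

## The categorical skew variable

The folded XCI values of all QC-passing samples are summarised by their
mean and SD, and each sample is assigned z = (folded − mean)/SD, with
z < 1 random (0), 1 ≤ z < 2 skewed (1), z ≥ 2 extreme (2); boundaries are
inclusive upward. On the cohort the design targets, these cuts fall near
75% and 91% folded XCI, but they are cohort moments, not fixed constants:
they are fitted once on the full QC-passing cohort, frozen, and reused
for every subgroup analysis. An alternative normalisation (z-scoring the
unfolded 0–100 values and classifying on |z|) is available via
`mode="absolute"`; the folded-scale default is the convention that makes
mean + 1·SD ≈ 75 and mean + 2·SD ≈ 91 arithmetically consistent. Whether
the original normalisation was moment- or rank-based is not recoverable;
the moment-based reading is an assumption. For survival analyses the
skewed and extreme groups are pooled into a binary flag, because event
counts are too small to resolve them.

## Association analyses

All cross-sectional tests use a linear mixed model with a single random
intercept per family (absorbing twin relatedness), fitted by REML via
statsmodels `MixedLM`; a singular fit falls back to OLS with a warning.
Outcomes are z-scored before fitting. Covariate schemes per test family:
ageing tests (age), blood counts and myeloid ratios (age, BMI,
seasonality, smoking), cytokines (age, seasonality), ASCVD score (BMI,
monocyte count). Monocyte- and neutrophil-to-lymphocyte ratios are
always computed from the counts, never accepted from input; zero
lymphocyte counts yield missing ratios with the row retained.

Each family carries its Bonferroni threshold as conventionally printed —
0.007 for 7 tests, 0.005 for 10, 0.025 for 2, 0.01 for 5 — rather than
recomputed at full precision, so significance flags match reported
rounding.

The intra-twin design compares skew-discordant co-twins with a one-sided
paired Wilcoxon signed-rank test (alternative: higher value in the
skewed co-twin). Zero differences are dropped before ranking (Pratt
handling optional); ties get average ranks. For ≤ 12 informative pairs
the null is the full 2^n sign-flip enumeration over the observed ranks;
beyond that, a normal approximation with tie and continuity correction.
The exact branch is authored here because the enumeration must respect
arbitrary tie patterns; scipy's implementation serves as an independent
cross-check in the tests, not as the implementation.

## Survival analyses

Cancer analysis eligibility mirrors registry practice: non-melanoma skin
cancer reports are filtered first (they neither count as events nor
exclude the individual); any remaining diagnosis before study entry or
within 6 months of entry (boundary inclusive — a conservative reading of
"within") excludes the individual; the event is the first remaining
diagnosis; censoring is at min(10 years, study end, death). Durations
are computed in days and divided by 365.25; a legitimate same-day
death/censoring is clamped to half a day at risk. All-cause mortality
mirrors this minus the diagnosis-based exclusions.

The Cox model adjusts for age and zygosity and handles relatedness with
family-clustered robust (sandwich) standard errors — a standard,
reproducible choice where the original mechanism ("controlled for
relatedness") is ambiguous between frailty, clustering, and covariate
adjustment. A shared-frailty backend was considered and not shipped: no
installed Python survival library fits one, and the clustered-variance
reading is the common default for twin cohorts. A Schoenfeld-type
proportional-hazards diagnostic is run on every fit and its minimum
p-value reported. Kaplan-Meier curves and cumulative event counts per
binary skew group accompany the model.

## The synthetic cohort generator

The generator defines the conditions under which the pipeline is tested.
It does **not** model the biology of skew acquisition mechanistically —
it is a minimal statistical emulation with the features the analyses
rely on:

- **Latent skew.** Folded skew is 0.5 + 0.5·X with X ~ Beta(k·t, k·(1−t)),
  t(age) = 0.28 + 0.044·(age−40)⁺/10, k = 3.0 — a two-parameter
  age-drift least-squares calibrated to the reference age-band skew
  prevalences (giving 18/24/33/46% across <40, 40–59, 60–69, ≥70 vs the
  reference 12/28/37/44%; the family cannot match all four bands
  exactly, and the tested property is the monotone stepwise increase).
  The closed-form band exceedance is exposed (`folded_exceedance`) as
  the oracle for Monte-Carlo checks. Direction (which parental X) is a
  fair coin. Co-twins share age and a Gaussian-copula latent value with
  correlation 0.68 (MZ) / 0.05 (DZ), calibrated so categorical
  discordance lands near the reference 27% / 45.5%; note independent
  pairs already give ~44% discordance under this marginal, so the DZ
  value sits near the boundary of what any shared-latent model allows.
- **Assay layer.** Mock heights = amplitude × length bias (1.2 on the
  shorter allele) × mean-one lognormal noise; *HpaII* heights carry an
  extra factor equal to each allele's inactive fraction, so the
  normalised ratio recovers p/(1−p) exactly at zero noise. Noise sigma
  defaults to 0.05, at which organic replicate-CV failures are <1% and
  folded-XCI measurement error is ~1 percentage point, consistent with
  the assay's reported 0.99 replicate correlation. Planted QC statuses
  (failed 194/2382, homozygous 601/2382, CV 12/2382 by default) are
  assigned as exact disjoint counts so sample accounting is
  reproducible. Stutter (−1 repeat) is available but off by default.
- **Phenotypes.** Standardised outcomes follow effect·skew + covariates
  + family intercept + noise; blood counts are exponentiated from the
  latent to stay positive. The reference study prints p-values but no
  effect magnitudes for the monocyte, IL-10 and ASCVD associations, so
  the planted sizes (0.2, −0.45, 0.3 SD) are free parameters of the
  generator, not reproductions.
- **Events.** Exponential event times under proportional hazards with
  log-HR log(1.95) for cancer and log(1.39) for death, an age trend of
  0.05/year, staggered entry 2–17 years before a fixed study end, and
  administrative censoring. The baseline hazards (2.7e-3 and 1.8e-3 per
  person-year at age 60) were solved from the closed-form expected event
  count to give ~58 cancer events at n = 1,417 and ~41 deaths at
  n = 1,575. The constant baseline is immaterial to the Cox analysis,
  which is semi-parametric in the baseline.

What passing tests on this generator do *not* show: robustness to
electrophoresis artefacts beyond simple stutter, non-proportional
hazards, informative censoring, genuinely non-Gaussian phenotype tails,
or assortative family structure — none of which the generator emulates.

## Problem sizes used in the checked experiments

The hazard-ratio recovery experiment uses 200 replicates of the full
n = 1,417 design; type-I-error calibration uses 400 null cohorts of 240
individuals (the mixed model's calibration is insensitive to cohort size
well below the study's n, and this size keeps each REML fit fast); the
formula-fidelity oracle uses 1,000 random peak quadruples; exact-test
oracle equivalence is enumerated for all n ≤ 12.

## Known limitations

- The cohort cutpoints (≈75/91%) are moments of the measured cohort; on
  a synthetic cohort they land where the generator's folded distribution
  puts them (typically 77–82 / 90–94 depending on noise), which is the
  intended behaviour of a cohort-relative definition, not a defect.
- The OLS fallback for singular mixed models changes the variance model;
  it is logged and recorded in the result's `method` field.
- The eligibility filter requires complete, consistent dates; it
  validates but does not impute.
- `MixedLM` Wald p-values are asymptotic; at very small n they are
  mildly anti-conservative, which the calibration tests bound but do not
  remove.
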