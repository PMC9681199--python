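# xciskew

Quantification and epidemiological analysis of skewed X-chromosome
inactivation (XCI) in blood.

In 46,XX individuals each cell silences one X at random during
development, so blood is normally a ~1:1 mosaic of maternal-X-active and
paternal-X-active cells. With age this mosaic can drift — *age-acquired
XCI skew* — reflecting changes in the haematopoietic stem cell pool, and
skew is of interest as a biomarker of chronic disease risk alongside
clonal haematopoiesis. `xciskew` is for researchers who measure XCI with
the HUMARA assay (a methylation-sensitive restriction digest plus PCR of
the polymorphic CAG repeat in *AR*) and analyse it in family-structured
cohorts.

## What it computes

**Quantification.** Per replicate, with peak heights from the mock and
*HpaII* digests,

    Rm = mock h₁/h₂,  Rh = HpaII h₁/h₂,  Rn = Rh/Rm,
    XCI% = 100 · Rn/(Rn + 1),

folded onto [50, 100] since the parental direction of skew is
uninformative. QC: replicate CV ≤ 0.15, heterozygosity (informative CAG
alleles ≥ 3 bp apart), and an *MspI* digestion-efficiency control.

**Classification.** Cohort z-scores of folded XCI define the categorical
variable: z < 1 random, 1 ≤ z < 2 skewed, z ≥ 2 extreme skew (on the
reference cohort these cuts correspond to ≥75% and ≥91% XCI).

**Analyses.** Family random-intercept linear mixed models with per-family
Bonferroni thresholds (ageing markers, blood counts, monocyte- and
neutrophil-to-lymphocyte ratios, cytokines, ASCVD risk score); exact
one-sided paired Wilcoxon tests for skew-discordant twin pairs;
registry-style cancer eligibility filtering and age-adjusted Cox
proportional-hazards models with family-clustered robust variance;
Kaplan-Meier summaries; age-band prevalence and longitudinal transition
tables.

**Synthetic cohorts.** A generator emulating the assay (triplicate peaks
with amplification bias, noise, planted QC failures) and the twin-cohort
structure (MZ > DZ skew concordance, age drift, skew-linked phenotypes,
event times under proportional hazards), so the full pipeline runs and is
tested without access-controlled data. See `docs/methods.md` for the
model and its calibration.

## Worked example

Simulate a cohort of 1,575 individuals (423 MZ pairs, 257 DZ pairs, 215
singletons) and push it through the pipeline:

```sh
xskew simulate --seed 1 --out demo
xskew run --peaks demo/peaks.tsv --cohort demo/cohort.tsv \
          --events demo/events.tsv --out demo/run
```

which prints

    wrote synthetic cohort (1575 individuals) to demo
    analyzable samples: 1030 of 1575 assayed

The manifest (`demo/run/manifest.json`) accounts for every sample: of
1,575 assayed, 128 failed amplification, 397 were homozygous for the CAG
repeat (uninformative), 20 exceeded the replicate CV threshold, leaving
1,030 analyzable. The fitted cohort thresholds land at

    cut1=81.5% cut2=94.1% (1030 samples)

— the 1-SD and 2-SD cuts of *this* cohort's folded distribution (the
classification is cohort-relative by construction, so they need not equal
the reference 75/91%). Downstream, `demo/run/cohort_classified.tsv`
carries the skew categories merged with phenotypes; twin discordance on
this run is 15.3% for MZ and 43.5% for DZ complete pairs, reproducing the
expected MZ < DZ ordering, and `demo/run/survival_summary.tsv` holds the
Cox hazard ratio for the binary skew flag with its eligibility
accounting.

In Python the same stages are plain functions:

```python
from xciskew.humara import read_peak_table, quantify_table
from xciskew.classify import fit_thresholds, classify

measures = quantify_table(read_peak_table("demo/peaks.tsv"))
passing = measures[measures.qc_status == "pass"]
thr = fit_thresholds(passing.xci_folded)
passing["skew_category"] = classify(passing.xci_folded.to_numpy(), thr)
```

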