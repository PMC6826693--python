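# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions made where the design was open.

## CT preprocessing

A threshold cycle is accepted as a measurement only inside the reliable
window [14, 32] (instrument guidance: earlier or later crossings are
experiment failures); values outside become missing. The window boundaries
are kept, while *detection* — membership in the per-sample global-mean
reference and in detection counts — uses the strict rule CT < 32. The two
conventions differ only at exactly CT = 32; keeping reliability inclusive
and detection strict resolves the boundary conservatively, and both are
configurable (`AnalysisConfig.ct_min/ct_max`).

Global-mean normalization subtracts each sample's mean detected CT. Two
exact algebraic properties follow and are asserted in tests: any constant
added to all CTs of one sample cancels, and re-normalizing already-centered
data is a no-op. A sample with fewer than two detected assays has a
degenerate reference and aborts with a named error rather than being
silently dropped — sample-level QC failures should be explicit and handled
upstream.

The detection filter keeps assays detected in ≥ 80% of samples, pooled over
both timepoints (the filter is about imputation risk, which does not depend
on the timepoint); the boundary is inclusive. Imputation then fills each
remaining missing well at the assay's maximum observed ΔCT plus one log2
unit — one CT unit below the assay's lowest expression — so every imputed
value is strictly less expressed than every measurement of that assay.
Order is fixed: reliability filter → normalization → detection filter →
imputation.

The CV diagnostic compares per-assay coefficients of variation before and
after normalization. CVs are computed on linear relative quantities
(2^−CT and 2^−ΔCT): this is the convention of the global-mean normalization
literature, and it avoids the degeneracy of sd/|mean| on the ΔCT scale,
where centering drives many per-assay means toward zero. A two-sample
Kolmogorov–Smirnov test on the two CV distributions quantifies the change;
a CT-scale variant (`scale="ct"`) is kept for completeness, with zero-mean
assays reported missing with a warning.

## PVCA batch assessment

PCA is run on column-centered ΔCT; the smallest set of leading components
reaching 60% cumulative variance is retained (the customary retention level
for this procedure; configurable). Each retained PC score vector is
decomposed by a linear mixed model with independent random effects for each
factor — center of origin (the batch factor), age, INSS stage, MYCN status
— and every eligible pairwise interaction (both factors ≥ 2 levels,
interaction ≥ 2 observed cells), fit by REML with variance components
clamped at zero; on non-convergence a per-factor one-way ANOVA
method-of-moments estimate is substituted and flagged. Age is a continuous
covariate used here as a grouping factor, binned into tertiles; missing
factor levels become an explicit "NA" level. Per PC, components plus the
residual are converted to proportions; the weighted average proportion
variance (WAPV) per factor is the eigenvalue-weighted mean over retained
PCs, renormalized to sum to one.

A batch WAPV strictly below 5% is "negligible"; exactly 5% classifies as
"significant" (conservative boundary, configurable). The pipeline treats a
significant verdict as a stop condition because no correction stage exists
downstream; `override_batch=True` records the decision and proceeds.

When the pipeline invokes PVCA it adds the sampling timepoint
(onset/end) to the biological factors. In a two-timepoint design the
treatment axis is routinely the largest source of variance; leaving it
unmodeled lets its residual inflate the apparent contribution of
small-center batch factors (on null-batch synthetic cohorts of this size,
by roughly 5–8 percentage points of WAPV). With the design factor modeled,
null-batch cohorts yield WAPV(origin) ≈ 0.01–0.02. `run_pvca` itself
defaults to the four clinical factors so the decomposition can also be run
exactly as a four-factor analysis.

Small-cohort caveat: with few centers (one large, several of ~5 patients)
the zero-clamped REML estimate of the batch component is biased upward on
null data; the 5% rule should be read with that in mind. PVCA calibration
against injected batch fractions {0, 0.1, 0.3, 0.5} (mean over 20
replicates within ±0.10) is part of the acceptance suite.

## Differential expression

Fold change is reported as −ΔΔCT = −(mean ΔCT_end − mean ΔCT_onset);
negative values mean downregulation after induction. Mean ΔCTs per
timepoint are computed over all patients with data at that timepoint,
while the t-test is paired over patients with both timepoints — mirroring
published summary tables, whose per-timepoint means are marginal. The test
is paired by default because the sampling is longitudinal per patient; an
unpaired Welch variant is available (`paired=False`) since summary tables
alone cannot distinguish the two. miRNAs with fewer than 3 complete pairs
get a missing p with a warning; an all-zero difference vector yields p = 1.
BH adjustment is step-up with missing p values excluded from the test
count. Significance combines |FC| ≥ 0.58 — inclusive, since log2(1.5) =
0.585 rounds to the conventional printed 0.58 — with adjusted p < 0.05.

## Elastic-net signature

Features are per-patient fold changes (−ΔΔCT per miRNA), not two separate
timepoint vectors: the signature question is about change under therapy.
Features are standardized to zero mean and unit variance (selection is then
invariant to per-assay affine rescaling); constant features are dropped
with a warning. The model is a squared-error elastic net,
penalty λ[α‖w‖₁ + (1−α)/2‖w‖²] with mixing α = 0.7. "Minimum mean squared
error" selection is interpreted as: λ minimizing the leave-one-out
cross-validated squared prediction error over a 100-point log-spaced grid
from λ_max (smallest penalty zeroing all coefficients) down four decades;
exact ties break toward the larger (sparser) penalty. LOOCV with squared
error and a fixed grid is deterministic. Labels are 0/1 group indicators
under squared-error loss, matching the minimum-MSE selection rule; the
procedure is a selection device, not a calibrated classifier.

A known property of minimum-CV-error selection, observed in the planted-
signal experiments here: the chosen λ tends to sit below the support-
recovery optimum, so a handful of noise features often enter alongside a
strongly planted signal. The recovery experiments therefore check that all
planted features are selected, not that nothing else is.

## Chemoresistance index, stratification, survival

Patient-level modulation direction is the sign of −ΔΔCT; exactly zero (a
measure-zero event under continuous noise) counts as no modulation, and no
magnitude threshold is applied by default — a strict mode with
|−ΔΔCT| ≥ 0.58 is available. For drug *d* with *M* listed miRNAs present in
the matrix and *m* concordant with the listed resistance direction, the
chemoresistance index is the add-one (Laplace) estimate (m+1)/(M+2): the
posterior-mean probability of resistance under a uniform prior, bounded
away from 0 and 1 and defined even for tiny lists. Listed miRNAs absent
from the matrix are excluded from both m and M and logged; drugs with no
usable miRNA (e.g. cyclophosphamide, whose list is empty) are excluded from
the matrix — their smoothed value would be the uninformative 1/2.

K-means uses raw CI profiles (already on a common (0,1) scale), k = 2 with
50 restarts at a recorded seed; patients are clustered on their drug
profile. The cluster with higher mean CI on carboplatin/cisplatin/
doxorubicin is labeled cluster 1, "poor-responder-like". Associations with
clinical covariates use pooled two-proportion z-tests on documented
dichotomies (INSS: stage 4 vs other; response: MR vs other; MYCN:
amplified vs other; EFS: event by 36 months vs event-free; "NA" levels
excluded per covariate), with a Fisher exact fallback on degenerate tables.
Survival uses Kaplan–Meier estimates administratively censored at the
36-month horizon and the standard log-rank test (hypergeometric variance).

## Synthetic cohort generator

The generator emulates the CT-level statistical structure of a 52-patient,
two-timepoint, 381-assay cohort: per-assay baselines U(18, 30) (spanning
the reliable window with realistic censoring at 32), Gaussian well noise
(σ = 0.5), per-sample technical offsets (σ = 0.5, what normalization must
remove), center × assay batch shifts (σ = 0.1 by default, producing the
"mild but negligible" few-percent origin WAPV regime), a four-center origin
mix (70/10/10/10), an end-of-induction CT increase of 2 on a random 30% of
assays (global downregulation; a uniform shift on all assays would cancel
under global-mean normalization, so the generator shifts a subset), and
MR/PR/VGPR/NA response frequencies 6:33:8:5.

The planted MR-only signature uses the three designated assays
(miR-29c, let-7b, miR-342-3p) with end-timepoint CT shifts 6.52, 3.31 and
2.83 — median fold-change magnitudes of the poor-responder contrast this
package models. Latent chemoresistance is a per-patient Bernoulli(0.5)
status shared across the three prognostic drugs (carboplatin, cisplatin,
doxorubicin) and applied as ±1 CT end-timepoint shifts signed to match the
curated list; the remaining drugs get independent statuses (prevalence
configurable, `independent_drug_prevalence`). EFS is exponential at
0.008 events/month (≈ 40% events by 3 years, a realistic relapse fraction
for this population), multiplied by a hazard ratio of 3 for latent-resistant
patients, with independent exponential censoring at 0.005/month. The shared
status is what k-means recovery is measured against; making it per-drug
independent everywhere would leave no well-defined two-group truth.

Not emulated: miRNA–miRNA correlation beyond the planted effects, plate
geometry, technical replicates, non-Gaussian well noise, and any exosome
biology (vesicle counts, marker positivity). Passing recovery tests
therefore demonstrates correctness of the statistical machinery on data
satisfying its assumptions, not performance on real cohorts.

## Problem sizes used in validation

Validation experiments are sized for a single CPU: PVCA calibration uses
50-sample × 100-assay matrices with 20 replicates per injected fraction;
signature recovery uses 14 × 81 designs over 50 seeds; latent-resistance
recovery uses full 52-patient cohorts over 50 seeds with EFS base hazard
1/36 per month in that experiment (mean event time equal to the 3-year
horizon, so the horizon is informative for the hazard-ratio power claim);
null calibrations use 200 × (10-patient, 40-assay) cohorts and 1000 z-test
draws.

## Known limitations

- PVCA WAPV on cohorts with few, unbalanced centers is upward-biased for
  small components; verdicts near the 5% line are unstable.
- The minimum-MSE elastic net overselects relative to exact support
  recovery (see above).
- The paired t assumes approximately normal ΔΔCT; the sign-flip
  permutation oracle in the tests quantifies the agreement at n = 15.
- Technical triplicate aggregation (validation-assay workflows) is out of
  scope: readers expect one CT per (sample, assay); aggregate (e.g.
  median) upstream.
- The chemoresistance list is consumed as given; no evidence weighting or
  re-curation is attempted.
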