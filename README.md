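# exopipe

Analysis pipeline for exosomal-miRNA (exo-miRNA) RT-qPCR profiles from
longitudinal liquid biopsies, built for two-timepoint pediatric oncology
cohorts: each patient contributes a plasma sample at disease onset and one at
the end of induction chemotherapy, profiled on a 381-assay TaqMan-style miRNA
array card. The package is aimed at computational biologists who need the
full chain from raw threshold-cycle (CT) tables to survival-stratified
chemoresistance calls, together with a synthetic cohort generator that makes
every stage testable without patient data.

## What it computes

**Preprocessing.** CT values outside the reliable window (CT < 14 or
CT > 32) are treated as experiment failures. Expression is normalized by the
global-mean method: for each sample, the mean CT over detected assays
(CT < 32) is subtracted,

&nbsp;&nbsp;&nbsp;&nbsp;ΔCT<sub>ij</sub> = CT<sub>ij</sub> − mean<sub>j∈detected(i)</sub> CT<sub>ij</sub>,

which removes per-sample technical offsets exactly. Assays detected in fewer
than 80% of samples are dropped; remaining missing wells are imputed at the
assay's lowest expression minus one log2 unit (one ΔCT unit above its highest
observed ΔCT). A coefficient-of-variation diagnostic (on linear relative
quantities, with a Kolmogorov–Smirnov test on the CV distributions) verifies
that normalization removed technical variability.

**Batch assessment.** Principal variance component analysis (PVCA): the
leading principal components (to 60% cumulative variance) are each decomposed
by a random-effects model over the center of origin, age, INSS stage, MYCN
status and their pairwise interactions; the eigenvalue-weighted average
proportion of variance (WAPV) per factor is reported. A batch WAPV below 5%
is classified negligible; otherwise the pipeline halts (it applies no batch
correction) unless explicitly overridden.

**Differential expression.** Per-miRNA paired t-tests of ΔCT(end) vs
ΔCT(onset) across patients, Benjamini–Hochberg adjustment, relative
quantities RQ = 2<sup>−ΔCT</sup>, and fold change FC = −ΔΔCT =
−(ΔCT<sub>end</sub> − ΔCT<sub>onset</sub>) (negative = downregulated after
therapy). Significance requires |FC| ≥ 0.58 (log2 of linear 1.5) and
adjusted p < 0.05.

**Signature selection.** Elastic net (mixing α = 0.7, squared-error loss) on
per-patient fold changes contrasts poor (MR) vs good (VGPR) responders; the
penalty λ is chosen by leave-one-out cross-validated MSE over a 100-point
log-spaced grid, and nonzero coefficients define the signature.

**Chemoresistance index and survival.** For each drug of the induction
regimen, a curated list gives the miRNAs whose up/down modulation promotes
resistance. For patient *i* and drug *d*, with *m* of the *M* listed miRNAs
modulated concordantly (sign of the patient-level −ΔΔCT), the Laplace-
smoothed chemoresistance index is

&nbsp;&nbsp;&nbsp;&nbsp;CI<sub>id</sub> = (m + 1) / (M + 2) ∈ (0, 1).

K-means (k = 2, 50 restarts) on the patient × drug CI matrix stratifies the
cohort; the cluster with higher mean CI on carboplatin/cisplatin/doxorubicin
is labeled poor-responder-like. Clusters are tested for association with
clinical covariates (two-proportion z-tests) and with 3-year event-free
survival (Kaplan–Meier curves, log-rank test).

**Synthetic cohorts.** `simulate_cohort` draws two-timepoint CT matrices with
per-assay baselines, sample offsets, center-specific batch shifts, an
end-of-induction downregulation, MR-only signature effects, latent
chemoresistance driving concordant modulation of the listed miRNAs,
detection censoring at CT 32, and exponential EFS whose hazard depends on the
latent resistance — with the ground truth returned for recovery tests.

## Worked example

```python
import exopipe as xp

cohort = xp.simulate_cohort(xp.SimulationConfig(seed=7))   # 52 patients, 381 assays
clist = xp.load_reference_chemoresistance_list()
result = xp.run_pipeline(cohort.ct, cohort.clinical, clist)

print("batch verdict:", result.batch_verdict,
      f"(WAPV origin = {result.pvca.wapv['origin']:.3f})")
print("significantly downregulated:",
      int((result.significant['direction'] == 'down').sum()))
print("cluster sizes:", result.clusters.labels.value_counts().to_dict())
print(f"3-year EFS log-rank p = {result.survival.logrank_p:.4f}")
```

prints

```
batch verdict: negligible (WAPV origin = 0.019)
significantly downregulated: 113
cluster sizes: {2: 28, 1: 24}
3-year EFS log-rank p = 0.0017
```

The center-of-origin batch contribution (1.9% of variance) is below the 5%
rule, so no correction is needed; 113 assays come out significantly
downregulated after induction (the generator plants downregulation on ~30%
of assays plus the resistance-linked shifts); and the two CI clusters — the
poor-responder-like cluster 1 with 24 patients — differ significantly in
3-year event-free survival, recovering the planted hazard structure.

The same stages are available as a CLI:

```sh
exopipe simulate --seed 7 --out-dir cohort/
exopipe run --ct cohort/ct.tsv --clinical cohort/clinical.tsv \
            --list src/exopipe/data/chemoresistance_list.tsv --out-dir results/
```

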