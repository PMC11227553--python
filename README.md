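# miromics

Integrative analysis of miRNA regulation by copy-number variation (CNV) and
promoter DNA methylation (DNAm), with downstream immune scoring and an
eight-miRNA prognostic risk model.  The package targets tumor cohorts — lower
grade glioma is the motivating setting — where miRNA expression, 450K-array
methylation and SNP-array copy-number segmentation are available for the same
samples, and it ships a synthetic cohort generator so every stage can be run
and validated without any data download.

## What it computes

**miRNA-level omics profiles.**  miRNAs are transcribed from their own
promoters; the promoter of a miRNA is the window from 2000 bp upstream to
500 bp downstream of its (CAGE-derived) TSS, strand-aware.  450K probes
falling in that window are re-annotated to the miRNA and its promoter
methylation is the mean beta-value of those probes.  Copy number is taken
from the segment mean, log2(CN/2), of the segment containing the mature
locus midpoint.  Probe betas are first cleaned: probes missing in more than
30% of samples are dropped, the rest KNN-imputed, and type II probe bias is
corrected by quantile-mapping type II betas onto the type I distribution
within three methylation states fit by a beta-mixture EM.

**Driver screen.**  For each miRNA, Pearson correlations of expression with
copy number (N) and promoter methylation (M) are computed, mapped to the
Fisher Z scale, z = ½·ln((1+r)/(1−r)), for landscape/skewness analysis, and
tested; Benjamini–Hochberg FDR < 0.05 with r > 0 defines CNV-driven miRNAs
(CNV-miRs), FDR < 0.05 with r < 0 defines DNAm-miRs.  A per-miRNA bivariate
regression

    Y ≈ β₀ + βm·M + βn·N

separates the two influences; βm < 0 (FDR < 0.05) marks the core DNAm set,
βn > 0 the core CNV set.  The same screen machinery handles correlations of
miRNA expression with immune-cell infiltration estimates, PD-L1 expression
and TIDE scores.

**Immune activity scores.**  From gene expression: CYT = √(GZMA·PRF1),
MHC = mean of a nine-gene MHC-I panel, CTL = mean of five cytotoxic
T-cell genes; rank-based single-sample gene-set enrichment (ssGSEA) for
arbitrary signatures; and T/I/S factor scores (tumor proliferation,
antitumor immunity, immunosuppression) as means of z-scored signature
enrichment.

**Prognostic risk model.**  A fixed linear score over eight miRNAs
(miR-10b-5p, miR-155-5p, miR-196a-5p, miR-196b-5p, miR-200a-3p, miR-204-5p,
miR-503-5p, miR-15b-5p) with published penalized-Cox coefficients
(0.1617, 0.3419, 0.0695, 0.1391, 0.1474, 0.0840, 0.0996, 0.2083) applied to
normalized expression.  Cohorts are split at the maximally selected log-rank
cutpoint and evaluated with Kaplan–Meier / log-rank statistics and
IPCW-weighted time-dependent ROC AUC.

## Worked example

```python
from miromics import generate_cohort, DriverScreenModel, RiskScoreModel

cohort = generate_cohort(n_samples=200, n_mirnas=300, seed=42)

screen = DriverScreenModel(cohort.expression, cnv=cohort.cnv, meth=cohort.meth).fit()
print(screen.summary())

risk = RiskScoreModel(cohort.expression, cohort.survival).fit(
    horizons=[365, 730, 1095, 1825]
)
print(risk.summary())
```

prints

```
Driver screen summary
==========================================
miRNAs screened        300
FDR threshold          0.05
CNV-miRs (r>0)         45
DNAm-miRs (r<0)        45
both labels            15
core CNV (bn>0)        45
core DNAm (bm<0)       45
Z skewness (cnv )      +1.612 (p=9.63e-18)
Z skewness (dnam)      -1.633 (p=5.21e-18)

Risk-score model summary
==========================================
samples scored        200
normalization         zscore
time unit             days
cutpoint              -0.1683
high / low risk       128 / 72
log-rank chi-square   14.689
log-rank p            0.000127
AUC(t=365)           0.634
AUC(t=730)           0.691
AUC(t=1095)           0.620
AUC(t=1825)           0.693
```

The generator planted 10% CNV-driven, 10% DNAm-driven and 5% jointly driven
miRNAs (45 = 30 + 15 per class including the joint set), all recovered by the
screen; the positive skew of the CNV Fisher-Z landscape and the mirrored
negative skew of the DNAm landscape reflect the planted regulatory signs.
Survival was generated with hazard proportional to exp(risk score), so the
high-risk group shows the expected excess mortality and the AUC(t) sits well
above 0.5 at every horizon.

The same stages are scriptable from the shell:

```bash
miromics simulate --preset small --seed 7 --out cohort/
miromics run-all --config config.yaml --out results/
```

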