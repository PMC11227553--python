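# Methods

This note documents the models and procedures implemented in `miromics`, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic cohorts do and do not establish about real data.

## Coordinates and formats

All genomic coordinates are handled 1-based inclusive, the convention of GFF3
and of the 450K manifest's `MAPINFO` column; BED input is converted from its
0-based half-open starts at read time.  A single inclusive convention
throughout (rather than an internal half-open representation) was chosen to
minimize conversion sites; boundary behaviour is pinned by tests at the
promoter edges and at segment boundaries.  Chromosome names are normalized to
the `chr`-prefixed style on read (`chr_prefix=False` toggles this); mixing
styles between inputs is a hard error rather than a silent empty join.
Matrices are exchanged as features × samples TSV with the feature id in the
first column.

## Promoter model and probe re-annotation

The promoter of a miRNA is `[TSS − 2000, TSS + 500]` on the plus strand and
its mirror on the minus strand, clipped at position 1.  Both window sizes are
parameters (`upstream`, `downstream`).  Probes are assigned to every promoter
containing them — a CpG shared by overlapping promoters contributes to each
miRNA's mean, which follows directly from defining the profile as "the mean of
probes within the promoter".  Positional categories use the strand-aware
upstream distance d: d ∈ (0, 200] → TSS200, d ∈ (200, 2000] → TSS2000;
a probe at or downstream of the TSS is Body when inside the mature locus and
Outside otherwise.  Distance 0 (probe exactly on the TSS) counts as
downstream so no probe can belong to two windows.  Duplicate TSS records for
one miRNA keep the first after sorting by (chrom, position), with a warning.

Copy number is assigned from the segment containing the midpoint of the
mature locus.  Mature miRNAs are ~22 nt, effectively point-like against
segment sizes, so the midpoint rule is deterministic and never fractional;
a locus in a segmentation gap is missing, and overlapping segments within a
sample are an error naming the sample and chromosome.

## Beta-matrix preprocessing

Probes missing in strictly more than 30% of samples (`max_missing_fraction`)
are removed; missingness is measured per probe across samples.  Remaining
holes are imputed by k-nearest-neighbour averaging over probes (k = 10
default), with neighbour distances computed over co-observed samples via
scikit-learn's `KNNImputer`; imputed cells are clipped to [0, 1] and observed
cells pass through bit-for-bit.  Imputation is deterministic.

Type II probes on the 450K array read compressed toward 0.5 relative to
type I.  The correction fits, per sample, a three-state beta mixture
(unmethylated / hemimethylated / methylated) to the type I and the type II
betas by EM with a weighted method-of-moments M-step, assigns each type II
value to its most probable state, and maps it through the state's beta CDF
onto the matching type I state quantile.  Type I values are never touched.
The EM is initialized from hard thresholds at beta 0.2/0.8 for type I, and
the type II fit is initialized from the converged type I parameters — this
anchors state correspondence between the two chemistries and makes the map
converge to the identity when the two distributions coincide.  Convergence is
declared when the mean per-observation log-likelihood moves by less than
1e-4; the cap is 300 iterations because EM on strongly overlapping beta
components approaches its optimum slowly.  A sample whose EM does not
converge falls back to rank-based quantile normalization of type II onto
type I, with a warning and a per-sample method record in the returned
metadata.  Correction refuses matrices that still contain missing cells; the
canonical order is filter → impute → correct.

## Driver screen

Pearson r is computed per miRNA over complete (expression, covariate) pairs;
features with fewer than `min_pairs = 10` pairs or a zero-variance vector are
reported as undetermined with a reason code, never as NaN propagation.
Significance comes from the two-sided t-test of r; the Fisher Z values
(arctanh r) are stored alongside for distributional analyses such as the
skewness of the regulatory landscape (moment estimator g1 by default, the
bias-corrected G1 available, with D'Agostino's transformed-Z p-value).
Benjamini–Hochberg adjustment runs separately within each declared family:
the CNV screen, the DNAm screen, each regression coefficient across miRNAs,
and the full feature × covariate grid of the generic correlation screen —
matching how each result set is interpreted on its own.

The bivariate decomposition fits ordinary least squares per miRNA with
intercept; coefficient t-tests use the exact residual degrees of freedom, and
collinear or constant inputs are undetermined.  Labels: CNV-miR (r > 0,
FDR < 0.05), DNAm-miR (r < 0, FDR < 0.05), core CNV (βn > 0, FDR < 0.05),
core DNAm (βm < 0, FDR < 0.05); the correlation labels may co-occur.

## Immune scores

CYT, MHC and CTL expect linear-scale non-negative expression (e.g. FPKM) and
refuse negative input rather than silently exponentiating a log matrix; all
three are scale-equivariant and independent of non-panel genes.  ssGSEA
ranks genes per sample (rank 1 = lowest; ties broken by gene identifier
through a stable sort), walks them in descending order, and accumulates the
difference between the weighted in-set ECDF (weights rankᵅ, α = 0.25
default) and the out-of-set ECDF; with normalization the whole score matrix
is divided by its max − min.  Both α and the normalization are configurable.
This same operation serves hallmark-style signature scoring; it is a
rank-statistic approximation, not the kernel-density GSVA estimator.  T/I/S
factor scores z-score each signature row across samples (zero-variance rows
excluded with a warning) and average within factor, so every factor score has
cohort mean zero by construction.  The nine factor gene sets shipped by the
generator are synthetic placeholders keyed to the factor allocation; real
analyses should supply their own GMT.

## Risk model

The eight-miRNA panel and its coefficients are fixed inputs, not estimates —
re-fitting the penalized Cox model is deliberately out of scope.  "Normalized
expression" defaults to per-miRNA z-scores across the scoring cohort;
min–max and identity schemes are available, and the scheme is part of the
model because scores do not transfer across schemes.  When validating on an
external cohort the model is re-applied with within-cohort normalization;
both modes are expressible by constructing the model on the cohort in
question.  The cutpoint maximizes the two-group log-rank statistic over all
thresholds leaving at least 10% of samples (`min_group_fraction`) on each
side, ties breaking to the lowest threshold; the scan uses a vectorized
log-rank statistic verified against lifelines to 1e-9 and against an
exhaustive per-split oracle in tests.  Kaplan–Meier curves and the two-group
log-rank test come from lifelines; time-dependent AUC is the
cumulative-cases / dynamic-controls estimator with Kaplan–Meier IPCW weights
from scikit-survival, with horizons outside the evaluable follow-up reported
as missing.  Time units are declared (`days` default) and echoed in outputs.

## Synthetic cohorts

The generator plants every structural feature the pipeline assumes: a toy
genome (5 chromosomes × 10 Mb) with uniformly placed TSS and 1 + Poisson(4)
probes per promoter in known positional zones plus a 3× background; design
types ~30/70 I/II; per-sample segment tracks with Normal(0, 0.3) segment
means; a bimodal, unmethylated-heavy logit-normal promoter methylation
landscape (as promoter CpG sets are in practice) with probe noise
(sd 0.05) and a known logistic compression of type II betas toward 0.5
(logit shrinkage, γ = 1.8), giving the bias correction a checkable target;
expression coupled positively to copy number and negatively to methylation
with effect sizes parameterized as target Pearson correlations (defaults:
10% CNV-driven, 10% DNAm-driven, 5% both, |r| = 0.5), so recovery tests are
invariant to noise scaling, with an explicit feasibility bound for joint
targets; marker genes log-linearly coupled to latent immune-cell
infiltration; an evasion score coupled to the immunosuppression latent and
weakly to one panel miRNA; and exponential survival with hazard proportional
to exp(log-HR × risk score) (log-HR = 1 per score unit, baseline set for a
~2-year median) under independent uniform censoring calibrated to ~30%.
Missing beta cells are injected at 2% plus a 2% subset of high-missingness
probes so the missingness filter has work to do.  Everything derives from a
single seed through spawned generators; identical seeds give identical
cohorts.

What passing tests show — and what they do not: the synthetic cohorts have
Gaussian noise, linear couplings, independent samples, exponential survival
and no batch structure, cell-type admixture, copy-number/methylation
interaction or annotation error.  Recovery and calibration results therefore
validate the statistical machinery and its conventions, not robustness to
the full messiness of tumor cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced scale chosen to make the
checked properties statistically unambiguous: 400 samples × 1000 miRNAs for
driver recovery, 20 replicate null cohorts (300 × 200) for calibration,
n = 500 for null AUC, cohorts of 30–300 miRNAs elsewhere.  Oracle
equivalences are exact: interval mapping against a quadratic containment
scan, ssGSEA against a literal running-sum recomputation (1e-9), BH against
the direct step-up formula (1e-12), the cutpoint against an exhaustive split
scan, and the log-rank statistic against a hand-tabulated risk table.  Beta
values are clipped to [1e-6, 1 − 1e-6] before beta-likelihood evaluation;
correlation ties at |r| = 1 are flagged collinear with p = 0 rather than fed
to the t-distribution.

## Known limitations

The BMIQ-style correction is a state-wise quantile map, simpler than the
original's mixed CDF/scaling treatment of the hemimethylated state; its
fallback is a plain rank quantile map.  ssGSEA stands in for GSVA where a
kernel-density estimator would otherwise be used.  The KNN imputer's
nan-aware Euclidean distance rescales by the fraction of co-observed
dimensions, which can reorder neighbours relative to a plain co-observed
distance when candidate probes are themselves missing in many samples.
LASSO-Cox fitting, consensus clustering, deconvolution (TIMER/ESTIMATE/TIDE)
and target-network assembly are out of scope; their outputs are consumed as
plain input matrices.
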