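# Methods

This note documents the models and procedures implemented in `mmlce`, the
assumptions behind them, and the choices made where the design was open.

## Setting

Light-chain escape (LCE) is a relapse pattern in multiple myeloma in which
serum free light chain rises without a matching intact monoclonal protein
(M-spike) rise. At the single-cell level this corresponds to a tumor
subpopulation that has lost immunoglobulin heavy-chain (IGH) constant-region
expression and secretes light chain only. The package implements the full
analysis arc around this phenomenon: splitting myeloma cells into
IGH-expressing vs light-chain-only subpopulations from scRNA-seq, deriving a
subpopulation gene signature, inferring chromosome-level copy-number
subclones from expression and tracking them across serial samples, scoring
bulk cohorts with the signature and associating it with osteolysis and
survival, and classifying LCE from serial clinical labs.

## Single-cell pipeline

**QC.** Cells with fewer than 250 detected genes or with a mitochondrial
read fraction above 10% are removed. The inequalities are strict removals:
a cell at exactly 250 genes and exactly 10% mitochondrial reads is
retained. The filter is idempotent.

**Normalization.** `value = ln(1 + count/total x scale_factor)` per cell,
with `scale_factor = 10,000` (the ecosystem convention; configurable).
Zeros map to zeros, so sparsity is preserved.

**Variable genes.** A Michaelis–Menten dropout model: the global curve
`d = 1 − S/(K + S)` is fit by least squares to per-gene (mean CP10k `S_j`,
dropout rate `d_j`); each gene's own `K_j = S_j d_j/(1 − d_j)` is tested
one-sided against the global `K` using a delta-method standard error on
`d_j` (`var = d_j(1 − d_j)/n`), with Benjamini–Hochberg adjustment at
FDR 0.05. Genes detected in every cell have `K_j = 0` and are never
selected. An `exclude_ig` option drops immunoglobulin genes from the
selection, reproducing the robustness check that the two myeloma
subpopulations are not an Ig-expression artifact.

**Cell typing.** Marker-rule assignment: per-cell score = mean normalized
expression of a label's canonical markers (T: CD3D/CD3E, B: MS4A1, NK:
NKG7, RBC: HBB/HBA1, megakaryocyte: PPBP, monocyte: CD14, myeloma:
CD38/SDC1/IGKC, progenitor: CD34); the argmax label is assigned when it
reaches `tau_type = 0.5`, else the cell is unassigned. A myeloma call
additionally requires unambiguous light-chain restriction: kappa is called
when mean kappa-gene expression is at least `rho = 5` times the lambda
score and at least `tau_lc = 0.5` (symmetrically for lambda). Thresholds
were chosen so that noiseless synthetic data classifies perfectly; all are
configurable.

**Myeloma split.** The IGH score is the mean normalized expression over
the nine IGH constant-region genes (IGHM, IGHD, IGHG1–4, IGHA1–2, IGHE);
cells at or above `tau_igh = 0.25` are IGH-MM, the rest LCE-MM. A cell
with zero across all constant genes is necessarily LCE-MM.

**Differential expression.** Per gene detected in ≥10% of either group, a
single-covariate logistic regression of group membership on normalized
expression, tested by likelihood ratio against the intercept-only model
(χ², 1 df). The Newton solver uses step halving; its p-values were checked
against `statsmodels.Logit` (test suite) and its null distribution is
uniform into the far tail (empirically to P < 5·10⁻⁵). Non-convergence or
quasi-separation (|slope| > 50) falls back to the rank-sum test and is
flagged. Fold change is `l2FC = log2[(mean(expm1 x)_1 + 1)/(mean(expm1 x)_2 + 1)]`
— de-logged group means with pseudocount 1, matching the convention of the
standard single-cell toolchain. Bonferroni adjustment defaults to the full
gene universe (all genes in the matrix); adjusting over tested genes only
is available. DE is antisymmetric under group exchange.

**Signatures and enrichment.** A signature keeps genes with
`|l2FC| > 1` (fold change > 2) and adjusted p < 0.05; the LCE signature
uses the up-only variant (`l2FC > 1`), the default. Pathway enrichment is
the upper-tail hypergeometric test with Haldane-corrected odds ratios and
BH adjustment across pathways; it agrees exactly with a subset-enumeration
oracle for all universes ≤ 12. Per-cell signature scores are mean
up-gene expression minus mean down-gene expression, compared between
groups by rank-sum.

## CNV inference and subclone tracking

Per gene, the signal is the normalized value minus its mean over a
reference set of normal cells (default: all non-myeloma types from the
same run). Genes are ordered by chromosome and start coordinate and
averaged over a 101-gene moving window within each chromosome (shrinking
at edges); profiles are median-centered per cell and clipped to ±1.
Chromosomes with fewer than 5 genes are excluded, as are the MT
"chromosome" and immunoglobulin genes — clonotype-driven Ig expression
(a quarter of the library in intact-Ig myeloma) reflects secretory state,
not dosage, and otherwise masquerades as focal CNV.

Chromosome-level calls use the mean window signal with thresholds ±0.1
(gain/loss), mirroring the cited tool's common defaults. Whole-chromosome
rather than arm-level calls are the default because the events of interest
here are whole-chromosome gains/losses; an arm column in the annotation
enables arm-level mode in principle.

Subclones are found by hierarchical clustering (average linkage,
Euclidean) of per-cell chromosome-mean profiles. k is chosen by maximum
mean silhouette over 2..10 (ties toward smaller k), falling back to k = 1
when the best silhouette is below 0.1. During the automatic search,
clusterings containing a cluster of fewer than 5 cells are skipped:
average linkage splits off noise singletons whose silhouette can be
deceptively high, and a two-cell "subclone" is not interpretable. The
reported k and silhouette are diagnostics, not assertions about a true
clone count.

Tracking matches subclone signatures across consecutive timepoints
greedily by Pearson correlation (larger subclones first, each target used
once, matches below r = 0.8 rejected); unmatched earlier subclones are
extinct, unmatched later ones emergent. Proportions per timepoint sum to 1
by construction.

## Cohort scoring, LCE labs classification, outcomes

**Gene-set score.** Per signature gene present in the cohort, a
cross-sample z-score with the sample (n−1) standard deviation; the score
is the sum over up-genes minus the sum over down-genes. Genes absent from
the cohort are skipped and logged; zero-variance genes contribute 0. The
score is invariant to affine rescaling of any gene. Strata cut at the
score mean ± 1 SD with strict inequalities (scores exactly at a cut are
mid), and mid samples are excluded from high-vs-low comparisons.

**LCE classification.** Three criteria on a patient's serial labs
(M-spike in g/dL, free light chains in mg/dL; the involved isotype is
given or inferred as the larger diagnosis value, ties are an error):
(i) some visit has dFLC = involved − uninvolved > 10 mg/dL with
M-spike < 1 g/dL; (ii) diagnosis M-spike > 1 g/dL; (iii) exclusion when
light-chain rises correspond to M-spike rises. Criterion (iii) is
operationalized as: over consecutive-visit pairs, every dFLC increase
greater than 5 mg/dL (half the dFLC threshold) is accompanied by an
M-spike increase greater than 0.1 g/dL AND the Pearson correlation of
visit-to-visit changes exceeds 0.7. Both components are configurable; the
conjunction makes the exclusion conservative, which protects sensitivity.

**Outcomes.** Survival comparisons are two-group Cox proportional-hazards
fits (group indicator as sole covariate, Efron ties, 95% Wald CIs) plus
Kaplan–Meier medians and the log-rank test; "low" (or a falsy label) is
always the reference group. A group with zero events yields an explicit
non-estimable result rather than an exception. Osteolysis uses Fisher's
exact test on the high/low × (≥3 vs <3 lesions) table and Welch's t-test
on continuous lesion counts.

## Synthetic data

The generators define the conditions under which the pipeline is tested.

**scRNA-seq.** Counts are negative binomial with `var = μ + φμ²` and a
single global dispersion φ = 0.1 (the field-standard UMI count model; the
underlying study publishes no count model). Per-cell mean:
baseline (log-normal across genes, named marker genes pinned to a
detectable level) × population program (markers ×25 in their own
population, suppressed elsewhere; IGH constant genes ×40 in IGH-MM and
~0 in LCE-MM; LAMP5 ×4 and MYC ×4 in LCE-MM vs ×2 in IGH-MM; IGKC high
and lambda genes silent in both myeloma populations) × CNV dosage
(×1.5 per gained chromosome copy, ×0.5 for loss, multiplicative on every
gene of the chromosome — what expression-based inference can detect) ×
library factor (log-normal, median ≈ 3,000 UMIs). Mitochondrial genes'
means are rescaled per cell so their expected library share equals a
Beta-distributed fraction (mean 3.5%, sd 1%), letting the QC filter be
exercised. Genes are laid out in contiguous blocks over 22 autosomes plus
MT; serial timepoints share the gene universe through a separate gene
seed. CNV events can share a carrier group, jointly defining a subclone.
Doublets are not simulated by default (an optional flag mixes random cell
pairs for robustness testing only). Not emulated: batch effects, ambient
RNA, empirical distributions of any real accession — passing tests show
the pipeline recovers planted structure under its stated noise model, not
that it is robust to artifacts absent from that model.

**Serial labs.** Noiseless template trajectories for three disease
patterns — concordant (M-spike and light chain rise together at relapse),
LCE-at-relapse (diagnosis M-spike 2.5 g/dL, suppressed below 1 g/dL after
treatment while dFLC climbs to >100 mg/dL), and light-chain-only
(diagnosis M-spike below 1 g/dL) — plus Gaussian measurement noise
(0.05 g/dL M-spike, 2 mg/dL light chain, truncated at zero) on an
eight-visit 90-day schedule. The LCE fraction defaults to 0.3 of
patients; the truth label marks only the LCE-at-relapse pattern.

**Bulk cohort.** log2 expression = gene base level (N(5, 2)) + a shared
per-sample effect (N(0, 0.5); library/technical variation, which keeps
summed z-scores continuous across samples as in real cohorts) +
independent noise (N(0, 1)) + δ = 1.5 on 50 signature genes for the
latent-high group (prevalence 0.25); values are exponentiated to a
TPM-like scale. Survival is exponential under proportional hazards with
administrative censoring — OS baseline hazard 0.10/year censored at
8 years with true HR 2.73, time-to-diffuse-lytic-lesions baseline
1/2000 per day censored at 2500 days with true HR 2.99 (the hazard ratios
the signature-high group shows in the clinical datasets). Lesion
categories {0, 1, 2, 3+} are multinomial per latent group (64% of
latent-high vs 37% of latent-low at 3+); continuous lesion counts are
Poisson (means 4.5 vs 1.5).

## Problem sizes and numerical choices

The test suite and the reproduction script run everything at desk scale:
2,000 cells for the QC exactness check; the published group sizes 4,370
vs 281 cells over a 1,000-gene universe for DE recovery (20 replicates);
3,000 genes and ~1,300 cells per timepoint over three timepoints for CNV
inference (more genes per chromosome than the default 1,200 because
window-averaged noise scales as 1/√genes); cohorts of 400–600 samples and
100 replicate cohorts for CI coverage. DE recovery uses balanced planting
(each effect planted up in one sample with a twin planted up in the
other) so that the two samples carry identical planted library mass —
otherwise per-cell normalization shifts every background gene slightly
and the null is not a null.

Ties and degenerate inputs: scores exactly at a stratification cut are
mid; tied diagnosis light chains without a declared isotype are an error;
zero-variance score distributions stratify everything as mid with a
warning; a constant expression matrix yields an all-zero CNV matrix; Cox
fits with an event-free group report non-estimable.

## Known limitations

- Expression-inferred CNV sees dosage only through transcription;
  strong cell-identity expression programs can leave residual signal on
  the chromosomes that host marker genes. Ig genes are excluded for this
  reason; other programs are diluted by window size and gene count.
- The logistic-regression DE treats cells as independent replicates, as
  the original toolchain does; with serial samples from one patient this
  is a descriptive, within-patient comparison, not a population inference.
- The LCE criterion (iii) concordance rule is one reasonable
  operationalization of "light chain increases corresponded to M-spike
  increases"; the underlying study publishes no formula.
- Subclone counts depend on clustering parameters; the package reports k
  and silhouette rather than asserting a particular count.
- No graph clustering/UMAP mathematics, no doublet detection, no
  HMM-based CNV segmentation, no allele-level validation.
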