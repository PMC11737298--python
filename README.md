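# mmlce

Single-cell and cohort analysis of **light-chain-escape (LCE) multiple
myeloma**: splitting myeloma cells into intact-immunoglobulin (IGH-MM) vs
light-chain-only (LCE-MM) subpopulations from scRNA-seq, deriving
subpopulation gene signatures, inferring chromosome-level copy-number
subclones from expression and tracking them across serial samples, scoring
bulk cohorts with a summed z-score gene-set statistic, classifying LCE from
serial clinical labs, and associating signature/LCE status with osteolytic
bone disease and survival.

It is written for computational biologists studying intrapatient myeloma
heterogeneity who want the full analysis arc — from a 10x-style
feature-barcode matrix or a clinical labs CSV to hazard ratios — as a
tested, reusable Python library, exercisable end to end on synthetic data
with the statistical structure the analysis assumes.

## The core statistics

* **Subpopulation split.** After QC (cells with <250 detected genes or >10%
  mitochondrial reads removed) and ln CP10k normalization, myeloma cells
  (CD38/CD138/IGKC marker rule plus light-chain restriction) are split by
  mean IGH constant-region expression: LCE-MM cells have no detectable IGH
  yet restricted light-chain expression.
* **Differential expression.** Per gene, logistic regression of group
  membership on normalized expression, likelihood-ratio χ²(1) p-values,
  Bonferroni adjustment over the gene universe;
  `l2FC = log2[(⟨expm1 x⟩₁+1)/(⟨expm1 x⟩₂+1)]`. Signatures keep
  `|l2FC| > 1` and adjusted p < 0.05 (up-only for the LCE set).
* **CNV subclones.** Reference-subtracted expression smoothed over a
  101-gene genomic window, chromosome-level gain/loss calls at ±0.1,
  hierarchical subclone clustering with silhouette-selected k, greedy
  signature matching across timepoints.
* **Gene-set score.** `score(s) = Σ_g z_g(s)` over signature genes
  (cross-sample z-scores, down-genes negated); samples with score
  > mean+1·SD are high, < mean−1·SD low. Strata are compared by Cox
  proportional hazards (OS and time-to-diffuse-lytic-lesions), log-rank,
  Fisher exact and Welch t tests.
* **LCE labs classifier.** LCE ⇔ (i) some visit has involved-minus-uninvolved
  free light chain > 10 mg/dL with M-spike < 1 g/dL, (ii) diagnosis M-spike
  > 1 g/dL, and (iii) light-chain rises do *not* track M-spike rises.

See `docs/methods.md` for the full model descriptions, parameter defaults
and limitations.

## Worked example

`examples/cohort_scoring_survival.py` simulates a 400-sample bulk cohort in
which a latent 25% of samples over-express a 50-gene signature (log2 shift
1.5) and carry higher lesion burden and mortality, then recovers that
structure:

```
strata (score > mean+1SD high, < mean-1SD low): {'mid': 327, 'high': 58, 'low': 15}
latent group recovered among called samples: accuracy 1.00
OS, high vs low stratum: HR 2.96 [1.34, 6.57], log-rank p 0.0051, median OS high 3.1 vs low >8 years
time to diffuse lytic lesions: HR 3.21 [1.63, 6.31]
high/low x lesion-burden table (rows high, low; cols >=3, <3):
      >=3  <3
high   39  19
low     9   6
Fisher exact p = 0.761; Welch t on lesion counts p = 9.33e-10 (means 4.0 vs 1.0)
```

The summed z-score separates the latent group perfectly among called
samples; the signature-high stratum dies sooner (hazard ratio 2.96, the
planted truth is 2.73) and develops diffuse lytic lesions faster (HR 3.21
vs planted 2.99). The other examples cover the single-cell subpopulation
split and signature derivation (`single_cell_subpopulations.py` — LAMP5
comes out as the top LCE-MM gene, IGH constant genes as the top IGH-MM
genes), CNV subclone tracking across three timepoints
(`cnv_subclone_tracking.py` — a planted chr19+chr22-gain subclone expanding
0.31 → 0.54 → 0.69 is called within ~0.02 of truth), and the serial-labs
classifier (`lce_lab_classification.py`).

## Command line

A thin CLI mirrors the library:

```bash
mmlce --out-dir sim --seed 1 simulate --kind sc
mmlce --out-dir out sc-qc --counts sim/counts --annotation sim/annotation.tsv
mmlce --out-dir out de --counts sim/counts --annotation sim/annotation.tsv
mmlce --out-dir out lce --labs labs.csv
```

Subcommands: `simulate`, `sc-qc`, `de`, `enrich`, `cnv`, `score`, `lce`,
`survival`, `all`; each writes TSV outputs plus a JSON run summary. Global
flags: `--config` (YAML, see `mmlce.config.PipelineConfig`), `--seed`,
`--out-dir`, `--log-level`.

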