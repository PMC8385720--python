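# methylomix

Joint DNA-methylation + transcriptome analysis for checkpoint-negative tumor
cohorts, built for studies of hepatocellular carcinoma samples whose PD-1
(*PDCD1*) expression falls below the normal-tissue average — the samples most
likely to resist checkpoint blockade. The package turns that analysis into a
tested, configurable pipeline that runs end-to-end on a bundled synthetic
cohort generator, so every stage can be exercised and validated at desk scale
without any data download.

## What it computes

Given a gene × sample expression matrix, a 450K-style probe × sample β-value
matrix with a probe → (gene, region, chromosome) manifest, clinical follow-up,
gene-set collections (GMT), a PPI edge list and a drug → target table:

1. **Stratification** — tumor samples with checkpoint expression strictly
   below the arithmetic mean of normals are called checkpoint-negative.
2. **Immune infiltration** — ssGSEA scores per sample for stromal and immune
   signatures; the ESTIMATE score is their sum. Groups are compared with a
   two-sided Wilcoxon rank-sum test.
3. **Differential expression / methylation** — an empirical-Bayes moderated
   t-statistic with a method-of-moments variance prior and BH-FDR. DEGs:
   FDR < 0.01 and |log2FC| > 1. β-values are averaged per gene-region
   (TSS200, TSS1500, gene body, …); DMGs: FDR < 0.05 and |Δβ| > 0.3.
4. **DMEG integration** — genes called in both tables, classified by sign:
   HypoUp (Δβ < −0.3, log2FC > 1), HypoDown, HyperUp, HyperDown; chromosome
   summaries; separability checks by PCA and two-class LDA with leave-one-out
   ROC/AUC.
5. **Enrichment** — hypergeometric over-representation of any gene list
   against GMT collections, BH-corrected.
6. **Drug proximity** — over a PPI graph (STRING-style confidence ≥ 600),

       d(S, T) = (1/|T|) · Σ_{t∈T} [ min_{s∈S} d(s, t) + ω(t) ],
       ω(t) = −ln(D_t + 1) if t ∈ S else 0,

   with S the disease (DMEG) genes, T a drug's targets, d(s, t) the
   shortest-path hop count and D_t the degree of t. Drugs with d(S, T) < 0.8
   are screened as candidates; random-gene-set null densities support the
   threshold.
7. **Prognostic signature** — the checkpoint-negative cohort is split into
   train/validation halves; 1000 × 10-fold cross-validated LASSO-Cox runs
   (re-randomising fold assignment) count how often each gene combination is
   selected per 100 repetitions; the modal combination defines a linear risk
   score `Σ coef_g · expr_g`, evaluated by Kaplan–Meier curves, the log-rank
   test and IPCW time-dependent ROC at 1/3/5-year horizons, alongside
   per-gene univariate Cox fits (Breslow ties, Newton iteration).

## Worked example

A synthetic cohort with 31 planted DMEGs (hypomethylated in TSS200, up-
regulated 2-fold), three of which carry proportional-hazards coefficients
(−0.9, +0.7, −0.8 per log2-expression unit):

```python
from methylomix import (
    CohortSpec, generate_cohort, pd1_negative_samples, moderated_t, call_degs,
    aggregate_region_beta, call_dmgs, intersect_dmegs, lasso_stability,
    fit_risk_model, risk_score, dichotomize, logrank, td_roc_auc, split_cohort,
)

spec = CohortSpec(
    n_normal=50, n_tumor=177, n_genes=300,
    planted_dmeg=tuple((f"G{i:04d}", "TSS200", -0.4, 2.0) for i in range(1, 32)),
    prognostic_genes=(("G0001", -0.9), ("G0002", 0.7), ("G0003", -0.8)),
    seed=3,
)
cohort = generate_cohort(spec)
expr = cohort.expression

negatives = pd1_negative_samples(expr, "PDCD1")
stats = moderated_t(expr.values, expr.samples_in_group("normal"), negatives)
deg = call_degs(stats, fdr_max=0.01, lfc_min=1.0)
beta = aggregate_region_beta(cohort.methylation, "TSS200")
dmg = call_dmgs(beta, expr.group_labels, "TSS200")
records = intersect_dmegs(deg, {"TSS200": dmg})

genes = sorted(records["gene"].unique())
train, val = split_cohort(cohort.clinical.samples, seed=7)
feats = expr.values.loc[genes]
stab = lasso_stability(feats[train], cohort.clinical.subset(train),
                       n_reps=100, k_folds=10, seed=7)
model = fit_risk_model(list(stab.top_combination), feats[train],
                       cohort.clinical.subset(train), seed=7)
```

prints, through the obvious `print` calls:

```
checkpoint-negative tumors: 40 / 177
DEGs (FDR<0.01, |log2FC|>1): 111
TSS200 DMGs (FDR<0.05, |dbeta|>0.3): 31
DMEG records: 31, modes: {'HypoUp': 31}
top LASSO combination (97/100): G0001+G0002+G0003
risk model: -0.409*G0001 +0.193*G0002 -0.302*G0003
validation log-rank: chi2=31.56, p=1.93e-08 (44 high / 45 low)
validation td-AUC at 365 d: 0.871
validation td-AUC at 1095 d: 0.873
```

The three planted prognostic genes are the modal LASSO combination in 97 of
100 repetitions; their penalized coefficients keep the planted signs
(shrunken toward zero, as expected of L1 estimates); risk-score
dichotomisation at z = 0 separates validation survival decisively.

The same run is available from the shell: `methylomix synth`, `stratify`,
`immune-score`, `deg`, `dmg`, `dmeg`, `ora`, `proximity`, `prognosis`,
`evaluate`, and `methylomix pipeline run --config config.yaml` for the whole
sequence with a hashed, bit-reproducible artifact manifest.

## Layout

- `src/methylomix/io.py` — containers + TSV/GMT readers and writers
- `src/methylomix/synthetic.py` — seeded cohort generator with planted truth
- `src/methylomix/immune.py` — stratification, ssGSEA / ESTIMATE scoring
- `src/methylomix/differential.py` — moderated t, BH-FDR, DEG/DMG calling
- `src/methylomix/dmeg.py` — DMEG classification, PCA/LDA separability
- `src/methylomix/enrichment.py` — hypergeometric ORA
- `src/methylomix/proximity.py` — weighted network proximity + screening
- `src/methylomix/prognosis.py` — Cox, LASSO stability selection, risk scores
- `src/methylomix/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
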