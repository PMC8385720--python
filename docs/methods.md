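# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of the package. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Cohort stratification

A tumor sample is checkpoint-negative when its checkpoint-gene expression is
*strictly* below the arithmetic mean of the normal samples. "Below the
average" leaves boundary ties ambiguous; the strict rule excludes them, and
the boundary behaviour is pinned by tests. The checkpoint gene is whatever
expression row the user names (default `PDCD1`); no probe-to-protein mapping
is attempted.

## Immune scoring (ssGSEA / ESTIMATE)

For one sample, genes are ranked by expression with average ranks on ties,
ties then ordered stably by input position so scores are deterministic.
Walking the ranking from highest to lowest expression, the score is the sum
over positions of the weighted in-set empirical CDF minus the unweighted
out-of-set ECDF, with in-set weights `rank^alpha`. The exponent defaults to
`alpha = 0.25`, the published ESTIMATE choice; `alpha = 0` weights all
in-set genes equally. Because only ranks enter, scores are invariant to any
strictly monotone transform of one sample's values — a property test. The
ESTIMATE score is defined as stromal + immune, enforced exactly by the
`ImmuneScores` container. Signature lists are user-supplied GMT files; the
package ships only the synthetic signatures of the generator, not any
proprietary list. Group comparisons use the two-sided Wilcoxon rank-sum test
(exact null when the pooled sample is tie-free and groups are small, normal
approximation otherwise); Welch's t is available by option.

## Moderated differential testing

Per feature, a two-sample comparison with effect `mean(B) − mean(A)` and a
pooled variance shrunk toward an ensemble prior: the prior `(d0, s0²)` is
estimated from the per-feature pooled variances by the method of moments on
log variances (matching the mean and variance of Fisher's log-chi-square
representation; the trigamma equation is inverted by Newton iteration). The
posterior variance is the convex combination
`s²_post = (d0·s0² + d·s²)/(d0 + d)` and the statistic is referred to a t
distribution with `d0 + d` degrees of freedom (normal when `d0 = ∞`, which
the moment estimator returns when the observed log-variance spread is no
larger than its sampling noise). A single feature, or `moderate=False`,
falls back to the ordinary pooled t. This moment-based prior is a
deliberate, documented approximation to the Fisher-scoring refinement some
empirical-Bayes implementations add; at desk scale the difference is well
below the calling thresholds.

Features missing in more than half of either group, or with fewer than two
observed values per group, are dropped with a logged count; remaining
missing values are handled pairwise by nan-aware moments.

Methylation is tested on β-values directly, after averaging probes per
(gene, region); an M-value transform is not applied by default because the
calling threshold (|Δβ| > 0.3) is stated on the β scale. Thresholds: DEGs at
FDR < 0.01 and |log2FC| > 1 (up/down by sign); DMGs at FDR < 0.05 and
|Δβ| > 0.3 (hyper/hypo by sign). Benjamini–Hochberg adjustment is delegated
to statsmodels and checked against a brute-force step-up implementation in
the tests. The linear-scale log2 transform uses pseudocount 1.

## DMEG classification

A (gene, region) pair called in both tables is classified by quadrant:
HypoUp (Δβ < −0.3 ∧ log2FC > 1), HypoDown (Δβ < −0.3 ∧ log2FC < −1),
HyperUp, HyperDown; anything inside the dead zone is `unclassified`, a
defined value rather than an error. The gene-level DMEG set is the union
over regions, deduplicated; both the per-region records and the deduplicated
set are exposed so either count can be produced. Separability checks use
centered PCA (component signs fixed by the largest-absolute-loading-positive
convention) and two-class LDA with leave-one-out cross-validation. The LDA
pooled covariance is shrunk toward its diagonal (`shrinkage = 0.1` by
default) because leave-one-out with p ≈ n makes the raw pooled covariance
singular. AUC uses the rank (Mann–Whitney) formulation with ties counting
one half, verified against the all-pairs estimator.

## Enrichment

Over-representation only: the hypergeometric upper tail P(X ≥ k) for the
overlap between the deduplicated query and each set, both intersected with a
finite universe, BH-corrected across all tested sets. The default universe
is the expression matrix's gene list — the natural background when the query
derives from that matrix — and is configurable. Depletion and ranked-list
(GSEA-style) testing are out of scope.

## Drug–disease network proximity

`d(S,T) = (1/|T|) Σ_{t∈T} [min_{s∈S} d(s,t) + ω(t)]` over an unweighted
simple graph; the 1/|T| normalisation is what makes scores comparable across
drugs with different target counts. Distances are BFS hop counts (the
STRING-style confidence threshold, default 600, gates which edges exist; it
never weights them). `ω(t) = −ln(degree(t) + 1)` when t belongs to the
disease set, else 0; the weighted gene is the target being scored, which —
since the weight only applies to disease-set members — coincides with its
own nearest disease gene at distance zero. Disease genes or targets absent
from the graph are dropped with a log message; a drug with no in-graph
target receives an undefined (NaN) score rather than infinity, and a drug
whose targets are all unreachable scores infinity. Screening keeps drugs
with proximity strictly below the threshold (default 0.8), sorted ascending.
Null densities draw pseudo-disease sets uniformly over graph nodes;
degree-matched sampling is available by flag since uniform sampling
over-represents low-degree nodes relative to a hub-heavy disease set.

## Survival arm

Unpenalized Cox fits maximise the Breslow partial likelihood by Newton
iteration with step halving (tolerance 1e-8, at most 50 steps). Breslow ties
were chosen as the simplest exact-gradient convention, and the analytic
gradient at the returned coefficient is checked (≤ 1e-6) in the tests.
Diverging coefficients (|β·sd(x)| > 20) flag monotone likelihood — perfect
risk separation — instead of failing; singular information and
non-convergence are flagged likewise. Wald CIs are `exp(β ± 1.96·se)`.

Penalized path fits use the coordinate-descent elastic-net Cox solver of
scikit-survival with pure L1 penalty on internally standardized features;
coefficients are reported on the original expression scale. Cross-validation
scores each λ by the Verweij–Van Houwelingen deviance
`−2·[pl_full(β_k) − pl_train(β_k)]`, which remains defined when a held-out
fold carries few events (a test-fold-only partial likelihood does not).

Stability selection fixes the data — and hence the full-sample
regularisation path — and re-randomises only the 10-fold assignment across
repetitions (1000 by default), recording the nonzero-coefficient gene set at
the chosen λ each time; combination and per-gene frequencies are normalised
per 100 repetitions. The default λ rule is the **1-SE rule** (sparsest λ
whose mean CV deviance lies within one fold-wise standard error of the
minimum). The deviance-minimising λ is available as `lambda_rule="min"`, but
it is deliberately not the default for selection: on a fixed path the
minimiser systematically lands beyond the window where only the true
predictors are active, so the modal combination under `min` absorbs noise
genes and can never be a sparse set — whereas the 1-SE rule recovers the
exact planted trio as the modal combination (97/100 repetitions in the
worked example). The final risk model takes the L1 coefficients at the
CV-chosen λ refitted on the training samples restricted to the selected
genes (`mode="penalized"`, the default, matching the shrunken magnitudes a
penalized analysis reports) or an unpenalized Newton refit (`mode="refit"`,
used when unbiased coefficient magnitudes are wanted, e.g. in the
parameter-recovery tests).

Risk scores are the linear form `Σ coef_g · expr_g`. Dichotomisation:
`median` sends scores ≥ median to "high" (ties high); `zscore` sends z > 0
to "high" — zero is the only canonical cutoff on the z scale. Degenerate
all-equal scores yield a single group with a logged warning. Kaplan–Meier
estimation and the two-group log-rank test are delegated to lifelines.
Time-dependent discrimination uses the IPCW cumulative/dynamic AUC at a
horizon (scikit-survival), with censoring weights from the Kaplan–Meier
estimate of the censoring distribution; on uncensored data it reduces
exactly to the rank AUC of event-by-horizon, which the tests verify. The
train/validation split is a seeded permutation into ⌊n/2⌋ / ⌈n/2⌉ halves,
recorded in the output metadata.

## Synthetic cohort generator

The generator defines the study conditions for every test. Defaults: 50
normal and 177 tumor samples (the cohort sizes this design emulates), 500
genes, log2 expression = per-gene baseline N(6, 2) + planted group shifts +
N(0, 1) noise; a checkpoint gene elevated by +2 in half the tumors so
stratification selects the complement; stromal/immune signature genes (40 +
40) shifted by a per-sample infiltration factor (N(+1, 0.5) in normals,
N(−1, 0.5) in tumors — tumors are infiltration-poor); probes per gene-region
1 + Poisson(2), β = clipped Gaussian around a region-typical mean (promoters
low, gene body high) with sd 0.05 and planted tumor Δβ centred so both group
means stay interior (|Δβ| > 0.9 errors as infeasible); survival for tumor
samples from a proportional-hazards model with exponential baseline hazard
1e-3/day on mean-centred planted-gene expression, censored at
Uniform(0, 3000) days (≈30% censoring); a Barabási–Albert PPI graph (each
arriving node attaches m = 3 edges, so |E| = m(n−m)) with DMEG genes mapped
onto it; drug target sets drawn from controlled distance bands (on-target /
near / remote). All randomness flows through a single
`numpy.random.Generator`; the seed fully determines the cohort, and
bit-identity under a repeated seed is a test.

Planted prognostic coefficients in the examples are 0.7–0.9 in absolute
value per log2-expression unit — the scale of a strong prognostic gene and
large enough that an n ≈ 88 training half can resolve the signature; Gaussian
log2 noise matches the approximate normality the moderated t assumes, and
clipped-Gaussian β noise is simpler than a Beta model and adequate for
threshold-based calling.

What the generator does **not** emulate: realistic 450K probe naming or
density, batch and platform effects, copy-number or mutational structure,
correlated co-expression modules beyond the planted signatures, Beta-shaped
β-value noise, non-proportional hazards, or informative censoring. Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the stated generative model, not performance on real
cohorts.

## Problem sizes used in the checked examples

Calibration nulls run 50 seeds of 20 + 20 samples × 120 genes; recovery runs
20 seeds of 30 + 30 samples with planted log2 shifts of 2 (noise sd 0.1) and
Δβ of 0.4 (noise sd 0.05); the stability-selection example uses 31 candidate
genes, an 88-sample training half and 100 repetitions; coefficient recovery
uses 200 tumors over 10 seeds. These sizes were chosen so the full suite
runs comfortably on a laptop while keeping every check statistically
well-powered.

## Known limitations

- The moderated-t prior uses moment inversion, not Fisher scoring; degrees
  of freedom can differ slightly from other empirical-Bayes implementations.
- Probe-level differential methylation (DMP/DMR calling), covariate
  adjustment, competing risks and multivariable clinical models are out of
  scope.
- The proximity score treats the PPI graph as unweighted and undirected;
  confidence scores act only as an edge filter.
- ORA ignores gene-ontology graph topology; sets are flat.
- The expression scale is whatever the caller declares; the reader records
  (and the log2 transform flips) a scale flag but cannot infer units.
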