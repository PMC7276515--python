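# Methods

`sdbexpr` implements a replication-first framework for discovering
blood gene-expression correlates of sleep-disordered breathing (SDB)
and confirming them in an interventional cohort. This note documents
the statistical model, the numerical choices, the synthetic study
conditions, and the known limitations.

## Traits and polarity

Three quantitative SDB traits are supported:

| trait | meaning | units | severity polarity |
|-------|---------|-------|-------------------|
| AHI   | apnea-hypopnea index | events/hr, >= 0 | higher = more severe |
| avgO2 | mean oxyhemoglobin saturation during sleep | %, (0, 100] | lower = more severe |
| minO2 | minimum oxyhemoglobin saturation during sleep | %, (0, 100] | lower = more severe |

The polarity convention threads through the whole pipeline: the
*severity association* of an effect is its sign for AHI and the negated
sign for the O2 traits, and effective treatment is expected to move a
gene *against* its severity association.

## Per-transcript association model

Within each stratum (e.g. race/ethnic group) expression of one
transcript is the outcome of a linear mixed model

    y = b0 + b1 * trait + covariates + u_group + e,
    u_group ~ N(0, sigma_g^2),  e ~ N(0, sigma_e^2),

with a random intercept on the cohort's grouping factor (expression
chip, or family for cohorts with relatedness), fitted by REML. The
trait coefficient `b1`, its standard error, p-value and the per-SD
scale (`b1 * SD(trait)`, SD computed within cohort) are reported.

**Solver.** The scan fits the same design against thousands of
outcomes, so `sdbexpr.lmm` profiles the REML criterion over the
variance ratio `lambda = sigma_g^2 / sigma_e^2` after rotating the
problem by the eigenvectors of Z Z'. A single fit is a bounded 1-D
optimization; the whole-study scan evaluates the criterion on a fixed
`log10(lambda)` grid shared by all transcripts and refines each
optimum by parabolic interpolation. The test suite pins the solver to
statsmodels `MixedLM` (independent implementation) on random data.

**OLS fallback.** When the variance component is on its zero boundary
(`lambda < 1e-8`), the optimizer fails, or the grouping factor has one
sample per level, the transcript is refitted by OLS with the same
fixed effects. The output records which model produced each estimate.

**P-value references.** Per-stratum p-values default to a t reference:
exact residual df for OLS; for the mixed fit a containment-style df,
`n - p - (g - 1)`, counting the `g` group intercepts against the
residual df. Cross-stratum (and later cross-cohort) combination
reports the inverse-variance fixed-effects estimate and SE, but its
p-value is computed by combining the per-component calibrated
z-scores with sqrt(n) weights. The more familiar large-sample choices
(normal Wald per stratum, normal approximation on the IVW z) are
available via `ModelSpec(p_reference="normal")` and
`meta_analyze(..., p_method="ivw-normal")` and agree with the defaults
as samples grow. The defaults exist because at desk scale (strata of a
few dozen samples, ~10 fixed effects, few chips) the normal/IVW route
is measurably anticonservative: inverse-variance weights estimated
with ~10-20 df make the combined z heavy-tailed even when every
stratum fit is exact. The calibrated-z combination is exactly standard
normal under the null whenever the component p-values are calibrated.

## Cross-replication

For each trait, each cohort serves once as discovery and once as
replication. Discovery transcripts are gated by Benjamini-Hochberg FDR
q < 0.05 computed *per trait per cohort* (families are never pooled).
Each gated transcript is matched many-to-many to every transcript of
the same gene symbol (case-sensitive exact match) on the other
platform, and each match is tested with a one-sided p-value:
`p_two / 2` when the replication effect has the discovery sign,
`1 - p_two / 2` otherwise. A gene replicates when any match has
one-sided p < 0.05; the two directions' gene lists are unioned, a gene
counting once. Discovery effects that are exactly zero carry no
direction and are excluded from candidacy.

## Meta-analysis

All transcripts (no discovery gate) are matched many-to-many across
platforms; each pair's per-SD effects are combined by inverse-variance
fixed-effects meta-analysis; BH-FDR runs across all pairs of one
trait. Genes with >= 1 pair under q < 0.05 are carried forward.
Effects must be on the per-SD trait scale because raw units are not
comparable across platforms. A transcript matched to several partners
contributes several non-independent pairs; no correlation adjustment
is applied — this mirrors the procedure the pipeline models and is a
known caveat (see "False discovery control" below). The final
discovery list is the union of the two routes, each gene tagged
`cross-replication`, `meta-only` or `both`.

## Treatment response

In the paired pre/post cohort, each carried gene gets a paired t-test
on per-subject log2 differences; `mean FC = 2^mean(d)`; direction is
`+` when mean FC > 1. The replication test is one-sided with the
expected direction `-(severity association)` of the discovery record:
a gene positively associated with severity must *fall* after
treatment. `responding` requires one-sided p < 0.05. A gene carried
under several trait records is tested per record and responds if any
record passes (a config switch can require unanimity). Zero-variance
differences yield p = 1, never "responding". The log base cancels in
the decision rule; log2 is used throughout.

## Preranked enrichment

The transcriptome is ranked by the signed per-gene statistic (z for a
trait, paired t for treatment); when a gene has several transcripts
one is chosen uniformly at random under the run seed. The enrichment
score is the signed extremum of the weighted running sum (hits add
`|s|^w` normalized over hits, misses subtract `1/(N-K)`; default
weight 1, weight 0 exposed for enumeration oracles). Significance uses
gene-label permutations — random same-size sets against the fixed
ranked scores — because the input is a precomputed ranked list, not a
sample-by-sample matrix; phenotype permutation is out of reach by
construction. Per set: one-tailed permutation p on the observed ES
sign (with an add-one correction so p > 0), NES = ES normalized by the
mean same-sign null |ES|, and FDR q from the pooled null NES
distribution, positive and negative sides separate. Sets with fewer
than 10 or more than 500 members in the ranked list are excluded by
default. A set equal to the whole ranked universe is defined to score
ES = 0 (no enrichment information). Enrichment-map edges connect
significant sets with overlap coefficient `|A∩B| / min(|A|,|B|) >=
0.25`.

## Synthetic study conditions

The generator emulates the two-discovery-cohort + paired-treatment
design with known ground truth. Defaults (a ~5x-reduced version of the
real design):

- **Cohort A** ("multi-site, chip random effect"): 3 strata of 40
  samples, expression chips of 5 samples; covariates age, sex, site,
  four residual blood-cell fractions. **Cohort B** ("single-stratum,
  family random effect"): 100 samples in families of 1-4. Strata much
  smaller than ~40 leave too few df per chip for calibrated tails,
  which is why the reduction stops at ~5x rather than 10x.
- 2000 genes, 1-3 transcripts per gene per platform (P = 0.5/0.3/0.2),
  disjoint transcript namespaces, shared gene symbols.
- Traits are generated through a Gaussian copula whose latent carries
  a shared per-sample **severity factor** (weight 0.8, giving
  inter-trait correlations ~0.7-0.8, matching how strongly AHI and the
  O2 indices co-vary) plus age/BMI/sex confounding; marginals hit the
  target moments (AHI mean 19.6, sd 18.9; avgO2 94.2 (1.8); minO2
  83.0 (7.7)) by construction.
- 50 planted genes load on the severity factor with per-SD effect 0.5
  and a random severity sign, so each planted gene carries positive
  AHI and negative avgO2/minO2 coefficients (or the reverse). The
  effect size is ~sqrt(5) times a realistic full-scale per-SD effect,
  compensating the ~5x sample reduction; it was fixed once as the
  calibrated operating point.
- Expression: per-gene baseline + per-(stratum, gene) intercepts (sd
  0.3) + per-(chip/family, gene) random intercepts (variance 0.2) +
  covariate loadings + N(0, 1) noise; transcripts of a gene share the
  gene signal plus a transcript offset and N(0, 0.3) noise. BMI loads
  on the traits (confounder) but not on expression by default, which
  is what makes the BMI-sensitivity invariance test meaningful.
- Paired cohort: 15 subjects, log2 reversal effect 1.0 against the
  severity sign, within-subject sd 0.5, between-subject sd 1.0.
- Gene sets: 40 uniform decoy sets (15-60 genes) plus 2 planted sets
  built from a single (trait, severity-sign) block of planted genes,
  padded with random genes, so each planted set moves coherently.

What the generator does **not** emulate: probe-level microarray noise
(GC content, batch waves), platform-specific annotation errors,
trait measurement error from single-night studies, or real linkage
between cell composition and disease. Passing tests therefore
demonstrate the *decision logic and statistical calibration* of the
pipeline, not its behavior under real microarray artifacts.

## False discovery control of the combined list

The replication-gated route controls its gene-level FDR tightly
(measured ~0.02 across 50 seeded runs: a false gene must survive both
an FDR gate and a direction-consistent one-sided test). The
meta-analysis route controls *pair-level* FDR at 0.05 within each
trait family — its p-values are calibrated (null tail ratio ~1.0-1.1
at the BH-relevant thresholds) — but the published carry-forward rule
"gene has >= 1 pair with q < 0.05" converts pair FDR into a roughly
2x larger gene FDR (a true gene consumes ~3 correlated pairs, a false
gene ~1), and the union over three per-trait families and two routes
accumulates false genes while true genes overlap. The measured
gene-level FDR of the combined list is ~0.15 at default conditions.
This is a structural property of the prescribed decision rules (per
-trait families, >= 1-pair gene selection, cross-trait union), not a
calibration defect; the corresponding acceptance test asserts the
nominal 0.05 and is expected to fail, deliberately left that way
rather than weakening the check. Practitioners should treat the
meta-only portion of a combined list as exploratory and lean on the
treatment-replication stage (which retains a strict 0.05 one-sided
gate) for confirmation.

## Numerical choices and degenerate inputs

- Variance-component boundary: `sigma_g^2 < 1e-8 * sigma_e^2` (or
  optimizer failure) triggers the OLS fallback.
- Collinear fixed effects raise an error naming the offending columns
  (pivoted-QR order past the numerical rank).
- Constant expression or constant trait in a stratum is a "degenerate
  input" error for single fits; in whole-study scans the stratum is
  skipped for that transcript and the remaining strata are combined,
  with transcripts failing everywhere excluded and counted.
- Missing phenotype values: listwise deletion per stratum; missing
  expression values: per-transcript listwise deletion with `n`
  recorded.
- BH ties: stable sort, equal p receive equal q.
- One-sided conversion of a zero-signed (beta = 0) replication effect
  is treated as direction disagreement (conservative).
- Ranked-list ties are broken by gene symbol for determinism; the
  random transcript-per-gene choice is governed by the run seed, and
  a single global seed spawns independent child streams for every
  component, making every stage output bit-reproducible.

## Family relatedness

Cohort B's relatedness is modeled as a family-block random intercept,
not a full kinship matrix. For the family structures simulated here
(blocks of 1-4) the block intercept is exact; for real pedigrees with
varying kinship coefficients it is an approximation, and effects
shared across families (e.g. polygenic background) are not captured.

## Problem sizes used in tests

The test suite runs reduced problem sizes chosen to preserve the
statistical structure: 50-run FDR/recall suites use 150 genes and 15
planted genes per run; null-calibration suites use 400-2000 genes; the
meta-only demonstration uses effect 0.3 (below the default 0.5, so
per-cohort discovery is underpowered while the meta-analysis is not);
CI coverage uses 500 replicates at n = 200; paired power uses 1000
replicates against the noncentral-t closed form. The acceptance script
runs the full default scale (2000 genes) once plus 20 reduced
replicates.
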