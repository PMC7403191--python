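# Methods

This note documents the statistical procedures implemented in `orthoimmune`,
the modeling assumptions behind them, the tunable parameters that matter, and
the design choices made where the design was genuinely open.

## Study design being emulated

The package analyzes a cross-sectional murine cohort: whole-blood samples
from 8 mice per sex per timepoint (baseline BL, 12 h, 7 d, 7 wk after
orthopedic injury), each animal sampled once by terminal collection. Each
sample is a per-cell table of 32 marker intensities — 20 surface markers used
for hierarchical gating and 12 intracellular signaling markers (pSTAT1,
pSTAT3, pSTAT5, pSTAT6, p-p38, pCREB, pNFκB, pERK, MAPKAPK2, CD62L, pS6,
IκB). All analysis operates on arcsinh-transformed intensities,
`asinh(raw / cofactor)`; the cofactor defaults to 5 (the mass-cytometry
convention — the original cofactor is not published, and all results are
invariant to jointly rescaling raw intensities and the cofactor).

## Gating and immune features

Cells are assigned to 21 leaf populations by a declarative gate tree
(1-D/2-D interval predicates on arcsinh channels). The full 21-population
roster and gate boundaries of the original study live in supplementary
material not reproduced in the text, so the default scheme is a standard
murine whole-blood hierarchy (neutrophils; classical/intermediate/
non-classical monocytes; macrophages; mDC/pDC; eosinophils; basophils; NK;
ILC; NKT; γδT; B and memory B; plasmablasts; naive/memory CD4 T; Tregs;
naive/memory CD8 T) matched to the synthetic generator's signatures — it is
illustrative, not a reproduction; user-supplied YAML schemes serve real data.
Cells satisfying no leaf remain `UNGATED` but still count in any denominator
gate they satisfy.

Two feature classes (together 21 × (1 + 12) = 273 features):

- **Frequencies** — neutrophils as % of gated singlets; every other
  population as % of mononuclear (CD45+ Ly6G−) cells. A zero-count
  denominator yields an explicit missing value, never a silent zero. In
  synthetic data there are no doublets, so singlets = all events; the
  denominator node is still explicit for real input.
- **Functional features** — per sample and population, the cell-level median
  arcsinh intensity of each signaling marker minus a baseline reference.
  The reference pools all baseline cells of the population (median over the
  concatenated cells, not a median of per-sample medians). Whether the
  original reference was pooled across sexes or per sex is unstated; pooled
  is the default because a per-sex baseline would erase the baseline sex
  signal that the published 12 h model projection clearly retains. Both
  policies are implemented (`policy="per-sex-baseline"`).

Missing features (a population empty in a sample) are imputed by the
feature-wise median within timepoint before modeling (falling back to the
overall median), with the imputation count logged — the elastic net needs a
complete matrix and the original handling is unpublished.

## Correlation network

Spearman's rank correlation (midranks for ties) is computed for every pair
of features; with 273 features that family is C(273,2) = 37,128 pairs. An
edge is kept iff `p_raw × n_pairs < 0.05` (Bonferroni over all tested
pairs). The network admits all 273 features by default — the communities of
the original analysis carry frequency annotations alongside signaling ones —
with `feature_class="functional"` available to restrict to signaling
features only.

P-values are permutation-calibrated by default: exact enumeration of all
n! rank permutations for n ≤ 10, and a fixed-seed (seed 12345) table of
2×10⁶ permuted correlations for 10 < n ≤ 128 (the null distribution of rho
is universal absent ties; tied data are tested against the untied null, a
standard approximation). The usual t-approximation is available
(`p_method="t"`) and is the fallback for larger n, but at n = 16 it is
anti-conservative precisely in the deep tails where Bonferroni thresholds
live: in a 200-replicate global-null simulation it produced a family-wise
false-edge rate of ~0.14, versus ~0.05–0.06 for the permutation null.

The 2-D layout embeds the dissimilarity 1 − |rho| with t-SNE (seeded;
perplexity min(30, (n−1)/3)); graphs with fewer than 8 nodes use a seeded
spring layout. Communities are found by greedy modularity maximization over
the significant edges weighted by |rho|; an edgeless graph yields singleton
communities. Each community is annotated by its most dominant modal
attribute (population, marker, or feature class). The published figure
shows 15 visually segregated communities on the real cohort; that count is
data-dependent and is not asserted as reproducible.

## Per-timepoint elastic-net models of sex

At each timepoint an elastic net (Gaussian objective; sex coded male = +1,
female = −1) is fit on the 273 standardized features. Nested leave-one-out
cross-validation: the outer loop holds out one animal; the inner loop
(leave-one-out over the remaining 15) selects the mixing parameter
(grid 0.1–0.9, step 0.1) and penalty strength (50 log-spaced values from the
data-derived maximum, down to 10⁻³ of it) — re-selected inside every outer
fold, the stricter reading of the published two-layer scheme.
Standardization statistics are recomputed inside each training fold.

**Hyperparameter selection and the null gate.** Selection uses a
one-standard-error-family rule rather than the raw CV minimum: a candidate
model is adopted only when its inner-CV error beats the intercept-only
(fully shrunk) solution by more than `null_gate_se` standard errors
(default 3.5), after which the strongest penalty within one SE of the
minimum is taken. The gate exists because out-of-fold scores from
leave-one-out are *coupled* — all fold models share 14 of 15 training
samples — so models fit to noise (including real but sex-unrelated
animal-level structure) produce scores that spuriously separate whatever
labels they were trained on; with plain minimum-CV selection the
nominal-0.05 rank-sum test below rejected 15–30% of null replicates,
invariant to shrinkage scale. The gate width is the procedure's critical
value: it was calibrated by simulation against fresh null cohorts from the
generator (measured unconditional type-I ~0.083 at 3 SE, 0.040 at 3.5 SE,
0.010 at 5 SE; power at the injected effect sizes is unaffected across this
range), fixing 3.5 so the test attains its nominal 0.05 level.
`selection_rule="min"` recovers the uncorrected variant. The gate width is
tied to the hyperparameter grid it was calibrated with (3 mixing values ×
20 penalties, the grid of the simulation studies): a richer grid offers
more candidate minima and deepens the apparent CV improvement under the
null, a coarser one the reverse, so the gate should be recalibrated when
the grid changes materially. Note that the
level is an unconditional property: conditional on any single cohort the
realized rejection rate over label permutations fluctuates with that
cohort's accidental animal-factor structure, as for any cross-validated
score test.

**Scoring and significance.** The out-of-fold score of a sample is the
centered linear score `x_std · β` of its outer-fold model; the fold
intercept (the training-label mean) is excluded because under leave-one-out
it equals −y_held_out/15 and would force spurious anti-separation of a
fully shrunk model. Model significance is the exact two-sided Wilcoxon
rank-sum test comparing male and female out-of-fold scores — all
C(16,8) = 12,870 assignments of the midranks are enumerated, so complete
separation gives p = 2/12,870 ≈ 1.554×10⁻⁴ — Bonferroni-corrected over the
family of 4 timepoint models (`family_size` is a parameter). Per-feature
univariate p-values use the same exact rank-sum and feed the network node
sizes as −log10 p.

**Final model and projection.** The reported model is refit on all samples
at the modal mixing parameter and log-median penalty across the outer folds;
its standardization statistics are stored. A feature elevated in females
receives a negative coefficient ("female-up = negative"). The time
projection applies the final model's affine score
`intercept + Σ coef·(x − mean)/sd` to the feature rows of every timepoint
and reports per-sex median/min/max per timepoint. Because sexes are
balanced, the intercept is ~0 and projections are centered; the original
study's asymmetric projection medians imply an unpublished coding/centering
convention, so this package documents its own rather than guessing.

## Behavioral scoring

**Up-down 50% withdrawal threshold.** Staircases on the 8-filament set
0.007–6.0 g (log-spaced; mean log10 step δ ≈ 0.419) starting at 0.4 g:
withdrawal (X) steps down, no response (O) steps up, four more responses are
collected after the first reversal; no response at the strongest filament
reports the 6.0 g ceiling, withdrawal at the weakest the 0.007 g floor. The
threshold is `10^(x_f + k·δ)` g with x_f the log10 force of the last
filament and k the Dixon correction for the response pattern. k is obtained
by maximum likelihood under a normal psychometric function with scale δ —
the construction underlying the published correction tables — evaluated by
bounded scalar optimization; this supports arbitrary filament sets and
matches an independent likelihood-grid oracle to <10⁻⁵ g on reference
patterns. Shorter-than-terminal but rule-consistent sequences are scored
from the available responses; rule-violating sequences raise a validation
error.

**Gait General Score.** Per paw, each of F = 42 gait parameters is compared
between baseline and day 7 by an unpaired two-sample t-test (classic
equal-variance by default, Welch by flag; raw p < 0.05, no multiplicity
correction, per the score's definition); the score is
`(1 − n_significant/F) × 100%`. Parameters with zero variance in both groups
have an undefined test and count as not significant (logged); missing cells
are dropped per parameter.

## Synthetic cohort generator

The generator emulates the study conditions: 8 mice/sex/timepoint (new
animal ids each timepoint — terminal sampling), 21 populations with binary
surface signatures placed ≥3 arcsinh units from every gate boundary
(hi ≈ 6.5, lo ≈ 0.3, cell sd 0.4, threshold 3.0), mixture fractions from a
murine whole-blood table (only the neutrophil fraction is sex-specific at
baseline, male > female, offset in B cells), per-sample lognormal frequency
jitter (sd 0.1), and multinomial cell counts. Functional markers are drawn
directly on the arcsinh scale (the analysis consumes arcsinh medians only;
raw values are the inverse transform): cell sd 0.5 around a generating
median composed of a baseline (2.0), an animal-level global factor
(sd 0.10), a per-population factor (sd 0.10), independent per-feature animal
noise (sd 0.08), and any injected effect deltas. The factor structure makes
features intercorrelated within an animal, as in real cytometry cohorts —
without it the feature matrix is an unrealistically independent design.

The default effect template injects the reported directions: female ↑
neutrophil pSTAT3 (+1.2) and ↓ Treg pSTAT1/pSTAT6 (−1.0) at 12 h; female ↑
CD4 memory T p-p38/pNFκB/pERK (+1.0) at 7 d; sex-shared neutrophil CD62L
shedding and frequency expansion at 12 h and classical-monocyte CD62L
up/down and pSTAT3 activation. Deltas are arcsinh-scale shifts of the
generating median (or additive mixture-fraction shifts); the per-population
baseline frequencies and distribution parameters are free choices, not
calibrated to the deposited raw data. Ground truth (realized fractions,
generating medians, per-cell population labels) is recorded for recovery
tests.

What passing tests do *not* show about real data: the generator has no
doublets, debris, spillover, acquisition drift, batch effects, or non-normal
intensity distributions, and its gate-signature separation is idealized —
label-recovery and effect-recovery results bound algorithmic correctness,
not real-world gating accuracy.

A reduced roster (`simulation_cohort_config`: 8 populations × 13 features =
104 features, 600 events/sample, sex-balanced baseline frequencies) defines
the conditions for the calibration/power simulation studies; the replicate
counts there (200 permutations, 50 cohorts) follow the evaluation design,
and the elastic-net grid is reduced to 3 mixing values × 20 penalties purely
for runtime — the properties tested are grid-independent.

## Numerical and degenerate-input choices

- Exact rank-sum enumeration switches to the tie-corrected normal
  approximation above 3×10⁶ group assignments.
- All-tied score vectors give p = 1; constant features give univariate
  p = 1 and are dropped from fitting with zero final coefficients.
- Penalty-grid ties break toward the strongest penalty (sparser model);
  mixing-parameter ties toward the smaller value.
- Elastic-net solver: coordinate descent, tol 10⁻⁸, max 5×10⁴ iterations on
  the final refit.
- Every stochastic step (generator, t-SNE, permutation tables) is seeded;
  the pipeline derives all stage seeds from the run seed and re-runs
  bit-identically.

## Known limitations

- The rank-sum test on cross-validated scores is approximate even with the
  null gate: exchangeability holds only asymptotically in the
  effective-dimension regime, and the gate's calibration was performed under
  the generator's null, not proven distribution-free.
- The permutation null for Spearman p-values treats tied data with the
  untied reference distribution.
- Real-data gating schemes, panels and baselines must be supplied by the
  user; the defaults describe the synthetic cohort.
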