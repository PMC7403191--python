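# orthoimmune

Sex-divergence analysis of the murine systemic immune response to orthopedic
injury, from single-cell cytometry events to multivariate models and
behavioral scores.

After a tibial fracture, male and female mice show similar pain-related
behavior but need not mount the same immune response. This package
implements the computational arm of that question for mass-cytometry-style
data collected at four timepoints (baseline, 12 h, 7 d, 7 wk; 8 animals per
sex per timepoint):

- **Gating & features** — hierarchical gating of per-cell events into 21
  immune populations and derivation of 273 immune features per sample: 21
  cell frequencies (neutrophils as % of singlets, all else as % of CD45+
  Ly6G− mononuclear cells) and 21 × 12 functional features, each the
  arcsinh-median signal of an intracellular marker minus its baseline
  reference.
- **Correlation network** — Spearman correlation over all C(273,2) = 37,128
  feature pairs with Bonferroni-thresholded edges (p·37,128 < 0.05),
  a seeded t-SNE layout of the association structure, and modularity-based
  community detection with automatic annotation.
- **Elastic-net models of sex** — per timepoint, an elastic net predicting
  sex (male = +1, female = −1) under two-layer leave-one-out
  cross-validation: the inner layer selects the penalty strength λ and
  mixing parameter from a grid, the outer layer scores each held-out animal
  with a model that never saw it. Model significance is the exact two-sided
  Wilcoxon rank-sum test on the out-of-fold scores (complete 8-vs-8
  separation gives p = 2/12,870 ≈ 1.55×10⁻⁴), Bonferroni-corrected over the
  4 timepoint models. Negative coefficients mark female-elevated features.
  Fitted models are time-projected onto every timepoint's data.
- **Behavior** — the up-down (Dixon) 50% mechanical withdrawal threshold on
  the 0.007–6.0 g von Frey filament set, and the per-paw Gait General Score
  `(1 − n_significant/42) × 100%` over 42 gait parameters (unpaired t-tests,
  baseline vs day 7).
- **Synthetic cohorts** — a seeded generator that emulates the study design
  (population mixtures, gate-separable surface signatures, intercorrelated
  animal-level signaling variation, configurable sex-by-time effects such as
  female-elevated neutrophil pSTAT3 at 12 h) with full ground-truth records,
  so every stage is testable offline.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the demonstration pipeline (simulate → gate → features → network →
models → projections → report):

```sh
orthoimmune run --demo --seed 7 --outdir demo_run
```

or equivalently from Python:

```python
from orthoimmune import demo_config, run_pipeline
run_pipeline(demo_config(outdir="demo_run", seed=7))
```

The run directory contains the cohort event files, the 64 × 273 feature
table (`features.csv` + `feature_annotations.csv`), the network
(`network.graphml`, node/edge tables, `network.png`), one model JSON and
projection table per timepoint, a `report.md`, and a `manifest.json` with a
checksum of every output (re-running the same config reproduces every file
bit-identically). The report's model table from this seed:

| timepoint | p_raw | p_bonferroni | significant (a=0.05) | nonzero features |
|---|---|---|---|---|
| BL | 0.000155 | 0.000622 | yes | 5 |
| 12h | 0.000155 | 0.000622 | yes | 6 |
| 7d | 0.000155 | 0.000622 | yes | 10 |
| 7wk | 0.00622 | 0.0249 | yes | 4 |

and its top 12 h coefficients:

```
- Neutrophils|pSTAT3: coef -0.549 (female-elevated)
- Tregs|pSTAT6: coef +0.305 (male-elevated)
- Bcells|FREQUENCY: coef -0.041 (female-elevated)
```

Reading: at 12 h the model separates every male from every female by their
out-of-fold scores (p = 2/12,870, the smallest achievable exact rank-sum
p, times the family of 4 models), and its signed coefficients recover the
injected biology — neutrophil pSTAT3 elevated in females, Treg
pSTAT1/pSTAT6 suppressed in females (hence male-positive coefficients).
The 7 d model is carried by the female-elevated CD4 memory T-cell MAPK
features (pNFκB, p-p38, pERK all negative). Baseline and 7-week models are
also significant in this cohort because the default generator, like the
emulated study, gives males a higher baseline neutrophil frequency — a
persistent sex difference the frequency features pick up at every
timepoint (a null run, `--no-effects` with sex-balanced frequencies, leaves
all four models non-significant in most seeds). Behavioral scoring works the same way
from the command line:

```sh
$ orthoimmune behavior gait --table gait.csv
gait general score: 85.71%
```

(a generated table in which 2 of 42 parameters truly shift at day 7 and
four more cross p < 0.05 by chance: (1 − 6/42) × 100 = 85.71%).

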