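# Methods

This note documents the models, parameter choices and numerical decisions
behind `immunofrail`, in the order data flows through the pipeline.

## Synthetic cohort model

**Design.** The generator emulates an age- and sex-stratified subcohort of
older adults: `n_men=145`, `n_women=144`, ages drawn uniformly on 60–87
(integer years), sampled in *equal numbers* from three frailty strata —
the healthiest 15%, intermediate 70% and frailest 15% of the underlying
population (configurable `strata_fractions`). Stratum membership is
realized by inverse-CDF sampling of a latent health score *H* ~ N(0,1)
restricted to the stratum's quantile band. Five men and seven women are
flagged as missing their frailty assessment.

**Frailty.** Each participant carries 36 binary deficits obtained by
probit thresholding: deficit *i* is present iff `H + δ_g > τ_i`, where
`τ_i = Φ⁻¹(1 − p_i)` and the item prevalences `p_i` are log-spaced from
0.02 to 0.95. The log spacing (many rare items, a few near-universal
ones) keeps exact ties in the index rare — fewer than ~12% of
participants sit at FI = 0 — which matters because the rank-based
analyses degrade under heavy ties. `δ_g` is an age-group offset
(−0.25, −0.08, 0.08, 0.25 across the four age quartiles), so frailty
rises with age yet remains a monotone function of *H* *within* each
block. Deficits are deterministic given *H*; the resulting item patterns
are nested (a participant with a rarer deficit has all commoner ones),
which real deficit data are not — see Limitations.

**Cell concentrations.** Thirty generative "leaf" populations partition
leukocytes; the 37 reported subpopulations are fixed unions of leaves.
Leaf log-concentrations are Gaussian:
`log c = log(base) + sex + CMV + age·slope + σ·z`, with σ = 0.5 and
base concentrations set at typical adult values (neutrophils 3500/µL,
classical monocytes 400/µL, T cells ≈ 1200/µL, …). Sex, CMV and age-group
terms are constant within an analysis block, so they do not disturb
within-block rank correlations; the small continuous age slopes
(|slope| ≤ 0.008/yr) add at most ~0.03 SD of within-block noise.

**Effect calibration.** The latent part `z = r·G + √(1−r²)·ε` couples a
profiled population to frailty through a one-factor Gaussian copula.
*G* is the rank-normalized health score under the stratified sampling
design, `G = Φ⁻¹(F_strat(H))` — the copula is applied to the score's
*sample* ranks, so targets hold in the selected cohort rather than the
source population. `r = 2·sin(πρ/6)` inverts the Spearman–Pearson
relation for bivariate Gaussians, making the within-block Spearman
correlation between concentration and FI equal the target ρ up to the
(small) tie attenuation of the deficit staircase. Leaves belonging to one
effect-profile entry share a single idiosyncratic draw ε; without this,
summing leaves would cancel noise and *amplify* the aggregate's rank
correlation beyond its target. A consequence is that the member leaves of
a profiled aggregate (e.g. the three CD4 TemRA stages) are perfectly
rank-correlated with one another — acceptable for rank-based analyses,
unrealistic in detail. Under the one-factor construction any set of
targets with |ρ| < 1 is jointly attainable, so validation reduces to the
per-target bound. Default targets: neutrophils 0.40 (women) / 0.25
(men); CD16⁻ monocytes 0.24, CD16⁺ monocytes 0.12, CD56⁺ T −0.20,
CD4 TemRA −0.13 (women). Total monocytes then land near 0.23
automatically, since classical monocytes dominate the sum. CMV
serostatus is sampled independently of *H* (no direct frailty effect);
it shifts late-memory T-cell concentrations (+0.6 log units), which
drives the CMV association study.

**Events.** Per tube, each leaf contributes Poisson(concentration ×
stained volume × acquisition fraction) events; channel intensities are
lognormal around population level means at log-intensity 0 / 2 / 4
(negative / dim / bright) with log-SD 0.25. With cuts at e¹ and e³,
every level mean sits 4σ from the nearest cut: cross-gate leakage is
~3·10⁻⁵ per channel, small enough that rare populations adjacent to
abundant ones (CD16⁺ monocytes next to neutrophils) are recovered within
Poisson error. Defaults: 50 µL stained volume, 50,000 beads, acquisition
fraction 1/3 (≈10⁵ events/tube), 200/µL debris events; all are
instrument-side conventions, not estimates. Bead events are identified
by a CD3⁺CD19⁺ "double-bright" signature no cell carries.

## Gating

Definitions form one tree per tube (TruCOUNT: lineages, B/NK subsets,
CD4/CD8 totals; Falcon: memory subsets, Tregs, Tfh rooted at CD3⁺), with
each node a conjunction of negative/positive/dim/bright predicates over
its parent's events. Ties exactly at a cut go to the higher band.
The neutrophil gate is SSC-bright ∧ CD45-dim; monocytes SSC-dim ∧
CD45-dim ∧ CD3⁻CD19⁻. NK cells are the CD3⁻CD19⁻ lymphocyte remainder,
subdivided into four CD16×CD56 subsets (CD56^bright CD16⁻,
CD56^dim CD16⁺, CD56^dim CD16⁻, CD56⁻CD16⁺); with the four NK subsets
the default table enumerates exactly 37 subpopulations. T cells appear
in both tubes; CD4/CD8 gates exclude CD56⁺ T cells so the T compartments
are disjoint. The table ships as an editable YAML config
(`data/phenotypes.yaml`); thresholds are per-channel configuration,
defaulting to the cuts that bisect the generator's intensity bands — the
stand-in for manual gate placement. An HLA-DR⁺ restriction of the
monocyte gates is available as a sensitivity filter.

## Quantification

TruCOUNT: `cells/µL = events × (beads_per_tube / bead_events) / volume`.
Falcon phenotypes are scaled by `falcon_events × (CD3 concentration from
the TruCOUNT tube / CD3 events in the Falcon tube)` — the only
dimensionally consistent form of the cross-tube CD3 ratio. Phenotypes
measured in both tubes are reported from the bead-calibrated tube.
Concentrations are kept as reals (no rounding: downstream rank statistics
are tie-sensitive). Debris-exclusion flags are input metadata, mirroring
manual judgment; a flagged lineage is blanked for that participant.

## Frailty index

Mean of the 36 items (each in [0, 1]; graded severities allowed, binary
generated). Records missing more than 6 of 36 items get a missing index
(the usual deficit-index completeness convention, configurable);
participants with a missing index are excluded from frailty analyses
only. √FI is the forest response — the index is right-skewed and the
square root roughly symmetrizes it without breaking ranks.

## Serostatus

Two-component Gaussian EM on log titers, five restarts (quantile-anchored
plus random pairs), collapse of a component variance below 1e-4 discards
the restart; best log-likelihood kept, components relabeled so µ1 < µ2.
The cutoff solves the weighted density equality — a quadratic in the log
domain — and takes the root inside (µ1, µ2); equal variances reduce it to
`(µ1+µ2)/2 + σ²·ln(w/(1−w))/(µ2−µ1)`. Titers at the cutoff classify as
seropositive. The fit set may differ from the classification set,
mirroring cutoff derivation on a pooled multi-cohort sample.

## Association tests

Blocks: four age groups (the cohort's age quartiles, or a precomputed
`age_group` column when present) crossed with CMV serostatus for the sex
and frailty studies; age only for the CMV studies. Within each block the
weighted-ρ statistic uses centered unit-norm midranks, combined with
weights w_b = n_b (w_b = n_b − 1 available); the blocked WMW statistic
sums per-block centered rank sums each scaled by its rank-sum SD
(equal-precision van Elteren weighting — other weightings differ only by
a permutation-invariant factor and give identical p-values). Blocks with
fewer than 3 usable pairs, a constant variable, or a missing group are
dropped and logged. Monte-Carlo p-values use the add-one estimator
p = (1+B)/(n_perm+1), valid at any n_perm; the Monte-Carlo SE is
reported. Default n_perm = 10⁴ — with the SE in hand users can scale to
the 10⁸ used on dedicated hardware; the pipeline default (2,000) keeps a
full 10-study run under a minute. BH step-up at q = 0.15 is applied
separately per study family (per sex, per scale). Midranks throughout.

## Random forest

Bagged `DecisionTreeRegressor`s (scikit-learn) with package-side
bootstrap/OOB bookkeeping: 1000 trees, mtry = ⌊p/3⌋, node size 5 —
regression-forest conventions. Predictors: all 37 concentrations + age +
CMV serostatus (0/1) + days since the earliest blood draw; entirely
missing predictors are dropped, remaining gaps median-imputed.
PEV = 100·(1 − OOB-MSE / Var(√FI)) (sample variance, ddof 1; response
kept on the √ scale). %IncMSE permutes a predictor among each tree's OOB
samples, re-aggregates OOB predictions, and reports
100·(MSE_perm − MSE_OOB)/MSE_OOB averaged over repeats with its SE —
the raw-percentage definition; an SD-scaled variant is available.
Importance ties rank by predictor name (stable). Partial dependence
averages predictions over the data with the target predictor(s) fixed on
a grid spanning the 1st–99th percentile; predictor deciles accompany each
curve for axis rugs.

## Reproducibility

Every stochastic routine takes a seed; the pipeline expands one master
seed into per-stage seeds via `SeedSequence(master, spawn_key=(stage,
k))`, so stages are independently reproducible and a rerun of `run_all`
is byte-identical. Output tables carry a metadata sidecar with the
config hash, seed and package version.

## Problem sizes in the shipped checks

Effect-size recovery uses ~5,000 participants per age × CMV block
(40,000 per sex); FDR calibration uses 100 simulated 37-phenotype studies
at n = 150 with 2,000 permutations; forest checks use default-size
cohorts (n ≈ 140 per sex) over 10–20 replicate seeds with 500–1,000
trees. These sizes put Monte-Carlo noise well inside the tolerances
being checked while keeping a full run in the minutes range on one core.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* the analysis relies
on: hierarchical gates separated in intensity space, bead-calibrated
counts, a deficit index tied to cell counts through a rank copula at
stated effect sizes, bimodal titers, confound structure by age and CMV.
It deliberately omits spillover/compensation, doublets, debris ambiguity
beyond a flat contaminant class, instrument drift, day effects,
non-nested deficit patterns, and any marginal distribution mismatch with
real blood. Passing tests therefore validate the inferential machinery
and its calibration — not the biology of any real cohort. On real data
the manual gates, the deficit list and the titer assay would replace
their synthetic stand-ins unchanged through the same interfaces.

## Known limitations

* Forest PEV on default-size cohorts is noisy (SD of several points
  across seeds); only its sign/ordering structure is stable, and the
  package asserts only those.
* The weighted-ρ estimator is consistent for the common within-block
  Spearman correlation only when blocks share one target value, as the
  generator guarantees by construction.
* Exact ties in FI (participants below every deficit threshold) slightly
  attenuate rank correlations; with default prevalences the attenuation
  is under 1% of the target.
* The blocked WMW variance uses the midrank (tie-corrected) formula, but
  p-values come from the permutation distribution, not the normal
  approximation, so small blocks are handled exactly up to Monte-Carlo
  error.
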