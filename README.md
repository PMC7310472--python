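# immunofrail

Sex-specific associations between frailty and the immune cellular profile,
as a fully synthetic, end-to-end testable analysis pipeline.

## The scientific problem

With advancing age the composition of leukocyte subpopulations in blood
shifts, and how those shifts relate to *frailty* — accumulated health
deficits — appears to differ between men and women. Studying this requires
a long chain of quantitative steps: hierarchical flow-cytometry gating of
37 leukocyte subpopulations, bead-based absolute enumeration (cells/µL), a
deficit-accumulation frailty index, mixture-model CMV serostatus, blocked
(age × CMV-stratified) permutation association tests with FDR control, and
a random-forest prediction study. This package implements every one of
those steps as a library, together with a synthetic-data generator that
emulates the cohort design (289 participants aged 60–87, equal sampling
from the healthiest 15% / intermediate 70% / frailest 15% strata), so the
whole inferential machinery can be exercised and validated without any
access to participant data.

It is aimed at biostatisticians and immunologists who want a reference
implementation of this analysis style — or a calibrated sandbox in which
to study its operating characteristics (power, FDR, forest importance
behaviour) before touching real cohort data.

## The core statistics

* **Frailty index** (Rockwood type): FI = (deficits present)/36 ∈ [0, 1];
  √FI is used as the regression response.
* **Absolute counts**: for the bead-carrying tube,
  `cells/µL = gate events × (beads per tube / bead events) / volume`; the
  second tube is scaled through the CD3⁺ ratio between tubes.
* **Blocked association tests**: within blocks *b* (four age groups ×
  CMV serostatus), the weighted Spearman statistic
  ρ_w = Σ_b n_b ρ_b / Σ_b n_b, and a van-Elteren-style blocked
  Wilcoxon–Mann–Whitney statistic for group contrasts. Two-sided p-values
  are Monte-Carlo, p = (1 + #{|T*| ≥ |T|})/(n_perm + 1), with labels
  permuted only within blocks; Benjamini–Hochberg step-up at FDR 15% per
  study family.
* **Random forest**: bagged CART regression of √FI on all subpopulation
  concentrations + age + CMV + measurement date; performance as
  PEV = 100 × (1 − OOB-MSE / Var(√FI)); importance as %IncMSE, the
  percentage increase in OOB MSE when a predictor is permuted per tree.
* **CMV serostatus**: two-component Gaussian mixture on log IgG titers
  (EM), cut at the density intersection between the component means.

The synthetic generator couples cell concentrations to a latent health
score through a one-factor Gaussian copula, calibrated so the within-block
Spearman correlation with the frailty index hits configurable targets
(defaults: neutrophils 0.40 in women / 0.25 in men; CD16⁻ monocytes 0.24,
CD16⁺ monocytes 0.12, CD56⁺ T cells −0.20 and CD4 TemRA −0.13 in women;
CMV has deliberately **no** direct frailty effect).

## Worked example

The numbered scripts under `analysis/` run the whole study and write their
tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_gate_and_count.py
python analysis/03_serostatus.py
python analysis/04_associations.py
python analysis/05_predict_frailty.py
```

Output of a run (seed 20160801):

```
cohort: 289 participants (145 men, 144 women), ages 60-87
frailty index: median 0.194 (IQR 0.028-0.528), 12 missing
mean blood-draw to frailty-assessment interval: 1.61 years

gated and quantified 289 participants x 37 subpopulations
median |relative error| vs ground truth: 1.676%; 90th percentile: 5.968%
populations with >=500 expected events within 10%: 99.7%

mixture fit: seronegative N(-0.04, 0.50^2) weight 0.49;
             seropositive N(3.01, 0.64^2); converged in 12 iterations
seropositivity cutoff: 3.77; agreement with ground-truth labels: 99.3%

frailty_by_sex/absolute/F: BH-significant: neutrophils (rho_w=+0.36), ...
```

Reading this: the gating/quantification chain recovers the generator's
true concentrations to within a few percent (bead arithmetic and CD3
cross-tube scaling behave); the mixture fit recovers the two IgG
components and classifies serostatus at ~99% accuracy; and the strongest
planted effect (neutrophils vs frailty in women, target ρ = 0.40) is
detected and estimated at ρ_w = 0.36 in a single 137-woman stratum.
Weaker planted effects (|ρ| ≈ 0.13–0.24) hover at the edge of what
n ≈ 140 per sex can detect under BH at FDR 15% — single-cohort results
for them vary by seed, which is precisely the small-sample behaviour the
sandbox is meant to expose. At larger n (see below) every calibrated
effect is recovered to ±0.05.

One-command equivalent: `immunofrail.workbench.run_all(RunConfig(...))`
executes all stages from a config and master seed, writes every table
plus provenance metadata, and is byte-identical on rerun.

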