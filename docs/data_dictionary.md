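# Data dictionary

Columns of the tables written by the `analysis/` scripts and
`workbench.run_all` (all CSV/TSV, one row per participant unless noted).

## cohort.csv

| column | type | meaning |
|---|---|---|
| participant_id | str | index; `M####`/`F####` |
| sex | M/F | sex |
| age | int | age in years at blood draw (60–87) |
| age_group | 1–4 | cohort age quartile (blocking factor) |
| stratum | str | sampling stratum: healthiest / intermediate / frailest |
| cmv_igg | float | anti-CMV IgG concentration, arbitrary units |
| cmv_status | str | generator ground-truth component label |
| frailty_index | float | 36-item deficit index in [0, 1]; NaN = unassessed |
| blood_draw_date | date | cytometry measurement date |
| frailty_assessment_date | date | deficit assessment date; empty if missing |
| deficit_01 … deficit_36 | 0/1 | individual deficit items (NaN if unassessed) |

## count_matrix.csv / true_count_matrix.csv

Participants × 37 subpopulations, absolute concentrations in cells/µL.
`count_matrix.csv` comes from event-level gating + bead quantification;
`true_count_matrix.csv` is the generator's ground truth. Columns are the
phenotype ids of the default gating table (`subpopulation_names()`).

## proportions.csv

Same shape; each subpopulation as a percentage of its designated parent
(major lineage, or CD4/CD8 T cells for their subsets). Top-level lineages
have no measured parent and are omitted.

## serostatus.csv / mixture_fit.json

Classified CMV serostatus per participant; mixture-fit parameters
(log-scale component means/SDs, weight, log cutoff, iterations).

## associations.tsv

One row per (study, scale, stratum, phenotype):
`study` (sex / cmv_by_sex / frailty_by_sex), `scale`
(absolute / proportion), `stratum` (all, M, F), `test` (wmw / spearman),
`statistic` (blocked test statistic), `weighted_rho` (Spearman studies),
`p` (Monte-Carlo permutation p), `p_bh` (BH-adjusted), `mc_se`
(Monte-Carlo SE of p), `n`, `n_blocks` (blocks contributing), `n_perm`,
`bh_reject` (decision at the configured FDR).

## forest_importance.csv

Per sex and predictor: `pct_inc_mse` (%IncMSE), `se` (over permutation
repeats), `flagged` (above the 50% threshold), `rank`.

## partial_dependence.csv

Per sex and predictor (or predictor pair): grid value(s) and the partial
dependence of √frailty at that grid point.
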