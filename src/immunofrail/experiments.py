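"""Calibration experiments: effect recovery, FDR control, forest checks.

These drive the package's own machinery on generated cohorts at stated
problem sizes; they are shared by the test suite and the reproduction
script so both measure exactly the same quantities.
"""

from __future__ import annotations

import math

import numpy as np

from .association import bh_adjust, blocked_permutation_test, make_blocks, weighted_rho
from .frailty import analysis_set
from .prediction import fit_frailty_forest, rank_importance
from .synthetic_data import (
    CohortSpec,
    cohort_frame,
    generate_cohort,
    true_count_matrix,
)


def _spawn_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % 2**31)


def effect_recovery(sex: str, phenotypes: list[str],
                    n_per_block: int = 5000, seed: int = 0
                    ) -> dict[str, dict[str, float]]:
    """Block-weighted Spearman rho between phenotypes and frailty index.

    Generates a large single-sex cohort under the default effect profile
    (about ``n_per_block`` participants in each of the 8 age x CMV blocks)
    and measures the weighted per-block rank correlation of each requested
    phenotype with the frailty index.
    """
    n = 8 * n_per_block
    spec = CohortSpec(
        n_men=n if sex == "M" else 0,
        n_women=n if sex == "F" else 0,
        missing_frailty={"M": 0, "F": 0},
        seed=_spawn_seed(seed, 0))
    parts = generate_cohort(spec)
    cohort = analysis_set(cohort_frame(parts))
    cm = true_count_matrix(parts)
    design = make_blocks(cohort, ("age_group", "cmv_status"))
    out = {}
    for ph in phenotypes:
        rho = weighted_rho(cm.loc[cohort.index, ph].to_numpy(),
                           cohort["frailty_index"].to_numpy(), design)
        out[ph] = {"weighted_rho": float(rho), "n": len(cohort)}
    return out


def fdr_experiment(n_studies: int = 100, n: int = 150, n_blocks: int = 8,
                   n_null: int = 30, n_nonnull: int = 7,
                   effect_rho: float = 0.3, n_perm: int = 2000,
                   q: float = 0.15, seed: int = 0) -> dict[str, float]:
    """Empirical FDR of blocked permutation tests + BH step-up.

    Each simulated study has ``n_null + n_nonnull`` phenotypes measured on
    ``n`` participants split over ``n_blocks`` blocks; non-null phenotypes
    have within-block Spearman correlation ``effect_rho`` with the outcome
    through a Gaussian copula.  The empirical FDR is the mean over studies
    of (false rejections) / max(1, rejections).
    """
    rng = np.random.default_rng(_spawn_seed(seed, 1))
    r = 2.0 * math.sin(math.pi * effect_rho / 6.0)
    fdps, powers = [], []
    for s in range(n_studies):
        blocks = np.repeat(np.arange(n_blocks), -(-n // n_blocks))[:n]
        y = rng.standard_normal(n)
        rejected = 0
        false_rejected = 0
        p_values = []
        is_null = [True] * n_null + [False] * n_nonnull
        for k, null in enumerate(is_null):
            eps = rng.standard_normal(n)
            x = eps if null else r * y + math.sqrt(1 - r * r) * eps
            res = blocked_permutation_test(
                x, y, blocks.astype(str), "weighted_rho",
                n_perm=n_perm, seed=_spawn_seed(seed, 1, s, k))
            p_values.append(res.p_value)
        reject, _, _ = bh_adjust(p_values, q=q)
        rejected = int(reject.sum())
        false_rejected = int(reject[:n_null].sum())
        fdps.append(false_rejected / max(1, rejected))
        powers.append(reject[n_null:].mean())
    fdps = np.asarray(fdps)
    return {
        "empirical_fdr": float(fdps.mean()),
        "fdr_se": float(fdps.std(ddof=1) / np.sqrt(n_studies)),
        "mean_power": float(np.mean(powers)),
        "n_studies": n_studies,
    }


def cmv_importance_experiment(n_seeds: int = 20, n_trees: int = 1000,
                              seed: int = 0) -> dict[str, float]:
    """%IncMSE of CMV serostatus when CMV has no direct frailty effect.

    Default cohorts assign CMV status independently of the latent health
    score, so CMV carries no direct frailty signal; its permutation
    importance should stay near zero.  Returns the mean importance per sex
    over ``n_seeds`` replicate cohorts.
    """
    imps: dict[str, list[float]] = {"M": [], "F": []}
    for k in range(n_seeds):
        parts = generate_cohort(CohortSpec(seed=_spawn_seed(seed, 2, k)))
        cohort = cohort_frame(parts)
        cm = true_count_matrix(parts)
        for sex in ("M", "F"):
            report, _, _ = fit_frailty_forest(
                cm, cohort, sex, n_trees=n_trees,
                seed=_spawn_seed(seed, 2, k, ord(sex)),
                importance_predictors=["cmv_seropositive"],
                importance_repeats=3)
            imps[sex].append(
                float(report.importance.loc["cmv_seropositive",
                                            "pct_inc_mse"]))
    return {f"mean_pct_inc_mse_{sex}": float(np.mean(v))
            for sex, v in imps.items()} | {"n_seeds": n_seeds}


def forest_structure_experiment(n_seeds: int = 10, n_trees: int = 500,
                                seed: int = 0) -> dict[str, float]:
    """Importance ranking and explained variance on default cohorts.

    Measures, over replicate cohorts, how often neutrophils top the female
    importance ranking and the mean out-of-bag explained variance (PEV)
    per sex.
    """
    pev = {"M": [], "F": []}
    neut_first = 0
    for k in range(n_seeds):
        parts = generate_cohort(CohortSpec(seed=_spawn_seed(seed, 3, k)))
        cohort = cohort_frame(parts)
        cm = true_count_matrix(parts)
        for sex in ("M", "F"):
            full = sex == "F"
            report, _, _ = fit_frailty_forest(
                cm, cohort, sex, n_trees=n_trees,
                seed=_spawn_seed(seed, 3, k, ord(sex)),
                compute_importance=full, importance_repeats=3)
            pev[sex].append(report.pev)
            if full:
                ranked = rank_importance(report.importance)
                neut_first += int(ranked.index[0] == "neutrophils")
    return {
        "mean_pev_f": float(np.mean(pev["F"])),
        "mean_pev_m": float(np.mean(pev["M"])),
        "neutrophils_first_fraction": neut_first / n_seeds,
        "n_seeds": n_seeds,
    }
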