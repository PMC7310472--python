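"""Blocked (stratified) permutation association tests.

Associations between each leukocyte subpopulation and sex / CMV serostatus /
frailty are tested nonparametrically with permutations restricted to blocks
(age group, optionally crossed with CMV serostatus), which adjusts for those
factors without modeling them.  Two statistics are available:

* ``wmw`` — a van Elteren-style blocked Wilcoxon-Mann-Whitney statistic:
  the within-block centered rank sum of one group, scaled by the block's
  rank-sum standard deviation and summed over blocks;
* ``weighted_rho`` — the block-size-weighted average of within-block
  Spearman rank correlations.

P-values are two-sided Monte-Carlo estimates with the add-one correction
p = (1 + #{|T*| >= |T|}) / (n_perm + 1), which is valid (never
anti-conservative in expectation) for any number of permutations.
Benjamini-Hochberg step-up control is applied separately per association
study family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .frailty import analysis_set
from .phenotypes import subpopulation_names

log = logging.getLogger(__name__)

MIN_BLOCK = 3  # blocks with fewer pairs carry no rank information


@dataclass
class BlockDesign:
    """Partition of the analysis set into confounder strata."""

    factors: tuple[str, ...]
    labels: pd.Series  # block label per participant

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def indices(self) -> dict[str, np.ndarray]:
        pos = {}
        arr = self.labels.to_numpy()
        for b in pd.unique(arr):
            pos[b] = np.flatnonzero(arr == b)
        return pos


def make_blocks(cohort: pd.DataFrame,
                factors: tuple[str, ...] = ("age_group", "cmv_status")
                ) -> BlockDesign:
    """Cross-classify participants by the blocking factors.

    ``age_group`` is taken from the cohort table if present, otherwise
    computed as cohort age quartiles (four age groups).
    """
    parts = []
    for f in factors:
        if f == "age_group" and f not in cohort.columns:
            edges = np.quantile(cohort["age"], [0.25, 0.5, 0.75])
            grp = 1 + np.searchsorted(edges, cohort["age"].to_numpy(),
                                      side="left")
            parts.append(pd.Series(grp, index=cohort.index).astype(str))
        else:
            parts.append(cohort[f].astype(str))
    labels = parts[0]
    for p in parts[1:]:
        labels = labels + "|" + p
    return BlockDesign(factors=tuple(factors), labels=labels)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _normalized_ranks(v: np.ndarray) -> np.ndarray | None:
    """Centered, unit-norm midranks; None if constant."""
    r = stats.rankdata(v)
    r = r - r.mean()
    norm = np.sqrt((r ** 2).sum())
    if norm == 0:
        return None
    return r / norm


def weighted_rho(x, y, blocks: BlockDesign | pd.Series | np.ndarray,
                 weights: dict | None = None,
                 min_block: int = MIN_BLOCK) -> float:
    """Block-size-weighted average of within-block Spearman correlations.

    Blocks with fewer than ``min_block`` pairs, or with a constant variable,
    are dropped (logged).  Returns NaN if no block contributes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = blocks.labels.to_numpy() if isinstance(blocks, BlockDesign) \
        else np.asarray(blocks)
    num = den = 0.0
    used = 0
    for b in pd.unique(labels):
        idx = np.flatnonzero(labels == b)
        if idx.size < min_block:
            log.debug("block %r dropped (n=%d < %d)", b, idx.size, min_block)
            continue
        rx = _normalized_ranks(x[idx])
        ry = _normalized_ranks(y[idx])
        if rx is None or ry is None:
            log.debug("block %r dropped (constant variable)", b)
            continue
        w = idx.size if weights is None else weights[b]
        num += w * float(rx @ ry)
        den += w
        used += 1
    if used == 0:
        warnings.warn("no block large enough for a rank correlation",
                      stacklevel=2)
        return float("nan")
    return num / den


@dataclass
class AssociationResult:
    phenotype: str
    test: str                     # "wmw" or "spearman"
    statistic: float
    weighted_rho: float | None
    p_value: float
    n_perm: int
    mc_se: float
    n: int
    n_blocks_used: int
    bh_reject: bool | None = None


def blocked_permutation_test(x, y_or_group,
                             blocks: BlockDesign | pd.Series | np.ndarray,
                             statistic: str = "weighted_rho",
                             n_perm: int = 10_000,
                             seed: int | None = 0,
                             phenotype: str = "") -> AssociationResult:
    """Two-sided within-block permutation test.

    ``statistic='weighted_rho'`` treats ``y_or_group`` as a numeric
    covariate (Spearman machinery); ``statistic='wmw'`` treats it as a
    two-level group factor (blocked rank-sum machinery).  ``y_or_group``
    is permuted independently within each block.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if statistic not in ("weighted_rho", "wmw"):
        raise ValueError(f"unknown statistic {statistic!r}")
    x = np.asarray(x, dtype=float)
    labels = blocks.labels.to_numpy() if isinstance(blocks, BlockDesign) \
        else np.asarray(blocks)
    rng = np.random.default_rng(seed)

    obs_terms = []     # per-block observed contribution
    perm_terms = []    # per-block (n_perm,) permuted contributions
    weights = []
    if statistic == "weighted_rho":
        y = np.asarray(y_or_group, dtype=float)
        for b in pd.unique(labels):
            idx = np.flatnonzero(labels == b)
            if idx.size < MIN_BLOCK:
                continue
            rx = _normalized_ranks(x[idx])
            ry = _normalized_ranks(y[idx])
            if rx is None or ry is None:
                continue
            perm = rng.permuted(
                np.broadcast_to(ry, (n_perm, idx.size)).copy(), axis=1)
            obs_terms.append(idx.size * float(rx @ ry))
            perm_terms.append(idx.size * (perm @ rx))
            weights.append(idx.size)
        test_name = "spearman"
        denom = float(sum(weights)) if weights else 1.0
    else:
        groups = np.asarray(y_or_group)
        lv = pd.unique(groups[~pd.isna(groups)])
        if lv.size != 2:
            raise ValueError(f"wmw needs exactly two groups, got {lv}")
        g1 = lv[0]
        for b in pd.unique(labels):
            idx = np.flatnonzero(labels == b)
            m = (groups[idx] == g1)
            n1, n2 = int(m.sum()), int((~m).sum())
            if n1 == 0 or n2 == 0 or idx.size < MIN_BLOCK:
                continue
            r = stats.rankdata(x[idx])
            rc = r - r.mean()
            var = n1 * n2 / (idx.size * (idx.size - 1)) * float((rc ** 2).sum())
            if var == 0:
                continue
            sd = np.sqrt(var)
            obs_terms.append(float(rc[m].sum()) / sd)
            perm = rng.permuted(
                np.broadcast_to(rc, (n_perm, idx.size)).copy(), axis=1)
            perm_terms.append((perm @ m.astype(float)) / sd)
        test_name = "wmw"
        denom = 1.0

    n_used = len(obs_terms)
    n_total = int(sum(weights)) if statistic == "weighted_rho" else len(x)
    if n_used == 0:
        warnings.warn("statistic undefined (constant data or all blocks "
                      "too small); p = 1", stacklevel=2)
        return AssociationResult(phenotype, test_name, float("nan"),
                                 float("nan") if test_name == "spearman"
                                 else None,
                                 1.0, n_perm, 0.0, len(x), 0)

    t_obs = sum(obs_terms) / denom
    t_perm = np.sum(perm_terms, axis=0) / denom
    exceed = int(np.sum(np.abs(t_perm) >= np.abs(t_obs) - 1e-12))
    p = (1 + exceed) / (n_perm + 1)
    mc_se = float(np.sqrt(p * (1 - p) / n_perm))
    rho_w = t_obs if test_name == "spearman" else None
    return AssociationResult(phenotype, test_name, float(t_obs), rho_w,
                             float(p), n_perm, mc_se, n_total, n_used)


def bh_adjust(p_values, q: float = 0.15):
    """Benjamini-Hochberg step-up at FDR level q.

    Returns ``(reject, p_adjusted, k)`` where k is the step-up threshold
    index (number of rejections).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0), 0
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj, int(reject.sum())


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------

STUDIES = ("sex", "cmv_by_sex", "frailty_by_sex")


def run_association_study(cm: pd.DataFrame, cohort: pd.DataFrame,
                          study: str, scale: str = "absolute",
                          n_perm: int = 10_000, fdr_q: float = 0.15,
                          seed: int | None = 0,
                          phenotypes: list[str] | None = None
                          ) -> pd.DataFrame:
    """Run one association study over every phenotype column.

    ``cm`` is the participant x phenotype matrix on the requested scale
    (absolute cells/µL or percentage of parent — pass the proportions
    matrix with ``scale='proportion'``; the machinery is identical).
    Sex and frailty studies block on age group x CMV status; CMV studies
    block on age group only.  Frailty and CMV studies run separately per
    sex; BH correction is applied separately per (study, stratum) family.
    """
    if study not in STUDIES:
        raise ValueError(f"unknown study {study!r}; one of {STUDIES}")
    cohort = cohort.loc[cohort.index.intersection(cm.index)]
    phenos = [c for c in (phenotypes or subpopulation_names())]
    missing_cols = [c for c in phenos if c not in cm.columns]
    if missing_cols:
        warnings.warn(f"phenotypes missing from matrix, skipped: "
                      f"{missing_cols}", stacklevel=2)
        phenos = [c for c in phenos if c in cm.columns]

    if study == "sex":
        strata = {"all": cohort}
        factors = ("age_group", "cmv_status")
        target_col, stat = "sex", "wmw"
    elif study == "cmv_by_sex":
        strata = {s: cohort[cohort["sex"] == s] for s in ("M", "F")}
        factors = ("age_group",)
        target_col, stat = "cmv_status", "wmw"
    else:  # frailty_by_sex
        fr = analysis_set(cohort)
        strata = {s: fr[fr["sex"] == s] for s in ("M", "F")}
        factors = ("age_group", "cmv_status")
        target_col, stat = "frailty_index", "weighted_rho"

    ss = np.random.SeedSequence(seed)
    rows = []
    for stratum_idx, (stratum, sub) in enumerate(strata.items()):
        if sub.empty:
            warnings.warn(f"stratum {stratum!r} is empty, skipped",
                          stacklevel=2)
            continue
        design = make_blocks(sub, factors)
        target = sub[target_col].to_numpy()
        results = []
        for k, ph in enumerate(phenos):
            vals = cm.loc[sub.index, ph].to_numpy(dtype=float)
            ok = ~np.isnan(vals) & ~pd.isna(target)
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(stratum_idx, k))
            res = blocked_permutation_test(
                vals[ok], target[ok], design.labels[ok].to_numpy(),
                statistic=stat, n_perm=n_perm,
                seed=child, phenotype=ph)
            results.append(res)
        reject, p_adj, _ = bh_adjust([r.p_value for r in results], q=fdr_q)
        for r, rej, pa in zip(results, reject, p_adj):
            r.bh_reject = bool(rej)
            rows.append({
                "study": study, "scale": scale, "stratum": stratum,
                "phenotype": r.phenotype, "test": r.test,
                "statistic": r.statistic,
                "weighted_rho": (float("nan") if r.weighted_rho is None
                                 else r.weighted_rho),
                "p": r.p_value, "p_bh": pa, "mc_se": r.mc_se,
                "n": r.n, "n_blocks": r.n_blocks_used, "n_perm": r.n_perm,
                "bh_reject": r.bh_reject,
            })
    return pd.DataFrame(rows)
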