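"""Synthetic cohorts and flow-cytometry event data with known ground truth.

The generator emulates the study design the analysis assumes:

* 289 participants (145 men, 144 women) aged 60-87, sampled in equal numbers
  from the healthiest 15%, intermediate 70% and frailest 15% of a latent
  health distribution;
* a 36-item deficit-accumulation frailty index obtained by probit
  thresholding of the latent health score, with age-group shifts so frailty
  rises with age;
* anti-CMV IgG titers from a two-component lognormal mixture with retained
  component labels;
* per-participant true concentrations (cells/µL) for 30 "leaf" cell
  populations whose unions form the 37 reported subpopulations; profiled
  populations are tied to the latent health score through a one-factor
  Gaussian copula so that the within-block Spearman correlation between a
  phenotype's concentration and the frailty index hits a configurable
  target (sex-specific defaults: neutrophils 0.40 in women / 0.25 in men,
  CD16- monocytes 0.24, CD16+ monocytes 0.12, CD56+ T cells -0.20 and CD4
  TemRA cells -0.13 in women);
* event-level two-tube cytometry tables: per-population event counts are
  Poisson with mean concentration x stained volume x acquisition fraction,
  channel intensities are lognormal around population-specific levels, and
  the TruCOUNT tube carries a bead population of known size.

CMV serostatus is sampled independently of the latent health score, so CMV
has no direct effect on frailty (only late-memory T-cell concentrations
shift with CMV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import TRUCOUNT, FALCON, TUBE_CHANNELS, subpopulation_names

# ---------------------------------------------------------------------------
# Leaf populations (the generative partition of leukocytes)
# ---------------------------------------------------------------------------

#: log-intensity level means on the arbitrary-unit fluorescence scale.
LEVEL_LOG_MEAN = {"neg": 0.0, "dim": 2.0, "bright": 4.0}
# 4 sigma from a level mean to the nearest cut: population overlap across a
# gate boundary is ~3e-5, so even rare populations sitting next to abundant
# ones (CD16+ monocytes vs neutrophils) are recovered within Poisson error
INTENSITY_LOG_SD = 0.25


@dataclass(frozen=True)
class LeafPopulation:
    """One generative cell population.

    base_conc is the median concentration (cells/µL) for a CMV-seronegative
    man at the cohort's central age; sex/CMV/age terms shift the log
    concentration.  ``levels`` maps channels to neg/dim/bright expression
    (channels not listed are negative).
    """

    name: str
    base_conc: float
    levels: dict[str, str]
    sex_shift_f: float = 0.0   # log shift for women
    cmv_shift: float = 0.0     # log shift for CMV-seropositives
    age_slope: float = 0.0     # log shift per year of age (centered at 73)
    log_sd: float = 0.5        # between-person lognormal spread


def _t4(levels):  # CD4 T cell trucount/falcon base signature
    out = {"SSC": "neg", "CD45": "bright", "CD3": "bright", "CD4": "bright",
           "CD38": "dim", "CD127": "bright"}
    out.update(levels)
    return out


def _t8(levels):
    out = {"SSC": "neg", "CD45": "bright", "CD3": "bright", "CD8": "bright",
           "CD38": "dim", "CD127": "bright"}
    out.update(levels)
    return out


_LYMPH = {"SSC": "neg", "CD45": "bright"}
_STAGE = {
    "early": {"CD27": "bright", "CD28": "bright"},
    "late": {"CD27": "neg", "CD28": "neg"},
    "mixed": {"CD27": "bright", "CD28": "neg"},
}


def _memory_leaves(lin, f, base_by_stage, sex_shift, cmv_late):
    """Tem/TemRA leaves in early/late/mixed differentiation stages."""
    leaves = []
    for mem, ccr7_ra in (("tem", {"CCR7": "neg", "CD45RA": "neg"}),
                         ("temra", {"CCR7": "neg", "CD45RA": "bright"})):
        for stage in ("early", "late", "mixed"):
            levels = dict(ccr7_ra)
            levels.update(_STAGE[stage])
            leaves.append(LeafPopulation(
                f"{lin}_{mem}_{stage}", base_by_stage[(mem, stage)],
                f(levels),
                sex_shift_f=sex_shift[stage],
                cmv_shift=cmv_late if stage == "late" else
                (0.2 if stage == "mixed" else 0.0),
                age_slope=0.005 if stage == "late" else 0.0))
    return leaves


def default_leaf_populations() -> list[LeafPopulation]:
    leaves = [
        LeafPopulation("neutrophil", 3500,
                       {"FSC": "bright", "SSC": "bright", "CD45": "dim",
                        "CD16": "bright"},
                       age_slope=0.002),
        LeafPopulation("mono_cd16neg", 400,
                       {"FSC": "bright", "SSC": "dim", "CD45": "dim",
                        "CD4": "dim", "HLA-DR": "bright", "CD38": "bright"},
                       sex_shift_f=-0.10, cmv_shift=-0.05, age_slope=0.002),
        LeafPopulation("mono_cd16pos", 50,
                       {"FSC": "bright", "SSC": "dim", "CD45": "dim",
                        "CD4": "dim", "CD16": "bright", "HLA-DR": "bright",
                        "CD38": "dim"},
                       age_slope=0.004),
        LeafPopulation("b_transitional", 10,
                       {**_LYMPH, "CD19": "bright", "CD38": "bright",
                        "IgD": "bright", "HLA-DR": "bright"},
                       sex_shift_f=0.15, age_slope=-0.005),
        LeafPopulation("b_naive", 120,
                       {**_LYMPH, "CD19": "bright", "CD38": "dim",
                        "IgD": "bright", "HLA-DR": "bright"},
                       sex_shift_f=0.15, age_slope=-0.005),
        LeafPopulation("b_memory", 60,
                       {**_LYMPH, "CD19": "bright", "CD38": "dim",
                        "CD27": "bright", "HLA-DR": "bright"},
                       sex_shift_f=0.15),
        LeafPopulation("nk_cd56bright_cd16neg", 30,
                       {**_LYMPH, "CD56": "bright"}),
        LeafPopulation("nk_cd56dim_cd16pos", 220,
                       {**_LYMPH, "CD56": "dim", "CD16": "bright"},
                       age_slope=0.002),
        LeafPopulation("nk_cd56dim_cd16neg", 30,
                       {**_LYMPH, "CD56": "dim"}),
        LeafPopulation("nk_cd56neg_cd16pos", 20,
                       {**_LYMPH, "CD16": "bright"},
                       cmv_shift=0.1, age_slope=0.002),
        LeafPopulation("t_cd56pos", 75,
                       {**_LYMPH, "CD3": "bright", "CD56": "bright",
                        "CD8": "dim", "CD27": "bright"},
                       sex_shift_f=-0.20, cmv_shift=0.3, age_slope=0.002),
        # --- CD4 compartment ---
        LeafPopulation("cd4_naive_conv", 185,
                       _t4({"CCR7": "bright", "CD45RA": "bright",
                            "CD27": "bright", "CD28": "bright"}),
                       sex_shift_f=0.12, age_slope=-0.008),
        LeafPopulation("naive_treg", 15,
                       _t4({"CCR7": "bright", "CD45RA": "bright",
                            "CD27": "bright", "CD28": "bright",
                            "CD25": "bright", "CD127": "neg"}),
                       sex_shift_f=0.12, age_slope=-0.005),
        LeafPopulation("mem_treg", 25,
                       _t4({"CCR7": "bright", "CD45RA": "neg",
                            "CD27": "bright", "CD28": "bright",
                            "CD25": "bright", "CD127": "neg"}),
                       sex_shift_f=0.12),
        LeafPopulation("tfh", 25,
                       _t4({"CCR7": "bright", "CD45RA": "neg",
                            "CD27": "bright", "CD28": "bright",
                            "CXCR5": "bright"}),
                       sex_shift_f=0.12, cmv_shift=0.05),
        LeafPopulation("cd4_cm_conv", 200,
                       _t4({"CCR7": "bright", "CD45RA": "neg",
                            "CD27": "bright", "CD28": "bright"}),
                       sex_shift_f=0.12),
        # --- CD8 compartment ---
        LeafPopulation("cd8_naive", 90,
                       _t8({"CCR7": "bright", "CD45RA": "bright",
                            "CD27": "bright", "CD28": "bright"}),
                       sex_shift_f=0.10, age_slope=-0.008),
        LeafPopulation("cd8_cm", 60,
                       _t8({"CCR7": "bright", "CD45RA": "neg",
                            "CD27": "bright", "CD28": "bright"})),
    ]
    leaves += _memory_leaves(
        "cd4", _t4,
        {("tem", "early"): 60, ("tem", "late"): 30, ("tem", "mixed"): 30,
         ("temra", "early"): 15, ("temra", "late"): 8, ("temra", "mixed"): 7},
        {"early": 0.10, "late": -0.10, "mixed": 0.0}, cmv_late=0.6)
    leaves += _memory_leaves(
        "cd8", _t8,
        {("tem", "early"): 40, ("tem", "late"): 50, ("tem", "mixed"): 30,
         ("temra", "early"): 40, ("temra", "late"): 60, ("temra", "mixed"): 30},
        {"early": 0.10, "late": -0.10, "mixed": 0.0}, cmv_late=0.6)
    return leaves


#: Reported subpopulations as unions of generative leaves.
PHENOTYPE_LEAVES: dict[str, list[str]] = {}


def _build_phenotype_leaves() -> dict[str, list[str]]:
    cd4 = ["cd4_naive_conv", "naive_treg", "mem_treg", "tfh", "cd4_cm_conv",
           "cd4_tem_early", "cd4_tem_late", "cd4_tem_mixed",
           "cd4_temra_early", "cd4_temra_late", "cd4_temra_mixed"]
    cd8 = ["cd8_naive", "cd8_cm",
           "cd8_tem_early", "cd8_tem_late", "cd8_tem_mixed",
           "cd8_temra_early", "cd8_temra_late", "cd8_temra_mixed"]
    b = ["b_transitional", "b_naive", "b_memory"]
    nk = ["nk_cd56bright_cd16neg", "nk_cd56dim_cd16pos",
          "nk_cd56dim_cd16neg", "nk_cd56neg_cd16pos"]
    m = {
        "neutrophils": ["neutrophil"],
        "monocytes": ["mono_cd16neg", "mono_cd16pos"],
        "cd16neg_monocytes": ["mono_cd16neg"],
        "cd16pos_monocytes": ["mono_cd16pos"],
        "lymphocytes": cd4 + cd8 + b + nk + ["t_cd56pos"],
        "t_cells": cd4 + cd8 + ["t_cd56pos"],
        "b_cells": b,
        "nk_cells": nk,
        "cd56pos_t_cells": ["t_cd56pos"],
        "cd4_t_cells": cd4,
        "cd8_t_cells": cd8,
        "transitional_b_cells": ["b_transitional"],
        "naive_b_cells": ["b_naive"],
        "memory_b_cells": ["b_memory"],
        "tregs": ["naive_treg", "mem_treg"],
        "naive_tregs": ["naive_treg"],
        "tfh": ["tfh"],
        "cd4_naive": ["cd4_naive_conv", "naive_treg"],
        "cd4_cm": ["cd4_cm_conv", "mem_treg", "tfh"],
        "cd8_naive": ["cd8_naive"],
        "cd8_cm": ["cd8_cm"],
    }
    for nkname in nk:
        m[nkname] = [nkname]
    for lin, leaves in (("cd4", cd4), ("cd8", cd8)):
        for mem in ("tem", "temra"):
            m[f"{lin}_{mem}"] = [f"{lin}_{mem}_{s}"
                                 for s in ("early", "late", "mixed")]
            for s in ("early", "late"):
                m[f"{lin}_{mem}_{s}"] = [f"{lin}_{mem}_{s}"]
    return m


PHENOTYPE_LEAVES = _build_phenotype_leaves()


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CmvMixture:
    """Two-component lognormal IgG titer model (log-scale parameters)."""

    mu_neg: float = 0.0
    sigma_neg: float = 0.5
    mu_pos: float = 3.0
    sigma_pos: float = 0.6
    weight_neg: float = 0.45

    def __post_init__(self):
        if not 0 <= self.weight_neg <= 1:
            raise ValueError("weight_neg must lie in [0, 1]")
        if self.sigma_neg <= 0 or self.sigma_pos <= 0:
            raise ValueError("component sigmas must be positive")


#: Within-block Spearman targets between phenotype concentration and the
#: frailty index, per sex.
DEFAULT_EFFECT_PROFILE: dict[str, dict[str, float]] = {
    "M": {"neutrophils": 0.25},
    "F": {"neutrophils": 0.40, "cd16neg_monocytes": 0.24,
          "cd16pos_monocytes": 0.12, "cd56pos_t_cells": -0.20,
          "cd4_temra": -0.13},
}


@dataclass(frozen=True)
class CohortSpec:
    n_men: int = 145
    n_women: int = 144
    age_range: tuple[int, int] = (60, 87)
    strata_fractions: tuple[float, float, float] = (0.15, 0.70, 0.15)
    missing_frailty: dict[str, int] = field(
        default_factory=lambda: {"M": 5, "F": 7})
    effect_profile: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(p)
                                 for s, p in DEFAULT_EFFECT_PROFILE.items()})
    cmv_mixture: CmvMixture = field(default_factory=CmvMixture)
    n_deficits: int = 36
    deficit_prevalence_range: tuple[float, float] = (0.02, 0.95)
    age_group_health_shift: tuple[float, ...] = (-0.25, -0.08, 0.08, 0.25)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.strata_fractions) - 1.0) > 1e-9:
            raise ValueError("strata_fractions must sum to 1")
        if min(self.strata_fractions) <= 0:
            raise ValueError("strata_fractions must be positive")
        if self.n_men < 0 or self.n_women < 0:
            raise ValueError("cohort sizes must be non-negative")
        for sex, profile in self.effect_profile.items():
            for pheno, rho in profile.items():
                if not abs(rho) < 1:
                    raise ValueError(
                        f"unattainable effect target for {pheno!r} ({sex}): "
                        f"|rho| must be < 1, got {rho}")

    @property
    def size(self) -> int:
        return self.n_men + self.n_women


@dataclass(frozen=True)
class AcquisitionSettings:
    """Instrument-side defaults for event generation."""

    sample_volume: float = 50.0        # µL of blood per tube
    beads_per_tube: float = 50000.0
    acquisition_fraction: float = 1 / 3  # fraction of the tube acquired
    debris_conc: float = 200.0         # CD45- junk events, cells/µL


@dataclass
class SyntheticParticipant:
    id: str
    sex: str                      # "M" or "F"
    age: int
    age_group: int                # 1..4 (cohort age quartiles)
    stratum: str                  # healthiest / intermediate / frailest
    cmv_igg: float
    cmv_status: str               # ground-truth component label
    deficits: np.ndarray          # 36 values in [0,1] (NaN if unassessed)
    frailty_index: float
    blood_draw_date: date
    frailty_assessment_date: date | None
    latent_health: float          # ground truth, not observable
    leaf_concentrations: dict[str, float]
    concentrations: dict[str, float]  # true cells/µL per subpopulation


# ---------------------------------------------------------------------------
# Copula calibration
# ---------------------------------------------------------------------------

def latent_correlation(target_rho: float) -> float:
    """Pearson correlation of the Gaussian copula giving a Spearman target.

    For a bivariate Gaussian, rho_S = (6/pi) * arcsin(r/2); inverted here.
    """
    if not abs(target_rho) < 1:
        raise ValueError(f"|target rho| must be < 1, got {target_rho}")
    return 2.0 * math.sin(math.pi * target_rho / 6.0)


def _leaf_targets(profile: dict[str, float],
                  leaf_names: set[str]) -> dict[str, tuple[float, str]]:
    """Resolve a phenotype-level effect profile to per-leaf Spearman targets.

    Aggregate phenotypes spread their target over member leaves; explicit
    leaf-level (single-leaf) entries take precedence.  Leaves of one profile
    entry share the entry key: the generator gives them a common
    idiosyncratic draw so the aggregate phenotype — not only its parts —
    attains the target rank correlation.
    """
    items = []
    for key, rho in profile.items():
        if key in PHENOTYPE_LEAVES:
            leaves = PHENOTYPE_LEAVES[key]
        elif key in leaf_names:
            leaves = [key]
        else:
            raise KeyError(f"effect profile names unknown phenotype {key!r}")
        items.append((leaves, rho, key))
    targets: dict[str, tuple[float, str]] = {}
    # broad entries first so specific (fewer-leaf) entries override them
    for leaves, rho, key in sorted(items, key=lambda t: -len(t[0])):
        for leaf in leaves:
            targets[leaf] = (rho, key)
    return targets


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def sample_cmv_titers(n: int, mixture: CmvMixture | None = None,
                      seed: int | None = 0):
    """Draw IgG titers from the two-component lognormal mixture.

    Returns ``(titers, labels)`` with ground-truth component labels
    ("negative" / "positive") for recovery tests.
    """
    mixture = CmvMixture() if mixture is None else mixture
    rng = np.random.default_rng(seed)
    is_neg = rng.random(n) < mixture.weight_neg
    logt = np.where(is_neg,
                    rng.normal(mixture.mu_neg, mixture.sigma_neg, n),
                    rng.normal(mixture.mu_pos, mixture.sigma_pos, n))
    labels = np.where(is_neg, "negative", "positive")
    return np.exp(logt), labels


def _strata_counts(n: int) -> dict[str, int]:
    base = n // 3
    counts = {"healthiest": base, "intermediate": base, "frailest": base}
    counts["intermediate"] += n - 3 * base
    return counts


def generate_cohort(spec: CohortSpec | None = None,
                    leaves: list[LeafPopulation] | None = None
                    ) -> list[SyntheticParticipant]:
    """Generate the full synthetic cohort (deterministic given spec.seed)."""
    spec = CohortSpec() if spec is None else spec
    leaves = default_leaf_populations() if leaves is None else leaves
    leaf_names = {lf.name for lf in leaves}
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    f1, f2, f3 = spec.strata_fractions
    stratum_bands = {"healthiest": (0.0, f1),
                     "intermediate": (f1, f1 + f2),
                     "frailest": (f1 + f2, 1.0)}
    stratum_index = {"healthiest": 0, "intermediate": 1, "frailest": 2}

    lo, hi = spec.age_range
    participants: list[SyntheticParticipant] = []
    plan: list[tuple[str, int]] = [("M", spec.n_men), ("F", spec.n_women)]

    # ages drawn for everyone first so age-group quartiles are cohort-wide
    total = spec.size
    ages = rng.integers(lo, hi + 1, size=total)
    edges = np.quantile(ages, [0.25, 0.5, 0.75]) if total else np.array([])
    age_groups = (1 + np.searchsorted(edges, ages, side="left")
                  if total else np.array([], dtype=int))

    # deficit thresholds: item prevalences log-spaced over the configured
    # range (many rare items, a few very common ones), so that nearly every
    # participant carries some deficits and the index has few exact ties
    p_lo, p_hi = spec.deficit_prevalence_range
    prevalences = np.geomspace(p_lo, p_hi, spec.n_deficits)
    tau = stats.norm.ppf(1.0 - prevalences)

    idx = 0
    for sex, n_sex in plan:
        titers, cmv_labels = sample_cmv_titers(
            n_sex, spec.cmv_mixture, seed=rng.integers(2**31))
        # equal numbers per frailty stratum (the subcohort design)
        strata = []
        for name, cnt in _strata_counts(n_sex).items():
            strata += [name] * cnt
        strata = list(rng.permutation(np.array(strata)))

        # latent health: inverse-CDF sample within each stratum's band
        v = rng.random(n_sex)  # position within the stratum band
        band_lo = np.array([stratum_bands[s][0] for s in strata])
        band_w = np.array([stratum_bands[s][1] - stratum_bands[s][0]
                           for s in strata])
        u_pop = band_lo + v * band_w          # population quantile of health
        health = stats.norm.ppf(u_pop)        # latent health score H
        # rank-normalized score under the stratified sampling design: the
        # copula is applied to this score so Spearman targets hold in the
        # selected sample, not just the source population
        s_idx = np.array([stratum_index[s] for s in strata])
        g = stats.norm.ppf((s_idx + v) / 3.0)

        targets = _leaf_targets(spec.effect_profile.get(sex, {}), leaf_names)

        # per-leaf latent draws; leaves of one profile entry share their
        # idiosyncratic draw so aggregates also hit the target
        eps = rng.standard_normal((n_sex, len(leaves)))
        entry_eps = {key: rng.standard_normal(n_sex)
                     for key in sorted({k for _, k in targets.values()})}
        conc = np.empty_like(eps)
        shifts = np.asarray(spec.age_group_health_shift)
        sex_ages = ages[idx:idx + n_sex]
        sex_groups = age_groups[idx:idx + n_sex]
        for j, leaf in enumerate(leaves):
            rho, key = targets.get(leaf.name, (0.0, None))
            r = latent_correlation(rho)
            e = eps[:, j] if key is None else entry_eps[key]
            z = r * g + math.sqrt(1.0 - r * r) * e
            logc = (math.log(leaf.base_conc)
                    + (leaf.sex_shift_f if sex == "F" else 0.0)
                    + leaf.cmv_shift * (cmv_labels == "positive")
                    + leaf.age_slope * (sex_ages - 73)
                    + leaf.log_sd * z)
            conc[:, j] = np.exp(logc)

        # deficits: probit thresholding of the age-shifted health score
        h_eff = health + shifts[sex_groups - 1]
        deficits = (h_eff[:, None] > tau[None, :]).astype(float)

        # missing frailty assessments
        n_missing = spec.missing_frailty.get(sex, 0)
        missing = set(rng.choice(n_sex, size=n_missing, replace=False))

        # dates: draws Aug 2016 - Mar 2017; assessment 2 d - 3.2 y later
        draw0 = date(2016, 8, 1)
        draw_offsets = rng.integers(0, 213, size=n_sex)
        gap_days = rng.integers(2, 1168, size=n_sex)

        for i in range(n_sex):
            d = deficits[i].copy()
            if i in missing:
                d[:] = np.nan
                fi = float("nan")
                assess = None
            else:
                fi = float(d.mean())
                assess = (draw0 + timedelta(days=int(draw_offsets[i]))
                          + timedelta(days=int(gap_days[i])))
            leaf_conc = {leaf.name: float(conc[i, j])
                         for j, leaf in enumerate(leaves)}
            pheno_conc = {ph: float(sum(leaf_conc[x] for x in members))
                          for ph, members in PHENOTYPE_LEAVES.items()}
            participants.append(SyntheticParticipant(
                id=f"{sex}{i + 1:04d}",
                sex=sex,
                age=int(sex_ages[i]),
                age_group=int(sex_groups[i]),
                stratum=strata[i],
                cmv_igg=float(titers[i]),
                cmv_status=str(cmv_labels[i]),
                deficits=d,
                frailty_index=fi,
                blood_draw_date=draw0 + timedelta(days=int(draw_offsets[i])),
                frailty_assessment_date=assess,
                latent_health=float(health[i]),
                leaf_concentrations=leaf_conc,
                concentrations=pheno_conc,
            ))
        idx += n_sex
    return participants


def cohort_frame(participants: list[SyntheticParticipant]) -> pd.DataFrame:
    """Cohort table: demographics, CMV, deficits, frailty index, dates."""
    rows = []
    for p in participants:
        row = {
            "participant_id": p.id, "sex": p.sex, "age": p.age,
            "age_group": p.age_group, "stratum": p.stratum,
            "cmv_igg": p.cmv_igg, "cmv_status": p.cmv_status,
            "frailty_index": p.frailty_index,
            "blood_draw_date": p.blood_draw_date,
            "frailty_assessment_date": p.frailty_assessment_date,
        }
        for k, v in enumerate(p.deficits, start=1):
            row[f"deficit_{k:02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def true_count_matrix(participants: list[SyntheticParticipant]
                      ) -> pd.DataFrame:
    """Ground-truth participants x phenotypes concentration matrix."""
    cm = pd.DataFrame({p.id: p.concentrations for p in participants}).T
    cm.index.name = "participant_id"
    return cm.reindex(columns=subpopulation_names())


# ---------------------------------------------------------------------------
# Event-level generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """Per-tube intensity model of one leaf population."""

    name: str
    levels: dict[str, str]

    def log_means(self, channels: list[str]) -> np.ndarray:
        return np.array([LEVEL_LOG_MEAN[self.levels.get(c, "neg")]
                         for c in channels])


def default_population_models(
        leaves: list[LeafPopulation] | None = None) -> list[PopulationModel]:
    leaves = default_leaf_populations() if leaves is None else leaves
    return [PopulationModel(lf.name, dict(lf.levels)) for lf in leaves]


_BEAD_LEVELS = {c: "bright" for c in TUBE_CHANNELS[TRUCOUNT]}
_BEAD_LEVELS.update({"CD45": "neg", "FSC": "neg", "SSC": "neg"})


def generate_tube_events(participant: SyntheticParticipant, tube: str,
                         models: list[PopulationModel] | None = None,
                         seed: int | None = 0,
                         acquisition: AcquisitionSettings | None = None
                         ) -> pd.DataFrame:
    """Simulate one tube's event table for one participant.

    Event counts per population are Poisson with mean concentration x
    stained volume x acquisition fraction; the TruCOUNT tube additionally
    contains bead events (Poisson with mean beads_per_tube x acquisition
    fraction) and both tubes contain CD45- debris.  Channel intensities are
    lognormal around each population's level means.  The returned frame
    carries ``attrs``: tube, participant_id, beads_per_tube, sample_volume.
    """
    if tube not in (TRUCOUNT, FALCON):
        raise ValueError(f"unknown tube {tube!r}")
    acq = AcquisitionSettings() if acquisition is None else acquisition
    if acq.sample_volume <= 0:
        raise ValueError("acquired volume must be positive")
    if not 0 < acq.acquisition_fraction <= 1:
        raise ValueError("acquisition fraction must lie in (0, 1]")
    models = default_population_models() if models is None else models
    missing = set(participant.leaf_concentrations) - {m.name for m in models}
    if missing:
        raise ValueError(f"no population model for leaves {sorted(missing)}")

    channels = TUBE_CHANNELS[tube]
    rng = np.random.default_rng(seed)
    scale = acq.sample_volume * acq.acquisition_fraction

    blocks = []
    for model in models:
        c = participant.leaf_concentrations.get(model.name)
        if c is None:
            continue
        n = rng.poisson(c * scale)
        if n == 0:
            continue
        mu = model.log_means(channels)
        blocks.append(np.exp(mu + INTENSITY_LOG_SD
                             * rng.standard_normal((n, len(channels)))))
    # debris: all channels negative
    n_debris = rng.poisson(acq.debris_conc * scale)
    if n_debris:
        blocks.append(np.exp(INTENSITY_LOG_SD
                             * rng.standard_normal((n_debris, len(channels)))))
    if tube == TRUCOUNT:
        n_beads = rng.poisson(acq.beads_per_tube * acq.acquisition_fraction)
        if n_beads:
            bead_model = PopulationModel("beads", _BEAD_LEVELS)
            mu = bead_model.log_means(channels)
            blocks.append(np.exp(mu + INTENSITY_LOG_SD
                                 * rng.standard_normal((n_beads,
                                                        len(channels)))))
    if blocks:
        data = np.vstack(blocks)
        data = data[rng.permutation(len(data))]
    else:
        data = np.empty((0, len(channels)))
    events = pd.DataFrame(data, columns=channels)
    events.attrs.update({
        "tube": tube,
        "participant_id": participant.id,
        "beads_per_tube": acq.beads_per_tube,
        "sample_volume": acq.sample_volume,
    })
    return events
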