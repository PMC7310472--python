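"""Configuration and the one-command end-to-end pipeline run.

``run_all`` executes simulate -> gate -> count -> frailty -> serostatus ->
associations -> prediction from a single :class:`RunConfig` and writes all
tables (with a metadata sidecar) to the output directory.  A single master
seed is expanded into per-stage seeds through ``numpy.random.SeedSequence``
spawn keys, so each stage is independently reproducible and a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import run_association_study
from .frailty import sqrt_transform
from .gating import classify_events
from .phenotypes import FALCON, TRUCOUNT, subpopulation_names
from .prediction import fit_frailty_forest, partial_dependence
from .quantify import (
    TrucountCalibration,
    apply_exclusions,
    build_count_matrix,
    compute_proportions,
    participant_concentrations,
)
from .serology import (
    classify_serostatus,
    fit_two_component_mixture,
    seropositivity_cutoff,
)
from .synthetic_data import (
    AcquisitionSettings,
    CohortSpec,
    cohort_frame,
    generate_cohort,
    generate_tube_events,
    true_count_matrix,
)

log = logging.getLogger(__name__)

# stage names -> SeedSequence spawn keys
_STAGE_KEYS = {"cohort": 0, "events": 1, "serology": 2,
               "association": 3, "forest": 4}


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    n_men: int = 145
    n_women: int = 144
    simulate_events: bool = True        # False: use generator ground truth
    acquisition_fraction: float = 1 / 3
    n_perm: int = 2000
    fdr_q: float = 0.15
    n_trees: int = 500
    pdp_predictors: tuple[str, ...] = ("neutrophils", "cd16neg_monocytes")
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if not 0 < self.acquisition_fraction <= 1:
            raise ValueError("acquisition_fraction must lie in (0, 1]")
        unknown = [p for p in self.pdp_predictors
                   if p not in subpopulation_names()]
        if unknown:
            raise ValueError(f"unknown pdp predictors: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str, extra: int = 0) -> np.random.SeedSequence:
    """Documented seed-derivation rule: spawn key = (stage index, extra)."""
    return np.random.SeedSequence(
        entropy=master_seed, spawn_key=(_STAGE_KEYS[stage], extra))


def run_all(config: RunConfig) -> dict[str, object]:
    """Execute the full pipeline; returns the key result frames."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}

    def _stage(name):
        log.info("stage: %s", name)

    # 1. simulate ----------------------------------------------------------
    _stage("simulate")
    cohort_seed = int(stage_seed(config.seed, "cohort").generate_state(1)[0]
                      % 2**31)
    spec = CohortSpec(n_men=config.n_men, n_women=config.n_women,
                      seed=cohort_seed)
    participants = generate_cohort(spec)
    cohort = cohort_frame(participants)

    # 2-3. gate + count ----------------------------------------------------
    _stage("gate/count")
    acq = AcquisitionSettings(acquisition_fraction=config.acquisition_fraction)
    if config.simulate_events:
        per_part = {}
        for i, p in enumerate(participants):
            tru = generate_tube_events(
                p, TRUCOUNT, seed=stage_seed(config.seed, "events", 2 * i),
                acquisition=acq)
            fal = generate_tube_events(
                p, FALCON, seed=stage_seed(config.seed, "events", 2 * i + 1),
                acquisition=acq)
            tru_res = classify_events(tru)
            fal_res = classify_events(fal)
            cal = TrucountCalibration(acq.beads_per_tube,
                                      tru_res.bead_count, acq.sample_volume)
            per_part[p.id] = participant_concentrations(tru_res, fal_res, cal)
        cm = build_count_matrix(per_part)
    else:
        cm = true_count_matrix(participants)
    if config.exclusions:
        cm = apply_exclusions(cm, config.exclusions)
    props = compute_proportions(cm)

    # 4. frailty -----------------------------------------------------------
    _stage("frailty")
    frailty = cohort[["sex", "frailty_index"]].copy()
    frailty["sqrt_frailty_index"] = sqrt_transform(cohort["frailty_index"])

    # 5. serostatus --------------------------------------------------------
    _stage("serostatus")
    sero_seed = int(stage_seed(config.seed, "serology").generate_state(1)[0]
                    % 2**31)
    fit = fit_two_component_mixture(np.log(cohort["cmv_igg"].to_numpy()),
                                    seed=sero_seed)
    cutoff = seropositivity_cutoff(fit)
    fitted_status = classify_serostatus(cohort["cmv_igg"].to_numpy(), cutoff)
    analysis_cohort = cohort.copy()
    analysis_cohort["cmv_status_true"] = cohort["cmv_status"]
    analysis_cohort["cmv_status"] = fitted_status

    # 6. associations ------------------------------------------------------
    _stage("associations")
    assoc_frames = []
    for si, study in enumerate(("sex", "cmv_by_sex", "frailty_by_sex")):
        for sci, (scale, matrix) in enumerate(
                (("absolute", cm), ("proportion", props))):
            assoc_seed = int(stage_seed(
                config.seed, "association",
                10 * si + sci).generate_state(1)[0] % 2**31)
            assoc_frames.append(run_association_study(
                matrix, analysis_cohort, study, scale=scale,
                n_perm=config.n_perm, fdr_q=config.fdr_q, seed=assoc_seed,
                phenotypes=list(matrix.columns)))
    associations = pd.concat(assoc_frames, ignore_index=True)

    # 7. prediction --------------------------------------------------------
    _stage("prediction")
    forest_rows, pdp_frames = [], []
    for si, sex in enumerate(("M", "F")):
        forest_seed = int(stage_seed(config.seed, "forest",
                                     si).generate_state(1)[0] % 2**31)
        report, forest, X = fit_frailty_forest(
            cm, analysis_cohort, sex, n_trees=config.n_trees,
            seed=forest_seed, importance_repeats=3)
        imp = report.importance.copy()
        imp.insert(0, "sex", sex)
        imp.insert(1, "predictor", imp.index)
        forest_rows.append((report, imp))
        for pred in config.pdp_predictors:
            curve = partial_dependence(forest, X, pred)
            pdp_frames.append(pd.DataFrame({
                "sex": sex, "predictor": pred, "grid": curve.grid[0],
                "sqrt_frailty": curve.values}))

    # write ----------------------------------------------------------------
    _stage("write")
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "package_version": __version__,
            "config": dataclasses.asdict(config)}
    cohort.to_csv(out / "cohort.csv")
    cm.to_csv(out / "count_matrix.csv")
    props.to_csv(out / "proportions.csv")
    frailty.to_csv(out / "frailty.csv")
    pd.DataFrame({"participant_id": cohort.index,
                  "cmv_status": fitted_status}).set_index(
        "participant_id").to_csv(out / "serostatus.csv")
    with open(out / "mixture_fit.json", "w") as fh:
        json.dump({"mu1": fit.mu1, "mu2": fit.mu2, "sigma1": fit.sigma1,
                   "sigma2": fit.sigma2, "w1": fit.w1,
                   "log_cutoff": cutoff, "converged": fit.converged,
                   "n_iter": fit.n_iter}, fh, indent=2)
    associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    imp_all = pd.concat([imp for _, imp in forest_rows], ignore_index=True)
    imp_all.to_csv(out / "forest_importance.csv", index=False)
    with open(out / "forest_reports.json", "w") as fh:
        json.dump([{"sex": r.sex, "n": r.n, "n_trees": r.n_trees,
                    "mtry": r.mtry, "mse_oob": r.mse_oob,
                    "pev": r.pev} for r, _ in forest_rows], fh, indent=2)
    if pdp_frames:
        pd.concat(pdp_frames, ignore_index=True).to_csv(
            out / "partial_dependence.csv", index=False)
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)

    results.update({
        "cohort": cohort, "count_matrix": cm, "proportions": props,
        "associations": associations, "mixture_fit": fit,
        "forest_reports": [r for r, _ in forest_rows],
        "out_dir": str(out),
    })
    return results
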