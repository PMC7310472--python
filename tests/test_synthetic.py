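"""Cohort and event generator: design, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunofrail.association import make_blocks, weighted_rho
from immunofrail.gating import classify_events
from immunofrail.phenotypes import FALCON, TRUCOUNT
from immunofrail.synthetic_data import (
    AcquisitionSettings,
    CmvMixture,
    CohortSpec,
    cohort_frame,
    generate_cohort,
    generate_tube_events,
    latent_correlation,
    sample_cmv_titers,
    true_count_matrix,
)


class TestCohortDesign:
    def test_default_cohort_sex_counts(self, default_cohort):
        _, cohort, _ = default_cohort
        assert (cohort["sex"] == "M").sum() == 145
        assert (cohort["sex"] == "F").sum() == 144

    def test_ages_and_deficits_in_range(self, default_cohort):
        _, cohort, _ = default_cohort
        assert cohort["age"].between(60, 87).all()
        deficits = cohort.filter(like="deficit_")
        assert deficits.shape[1] == 36
        ok = deficits.dropna()
        assert ((ok >= 0) & (ok <= 1)).all().all()

    def test_equal_frailty_strata(self, default_cohort):
        _, cohort, _ = default_cohort
        men = cohort[cohort["sex"] == "M"]["stratum"].value_counts()
        assert men["healthiest"] == men["frailest"] == 48
        assert men["intermediate"] == 49

    def test_concentrations_nonnegative(self, default_cohort):
        _, _, cm = default_cohort
        assert (cm >= 0).all().all()

    def test_determinism(self):
        spec = CohortSpec(n_men=10, n_women=10, seed=5,
                          missing_frailty={"M": 1, "F": 1})
        a = cohort_frame(generate_cohort(spec))
        b = cohort_frame(generate_cohort(spec))
        pd.testing.assert_frame_equal(a, b)
        c = cohort_frame(generate_cohort(
            CohortSpec(n_men=10, n_women=10, seed=6,
                       missing_frailty={"M": 1, "F": 1})))
        assert not a["cmv_igg"].equals(c["cmv_igg"])

    def test_invalid_effect_target_names_phenotype(self):
        with pytest.raises(ValueError, match="neutrophils"):
            CohortSpec(effect_profile={"F": {"neutrophils": 1.0}})

    def test_strata_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(strata_fractions=(0.2, 0.2, 0.2))


class TestEffectCalibration:
    def test_latent_correlation_inverts_spearman_map(self):
        for rho in (-0.9, -0.2, 0.0, 0.3, 0.9):
            r = latent_correlation(rho)
            assert (6 / np.pi) * np.arcsin(r / 2) == pytest.approx(rho)

    def test_null_profile_gives_near_zero_rho(self):
        spec = CohortSpec(n_men=0, n_women=4000,
                          missing_frailty={"M": 0, "F": 0},
                          effect_profile={"F": {}}, seed=9)
        parts = generate_cohort(spec)
        cohort = cohort_frame(parts)
        cm = true_count_matrix(parts)
        design = make_blocks(cohort, ("age_group", "cmv_status"))
        for ph in ("neutrophils", "cd56pos_t_cells", "b_cells"):
            rho = weighted_rho(cm[ph], cohort["frailty_index"], design)
            assert abs(rho) < 0.05

    def test_strong_effect_recovery_single_phenotype(self):
        # a 0.9 target on neutrophils recovers within 0.03 at n=5000
        spec = CohortSpec(n_men=0, n_women=5000,
                          missing_frailty={"M": 0, "F": 0},
                          effect_profile={"F": {"neutrophils": 0.9}}, seed=13)
        parts = generate_cohort(spec)
        cohort = cohort_frame(parts)
        cm = true_count_matrix(parts)
        design = make_blocks(cohort, ("age_group", "cmv_status"))
        rho = weighted_rho(cm["neutrophils"], cohort["frailty_index"], design)
        assert rho == pytest.approx(0.9, abs=0.03)

    def test_aggregate_phenotype_hits_target(self):
        # profile on an aggregate (cd4_temra) binds its member leaves too
        spec = CohortSpec(n_men=0, n_women=5000,
                          missing_frailty={"M": 0, "F": 0},
                          effect_profile={"F": {"cd4_temra": -0.3}}, seed=17)
        parts = generate_cohort(spec)
        cohort = cohort_frame(parts)
        cm = true_count_matrix(parts)
        design = make_blocks(cohort, ("age_group", "cmv_status"))
        rho = weighted_rho(cm["cd4_temra"], cohort["frailty_index"], design)
        assert rho == pytest.approx(-0.3, abs=0.03)


class TestCmvTiters:
    def test_single_component_is_unimodal(self):
        titers, labels = sample_cmv_titers(
            200, CmvMixture(weight_neg=1.0), seed=0)
        assert (labels == "negative").all()
        assert stats.shapiro(np.log(titers)).pvalue > 0.01

    def test_mixture_mean_matches_moment_formula(self):
        mix = CmvMixture(mu_neg=0.0, sigma_neg=0.3, mu_pos=2.0,
                         sigma_pos=0.3, weight_neg=0.5)
        titers, _ = sample_cmv_titers(5000, mix, seed=1)
        assert np.log(titers).mean() == pytest.approx(1.0, abs=0.05)

    def test_determinism(self):
        a, la = sample_cmv_titers(50, seed=3)
        b, lb = sample_cmv_titers(50, seed=3)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(la, lb)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            CmvMixture(weight_neg=1.2)


@pytest.fixture()
def participant():
    return generate_cohort(CohortSpec(
        n_men=1, n_women=0, missing_frailty={"M": 0, "F": 0}, seed=2))[0]


class TestTubeEvents:
    def test_expected_event_and_bead_counts(self, participant):
        """Closed-form expectation: events = conc x volume x fraction."""
        p = participant
        p.leaf_concentrations = {"neutrophil": 4000.0}
        acq = AcquisitionSettings(sample_volume=50.0, beads_per_tube=50000,
                                  acquisition_fraction=0.5, debris_conc=0.0)
        n_cells, n_beads = [], []
        for s in range(100):
            ev = generate_tube_events(p, TRUCOUNT, seed=s, acquisition=acq)
            res = classify_events(ev)
            n_cells.append(res.counts["neutrophils"])
            n_beads.append(res.bead_count)
        # 4000/µL * 50 µL * 0.5 = 100,000 cell events; 25,000 bead events
        assert np.mean(n_cells) == pytest.approx(100_000, rel=0.01)
        assert np.mean(n_beads) == pytest.approx(25_000, rel=0.01)

    def test_zero_concentration_yields_zero_events(self, participant):
        p = participant
        p.leaf_concentrations = {"neutrophil": 0.0}
        acq = AcquisitionSettings(debris_conc=0.0)
        ev = generate_tube_events(p, TRUCOUNT, seed=0, acquisition=acq)
        assert classify_events(ev).counts["neutrophils"] == 0

    def test_falcon_tube_has_no_beads(self):
        p = generate_cohort(CohortSpec(
            n_men=1, n_women=0, missing_frailty={"M": 0, "F": 0}, seed=2))[0]
        ev = generate_tube_events(p, FALCON, seed=0)
        assert ev.attrs["tube"] == FALCON
        assert classify_events(ev).bead_count == 0

    def test_zero_volume_is_an_error(self, participant):
        with pytest.raises(ValueError, match="volume"):
            generate_tube_events(
                participant, TRUCOUNT, seed=0,
                acquisition=AcquisitionSettings(sample_volume=0.0))

    def test_event_tables_deterministic(self):
        p = generate_cohort(CohortSpec(
            n_men=1, n_women=0, missing_frailty={"M": 0, "F": 0}, seed=2))[0]
        acq = AcquisitionSettings(acquisition_fraction=0.05)
        a = generate_tube_events(p, TRUCOUNT, seed=8, acquisition=acq)
        b = generate_tube_events(p, TRUCOUNT, seed=8, acquisition=acq)
        pd.testing.assert_frame_equal(a, b)
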