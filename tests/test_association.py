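"""Blocked permutation machinery: weighted rho, WMW, BH, study driver."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunofrail.association import (
    bh_adjust,
    blocked_permutation_test,
    make_blocks,
    run_association_study,
    weighted_rho,
)
from immunofrail.phenotypes import subpopulation_names
from immunofrail.synthetic_data import (
    CohortSpec,
    cohort_frame,
    generate_cohort,
    true_count_matrix,
)


class TestMakeBlocks:
    def test_age_cmv_cross_classification(self, default_cohort):
        _, cohort, _ = default_cohort
        design = make_blocks(cohort, ("age_group", "cmv_status"))
        assert len(design.sizes) <= 8
        assert design.sizes.sum() == len(cohort)

    def test_single_factor_single_level(self):
        cohort = pd.DataFrame({"cmv_status": ["positive"] * 5})
        design = make_blocks(cohort, ("cmv_status",))
        assert len(design.sizes) == 1

    def test_age_quartiles_computed_when_missing(self):
        ages = [60, 62, 65, 68, 72, 76, 80, 86]
        cohort = pd.DataFrame({"age": ages})
        design = make_blocks(cohort, ("age_group",))
        expected = 1 + np.searchsorted(np.quantile(ages, [0.25, 0.5, 0.75]),
                                       ages, side="left")
        assert list(design.labels) == [str(e) for e in expected]


class TestWeightedRho:
    def test_single_block_reduces_to_spearman(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        blocks = np.zeros(30, dtype=int)
        assert weighted_rho(x, y, blocks) == pytest.approx(
            stats.spearmanr(x, y).statistic)

    def test_perfect_concordance_in_each_block(self):
        x = np.array([1, 2, 3, 10, 20, 30, 40], dtype=float)
        y = np.array([5, 6, 7, 1, 2, 3, 4], dtype=float)
        blocks = np.array(["a"] * 3 + ["b"] * 4)
        assert weighted_rho(x, y, blocks) == pytest.approx(1.0)

    def test_hand_computed_two_block_example(self):
        # blocks {(1,2),(2,1),(3,3)} and {(1,3),(2,2),(3,1),(4,4)}
        x = np.array([1, 2, 3, 1, 2, 3, 4], dtype=float)
        y = np.array([2, 1, 3, 3, 2, 1, 4], dtype=float)
        blocks = np.array(["a"] * 3 + ["b"] * 4)
        # by hand: block a has d^2 = (1-2)^2+(2-1)^2+0 = 2 -> rho = 0.5;
        # block b has d^2 = 4+0+4+0 = 8 -> rho = 1 - 48/60 = 0.2
        expected = (3 * 0.5 + 4 * 0.2) / 7
        assert weighted_rho(x, y, blocks) == pytest.approx(expected)
        assert stats.spearmanr(x[3:], y[3:]).statistic == pytest.approx(0.2)

    def test_small_blocks_dropped(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        blocks = np.array(["big"] * 10 + ["tiny"] * 2)
        assert weighted_rho(x, y, blocks) == pytest.approx(
            stats.spearmanr(x[:10], y[:10]).statistic)

    def test_all_blocks_too_small_gives_missing(self):
        with pytest.warns(UserWarning, match="no block"):
            out = weighted_rho([1, 2], [2, 1], np.array(["a", "b"]))
        assert np.isnan(out)

    def test_invariant_under_monotone_within_block_transforms(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        blocks = rng.integers(0, 3, size=40)
        base = weighted_rho(x, y, blocks)
        assert weighted_rho(np.exp(x), y, blocks) == pytest.approx(base)
        assert weighted_rho(x, y**3, blocks) == pytest.approx(base)


def exact_weighted_rho_p(x, y, block_slices):
    """Exhaustive within-block permutation p-value (oracle)."""
    def statistic(ys):
        num = den = 0.0
        for sl in block_slices:
            n = sl.stop - sl.start
            r = stats.pearsonr(stats.rankdata(x[sl]),
                               stats.rankdata(ys[sl])).statistic
            num += n * r
            den += n
        return num / den

    t_obs = statistic(y)
    count = total = 0
    parts = [list(itertools.permutations(y[sl])) for sl in block_slices]
    for combo in itertools.product(*parts):
        ys = np.concatenate([np.asarray(c) for c in combo])
        total += 1
        count += abs(statistic(ys)) >= abs(t_obs) - 1e-12
    return count / total


class TestBlockedPermutationTest:
    def test_matches_exact_enumeration_weighted_rho(self):
        x = np.array([1.0, 2, 3, 4, 1, 2, 3])
        y = np.array([2.0, 1, 4, 3, 3, 1, 2])
        blocks = np.array(["a"] * 4 + ["b"] * 3)
        res = blocked_permutation_test(x, y, blocks, "weighted_rho",
                                       n_perm=10_000, seed=1)
        p_exact = exact_weighted_rho_p(x, y, [slice(0, 4), slice(4, 7)])
        assert abs(res.p_value - p_exact) <= 2 * res.mc_se + 1e-9

    def test_matches_exact_enumeration_wmw(self):
        x = np.array([3.0, 1, 4, 2, 7, 5, 6, 8])
        g = np.array(["A", "A", "B", "B", "A", "B", "A", "B"])
        blocks = np.array(["a"] * 4 + ["b"] * 4)
        res = blocked_permutation_test(x, g, blocks, "wmw",
                                       n_perm=10_000, seed=2)
        # oracle: enumerate group-label assignments within each block
        def stat(groups):
            t = 0.0
            for sl in (slice(0, 4), slice(4, 8)):
                r = stats.rankdata(x[sl])
                rc = r - r.mean()
                m = groups[sl] == "A"
                n1, n2 = m.sum(), (~m).sum()
                var = n1 * n2 / (4 * 3) * (rc ** 2).sum()
                t += rc[m].sum() / np.sqrt(var)
            return t

        t_obs = stat(g)
        count = total = 0
        for c1 in itertools.permutations(g[:4]):
            for c2 in itertools.permutations(g[4:]):
                gs = np.array(c1 + c2)
                total += 1
                count += abs(stat(gs)) >= abs(t_obs) - 1e-12
        p_exact = count / total
        assert abs(res.p_value - p_exact) <= 2 * res.mc_se + 1e-9

    def test_type_one_error_calibrated(self, rng):
        """Under within-block exchangeability, P(p <= .05) is ~.05."""
        hits = 0
        n_sim = 400
        blocks = np.repeat(["a", "b"], 15)
        for s in range(n_sim):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            res = blocked_permutation_test(x, y, blocks, "weighted_rho",
                                           n_perm=199, seed=s)
            hits += res.p_value <= 0.05
        assert 0.03 <= hits / n_sim <= 0.07

    def test_monotone_association_reaches_minimum_p(self, rng):
        x = rng.normal(size=40)
        blocks = np.repeat(["a", "b"], 20)
        res = blocked_permutation_test(x, np.exp(x), blocks, "weighted_rho",
                                       n_perm=999, seed=3)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_constant_x_gives_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            res = blocked_permutation_test(
                np.ones(20), np.arange(20.0), np.repeat(["a", "b"], 10),
                "weighted_rho", n_perm=100, seed=0)
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        blocks = np.repeat(["a", "b", "c"], 10)
        a = blocked_permutation_test(x, y, blocks, "weighted_rho",
                                     n_perm=500, seed=7)
        b = blocked_permutation_test(x, y, blocks, "weighted_rho",
                                     n_perm=500, seed=7)
        assert a.p_value == b.p_value

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            blocked_permutation_test([1.0, 2], [1.0, 2], ["a", "a"],
                                     n_perm=10)


class TestBH:
    def test_step_through_example(self):
        reject, _, k = bh_adjust([0.01, 0.02, 0.2, 0.9], q=0.15)
        assert list(reject) == [True, True, False, False]
        assert k == 2

    def test_all_ones_rejects_none(self):
        reject, _, k = bh_adjust([1.0, 1.0, 1.0], q=0.15)
        assert not reject.any() and k == 0

    def test_bonferroni_dominated_rejects_all(self):
        m, q = 6, 0.15
        reject, _, _ = bh_adjust([q / m / 2] * m, q=q)
        assert reject.all()


@pytest.fixture(scope="module")
def big_cohort():
    parts = generate_cohort(CohortSpec(
        n_men=400, n_women=400, missing_frailty={"M": 5, "F": 7},
        seed=31))
    return cohort_frame(parts), true_count_matrix(parts)


class TestStudyDriver:
    def test_frailty_study_flags_neutrophils_in_both_sexes(self, big_cohort):
        cohort, cm = big_cohort
        out = run_association_study(cm, cohort, "frailty_by_sex",
                                    n_perm=1000, seed=0)
        neut = out[out["phenotype"] == "neutrophils"].set_index("stratum")
        assert bool(neut.loc["M", "bh_reject"])
        assert bool(neut.loc["F", "bh_reject"])
        # female weighted rho near its calibration target
        assert neut.loc["F", "weighted_rho"] == pytest.approx(0.40, abs=0.1)

    def test_sex_study_detects_higher_female_b_cells(self, big_cohort):
        cohort, cm = big_cohort
        out = run_association_study(cm, cohort, "sex", n_perm=1000, seed=1,
                                    phenotypes=["b_cells", "naive_b_cells"])
        assert (out["p"] < 0.05).all()

    def test_missing_columns_skipped_with_warning(self, big_cohort):
        cohort, cm = big_cohort
        with pytest.warns(UserWarning, match="skipped"):
            out = run_association_study(
                cm.drop(columns=["tfh"]), cohort, "frailty_by_sex",
                n_perm=200, seed=2)
        assert "tfh" not in set(out["phenotype"])

    def test_unknown_study_rejected(self, big_cohort):
        cohort, cm = big_cohort
        with pytest.raises(ValueError):
            run_association_study(cm, cohort, "diet", n_perm=200)
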