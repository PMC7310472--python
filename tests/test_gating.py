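"""Event classification against the hierarchical phenotype tree."""

import numpy as np
import pandas as pd
import pytest

from immunofrail.gating import (
    GatingError,
    b_nk_partition,
    classify_events,
    hladr_sensitivity_filter,
    marker_expression_summary,
    memory_t_partition,
)
from immunofrail.phenotypes import (
    FALCON,
    TRUCOUNT,
    TUBE_CHANNELS,
    default_phenotype_table,
)
from immunofrail.synthetic_data import (
    INTENSITY_LOG_SD,
    LEVEL_LOG_MEAN,
    PHENOTYPE_LEAVES,
    default_population_models,
)

NEG, DIM, BRIGHT = (np.exp(LEVEL_LOG_MEAN[k]) for k in ("neg", "dim", "bright"))


def make_events(tube, rows):
    """Event table from {channel: value} dicts (unset channels negative)."""
    channels = TUBE_CHANNELS[tube]
    data = [[row.get(c, NEG) for c in channels] for row in rows]
    ev = pd.DataFrame(data, columns=channels)
    ev.attrs["tube"] = tube
    return ev


def test_canonical_gate_assignments():
    ev = make_events(TRUCOUNT, [
        {"CD45": DIM, "SSC": BRIGHT, "CD16": BRIGHT},        # neutrophil
        {"CD45": DIM, "SSC": DIM},                            # CD16- monocyte
        {"CD45": BRIGHT, "CD3": BRIGHT, "CD56": BRIGHT},      # CD56+ T
        {"CD45": BRIGHT, "CD19": BRIGHT, "CD38": DIM,
         "CD27": BRIGHT},                                     # memory B
        {"CD45": BRIGHT, "CD56": BRIGHT},                     # CD56bright NK
    ])
    res = classify_events(ev)
    for name, expected in [
        ("neutrophils", 1), ("monocytes", 1), ("cd16neg_monocytes", 1),
        ("cd56pos_t_cells", 1), ("memory_b_cells", 1),
        ("nk_cd56bright_cd16neg", 1), ("t_cells", 1), ("b_cells", 1),
        ("nk_cells", 1), ("lymphocytes", 3),
    ]:
        assert res.counts[name] == expected, name


def test_falcon_memory_gates():
    ev = make_events(FALCON, [
        {"CD3": BRIGHT, "CD4": BRIGHT, "CCR7": BRIGHT, "CD45RA": BRIGHT},
        {"CD3": BRIGHT, "CD8": BRIGHT, "CD45RA": BRIGHT},  # CCR7- -> TemRA
    ])
    res = classify_events(ev)
    assert res.counts["cd4_naive"] == 1
    assert res.counts["cd8_temra"] == 1
    # CD27-CD28- TemRA is late stage
    ev2 = make_events(FALCON, [{"CD3": BRIGHT, "CD8": BRIGHT,
                                "CD45RA": BRIGHT}])
    assert classify_events(ev2).counts["cd8_temra_late"] == 1


def test_child_counts_never_exceed_parent(rng):
    ev = pd.DataFrame(
        np.exp(rng.normal(1.5, 1.5, size=(3000, len(TUBE_CHANNELS[TRUCOUNT])))),
        columns=TUBE_CHANNELS[TRUCOUNT])
    ev.attrs["tube"] = TRUCOUNT
    res = classify_events(ev)
    by_name = {d.name: d for d in default_phenotype_table()
               if d.tube == TRUCOUNT}
    for name, d in by_name.items():
        if d.parent is not None:
            assert res.counts[name] <= res.counts[d.parent]


def test_cd4_cd8_cd56_t_partitions_disjoint(rng):
    ev = pd.DataFrame(
        np.exp(rng.normal(1.5, 1.5, size=(2000, len(TUBE_CHANNELS[TRUCOUNT])))),
        columns=TUBE_CHANNELS[TRUCOUNT])
    ev.attrs["tube"] = TRUCOUNT
    res = classify_events(ev)
    overlap = (res.masks["cd4_t_cells"] & res.masks["cd8_t_cells"])
    assert not (res.masks["cd56pos_t_cells"] & res.masks["cd4_t_cells"]).any()
    assert not (res.masks["cd56pos_t_cells"] & res.masks["cd8_t_cells"]).any()
    # CD4+CD8+ doublets are possible in random noise but must be in both
    # parents' t_cells gate anyway
    assert (res.masks["t_cells"][overlap]).all()


def test_missing_channel_error_names_channel_and_phenotype():
    ev = make_events(TRUCOUNT, [{"CD45": BRIGHT}]).drop(columns=["CD16"])
    ev.attrs["tube"] = TRUCOUNT
    with pytest.raises(GatingError, match="CD16.*monocytes"):
        classify_events(ev)


def test_memory_partition_is_exact_and_mixed_stage_excluded(rng):
    n = 500
    ev = pd.DataFrame(
        np.exp(rng.normal(2.0, 2.0, size=(n, len(TUBE_CHANNELS[FALCON])))),
        columns=TUBE_CHANNELS[FALCON])
    part = memory_t_partition(ev)
    counts = part["subset"].value_counts()
    assert counts.sum() == n  # the four quadrants partition the input
    assert set(counts.index) <= {"naive", "cm", "tem", "temra"}
    # CD27+CD28- event in the Tem quadrant: neither early nor late
    one = make_events(FALCON, [{"CD3": BRIGHT, "CD4": BRIGHT,
                                "CD27": BRIGHT, "CD28": NEG}])
    lab = memory_t_partition(one)
    assert lab.loc[0, "subset"] == "tem"
    assert lab.loc[0, "stage"] == "mixed"


def test_cd27_cd28_state_enumeration():
    """All four CD27xCD28 combinations: only ++ is early, only -- is late."""
    rows = [{"CD3": BRIGHT, "CD8": BRIGHT, "CD27": c27, "CD28": c28}
            for c27 in (NEG, BRIGHT) for c28 in (NEG, BRIGHT)]
    res = classify_events(make_events(FALCON, rows))
    assert res.counts["cd8_tem"] == 4
    assert res.counts["cd8_tem_early"] == 1
    assert res.counts["cd8_tem_late"] == 1


def test_b_nk_partition_labels():
    ev = make_events(TRUCOUNT, [
        {"CD45": BRIGHT, "CD19": BRIGHT, "CD38": DIM, "CD27": BRIGHT},
        {"CD45": BRIGHT, "CD56": BRIGHT},
        {"CD45": BRIGHT, "CD3": BRIGHT, "CD56": BRIGHT},
    ])
    labels = b_nk_partition(ev)
    assert labels[0] == "memory_b_cells"
    assert labels[1] == "nk_cd56bright_cd16neg"
    assert labels[2] == "cd56pos_t_cells"  # CD3+CD56+ is a T cell, not NK


def test_marker_expression_summary(rng):
    ev = make_events(TRUCOUNT, [
        {"CD45": DIM, "SSC": BRIGHT, "CD16": 7.0},
        {"CD45": DIM, "SSC": BRIGHT, "CD16": 7.0},
    ])
    res = classify_events(ev)
    assert marker_expression_summary(res, "neutrophils", "CD16") == 7.0
    assert np.isnan(marker_expression_summary(res, "b_cells", "CD38"))
    # lognormal(mu, sigma) sample median ~= e^mu
    mu = 3.0
    big = make_events(TRUCOUNT, [
        {"CD45": DIM, "SSC": BRIGHT, "CD16": v}
        for v in np.exp(rng.normal(mu, 0.4, size=4000))])
    med = marker_expression_summary(classify_events(big),
                                    "neutrophils", "CD16")
    assert abs(np.log(med) - mu) < 0.05


def test_hladr_filter_monotone_and_idempotent():
    defs = default_phenotype_table()
    once = hladr_sensitivity_filter(defs)
    assert hladr_sensitivity_filter(once) == once
    # HLA-DR negative contaminants (NK-like scatter-dim events) excluded
    ev = make_events(TRUCOUNT, [
        {"CD45": DIM, "SSC": DIM, "HLA-DR": BRIGHT},
        {"CD45": DIM, "SSC": DIM, "HLA-DR": NEG},   # contaminant
    ])
    before = classify_events(ev, defs)
    after = classify_events(ev, once)
    assert before.counts["monocytes"] == 2
    assert after.counts["monocytes"] == 1
    for name in ("monocytes", "cd16neg_monocytes", "cd16pos_monocytes"):
        assert after.counts[name] <= before.counts[name]
    # non-monocyte definitions untouched
    assert [d for d in once if "monocyte" not in d.name] == \
        [d for d in defs if "monocyte" not in d.name]


@pytest.mark.parametrize("tube", [TRUCOUNT, FALCON])
def test_classification_accuracy_on_labeled_populations(tube, rng):
    """Events drawn from each leaf's intensity model land in every
    phenotype that should contain that leaf with >= 99% accuracy."""
    defs = default_phenotype_table()
    tube_phenos = {d.name for d in defs if d.tube == tube} \
        - {"beads", "leukocytes"}
    channels = TUBE_CHANNELS[tube]
    n = 400
    for model in default_population_models():
        mu = model.log_means(channels)
        ev = pd.DataFrame(np.exp(mu + INTENSITY_LOG_SD * rng.standard_normal(
            (n, len(channels)))), columns=channels)
        ev.attrs["tube"] = tube
        res = classify_events(ev)
        for ph in tube_phenos:
            expected = model.name in PHENOTYPE_LEAVES.get(ph, [])
            frac = res.counts[ph] / n
            if expected:
                assert frac >= 0.99, (model.name, ph, frac)
            else:
                assert frac <= 0.01, (model.name, ph, frac)
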