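"""Hierarchical gating of event tables into leukocyte subpopulations.

Events are pandas DataFrames (one row per event, one column per channel)
produced by the synthetic generator or read from per-participant CSV files.
Classification descends the phenotype tree: a phenotype's events are its
parent's events that satisfy every marker predicate, so child counts can
never exceed parent counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotypes import (
    FALCON,
    TRUCOUNT,
    MarkerPredicate,
    PhenotypeDefinition,
    default_phenotype_table,
    default_thresholds,
)

#: (phenotype, channel) pairs whose expression is summarized by default:
#: CD16 on neutrophils (maturation), HLA-DR / CD38 on monocyte subsets
#: (inflammation-related activation markers).
EXPRESSION_PANEL: tuple[tuple[str, str], ...] = (
    ("neutrophils", "CD16"),
    ("cd16neg_monocytes", "HLA-DR"),
    ("cd16neg_monocytes", "CD38"),
    ("cd16pos_monocytes", "HLA-DR"),
    ("cd16pos_monocytes", "CD38"),
)


class GatingError(ValueError):
    pass


@dataclass
class GatingResult:
    """Counts and event masks for one tube of one participant."""

    tube: str
    counts: dict[str, int]
    masks: dict[str, np.ndarray]
    events: pd.DataFrame
    bead_count: int = 0
    unclassified: int = 0
    expression: dict[tuple[str, str], float] = field(default_factory=dict)


def classify_events(
    events: pd.DataFrame,
    defs: list[PhenotypeDefinition] | None = None,
    thresholds: dict[str, tuple[float, float]] | None = None,
    tube: str | None = None,
) -> GatingResult:
    """Assign each event to the gating tree of one tube.

    ``tube`` defaults to the table attribute ``events.attrs['tube']``.
    Raises :class:`GatingError` if a definition references a channel the
    table does not contain.
    """
    defs = default_phenotype_table() if defs is None else defs
    thresholds = default_thresholds() if thresholds is None else thresholds
    if tube is None:
        tube = events.attrs.get("tube")
    if tube not in (TRUCOUNT, FALCON):
        raise GatingError(f"unknown tube {tube!r}")

    tube_defs = [d for d in defs if d.tube == tube]
    by_name = {d.name: d for d in tube_defs}
    n = len(events)
    masks: dict[str, np.ndarray] = {}

    def mask_for(d: PhenotypeDefinition) -> np.ndarray:
        if d.name in masks:
            return masks[d.name]
        base = (np.ones(n, dtype=bool) if d.parent is None
                else mask_for(by_name[d.parent]).copy())
        for pred in d.predicates:
            if pred.channel not in events.columns:
                raise GatingError(
                    f"channel {pred.channel!r} required by phenotype "
                    f"{d.name!r} is missing from the event table")
            base &= pred.evaluate(events[pred.channel].to_numpy(), thresholds)
        masks[d.name] = base
        return base

    for d in tube_defs:
        mask_for(d)

    counts = {name: int(m.sum()) for name, m in masks.items()}
    bead_count = counts.pop("beads", 0)
    bead_mask = masks.pop("beads", np.zeros(n, dtype=bool))

    roots = [d.name for d in tube_defs if d.parent is None and d.name != "beads"]
    in_any_root = np.zeros(n, dtype=bool)
    for r in roots:
        in_any_root |= masks[r]
    unclassified = int((~in_any_root & ~bead_mask).sum())

    result = GatingResult(tube=tube, counts=counts, masks=masks,
                          events=events, bead_count=bead_count,
                          unclassified=unclassified)
    for phenotype, channel in EXPRESSION_PANEL:
        if phenotype in masks and channel in events.columns:
            result.expression[(phenotype, channel)] = \
                marker_expression_summary(result, phenotype, channel)
    return result


def marker_expression_summary(result: GatingResult, phenotype: str,
                              channel: str) -> float:
    """Median channel intensity over a phenotype's events (NaN if empty)."""
    if phenotype not in result.masks:
        raise GatingError(f"phenotype {phenotype!r} not gated in this tube")
    mask = result.masks[phenotype]
    if not mask.any():
        return float("nan")
    return float(result.events.loc[mask, channel].median())


def memory_t_partition(t_events: pd.DataFrame,
                       thresholds=None) -> pd.DataFrame:
    """Label CD4+/CD8+ T events by CCR7 x CD45RA quadrant and memory stage.

    Returns a frame with columns ``subset`` (naive / cm / tem / temra — an
    exact partition of the input) and ``stage`` (early for CD27+CD28+, late
    for CD27-CD28-, mixed otherwise; only meaningful for tem / temra).
    """
    thresholds = default_thresholds() if thresholds is None else thresholds
    ccr7 = MarkerPredicate("CCR7", "positive").evaluate(
        t_events["CCR7"].to_numpy(), thresholds)
    ra = MarkerPredicate("CD45RA", "positive").evaluate(
        t_events["CD45RA"].to_numpy(), thresholds)
    subset = np.where(ccr7, np.where(ra, "naive", "cm"),
                      np.where(ra, "temra", "tem"))
    cd27 = MarkerPredicate("CD27", "positive").evaluate(
        t_events["CD27"].to_numpy(), thresholds)
    cd28 = MarkerPredicate("CD28", "positive").evaluate(
        t_events["CD28"].to_numpy(), thresholds)
    stage = np.where(cd27 & cd28, "early",
                     np.where(~cd27 & ~cd28, "late", "mixed"))
    stage = np.where(np.isin(subset, ("tem", "temra")), stage, "n/a")
    return pd.DataFrame({"subset": subset, "stage": stage},
                        index=t_events.index)


def b_nk_partition(events: pd.DataFrame, thresholds=None) -> pd.Series:
    """Label lymphocyte-gate events as B / NK subsets, CD56+ T, or other.

    Runs the TruCOUNT lymphocyte subtree on the given events and labels each
    event with the finest B-cell / NK subset (or CD56+ T) it falls into.
    """
    defs = default_phenotype_table()
    sub = classify_events(events, defs, thresholds, tube=TRUCOUNT)
    labels = pd.Series("other", index=events.index, dtype=object)
    order = ["cd56pos_t_cells",
             "transitional_b_cells", "naive_b_cells", "memory_b_cells",
             "nk_cd56bright_cd16neg", "nk_cd56dim_cd16pos",
             "nk_cd56dim_cd16neg", "nk_cd56neg_cd16pos"]
    for name in order:
        labels[sub.masks[name]] = name
    return labels


def hladr_sensitivity_filter(
        defs: list[PhenotypeDefinition]) -> list[PhenotypeDefinition]:
    """Restrict monocyte gates to HLA-DR+ events (contamination check).

    Adds an HLA-DR positive predicate to the monocyte parent gate (children
    inherit it); all other definitions are untouched.  Idempotent.
    """
    hladr = MarkerPredicate("HLA-DR", "positive")
    out = []
    for d in defs:
        if d.name == "monocytes" and d.tube == TRUCOUNT \
                and hladr not in d.predicates:
            d = d.with_predicate(hladr)
        out.append(d)
    return out
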