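"""Leukocyte phenotype definitions for two-tube whole-blood immunophenotyping.

The default table enumerates 37 leukocyte subpopulations across two staining
tubes: a TruCOUNT tube (lineage markers plus counting beads) resolving
neutrophils, monocytes, B/NK subsets and total T/CD4/CD8 numbers, and a
Falcon tube (memory/regulatory markers) resolving CD4/CD8 memory subsets,
regulatory T cells and follicular helper T cells.  Definitions form a tree:
each phenotype is its parent's events restricted by a conjunction of marker
predicates (negative / positive / dim / bright relative to per-channel cuts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

TRUCOUNT = "trucount"
FALCON = "falcon"

#: Channels acquired in each tube (scatter first, then antigens).
TUBE_CHANNELS: dict[str, list[str]] = {
    TRUCOUNT: ["FSC", "SSC", "CD45", "CD3", "CD19", "CD56", "CD16",
               "CD4", "CD8", "CD27", "CD38", "HLA-DR", "IgD"],
    FALCON: ["FSC", "SSC", "CD3", "CD4", "CD8", "CD45RA", "CCR7",
             "CD27", "CD28", "CD25", "CD127", "CXCR5"],
}

# Intensities are modeled on an arbitrary-unit scale where populations sit at
# log-intensity ~0 (negative), ~2 (dim) or ~4 (bright).  The default cuts
# bisect adjacent bands in log space.
NEGATIVE_CUT = math.e ** 1.0
BRIGHT_CUT = math.e ** 3.0

RELATIONS = ("negative", "positive", "dim", "bright")


def default_thresholds() -> dict[str, tuple[float, float]]:
    """(negative_cut, bright_cut) per channel; dim lies between the cuts."""
    channels = sorted({c for chans in TUBE_CHANNELS.values() for c in chans})
    return {c: (NEGATIVE_CUT, BRIGHT_CUT) for c in channels}


@dataclass(frozen=True)
class MarkerPredicate:
    """One marker requirement, e.g. CD3 positive or SSC bright.

    ``positive`` means at or above the negative cut (dim or bright); ties at
    a cut are assigned to the higher band.
    """

    channel: str
    relation: str

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")

    def evaluate(self, values, thresholds):
        neg_cut, bright_cut = thresholds[self.channel]
        if not neg_cut < bright_cut:
            raise ValueError(f"{self.channel}: dim band is empty "
                             f"({neg_cut} >= {bright_cut})")
        if self.relation == "negative":
            return values < neg_cut
        if self.relation == "positive":
            return values >= neg_cut
        if self.relation == "dim":
            return (values >= neg_cut) & (values < bright_cut)
        return values >= bright_cut


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A node of the gating tree for one tube."""

    name: str
    tube: str
    parent: str | None
    predicates: tuple[MarkerPredicate, ...] = field(default_factory=tuple)

    def with_predicate(self, pred: MarkerPredicate) -> "PhenotypeDefinition":
        return replace(self, predicates=self.predicates + (pred,))


def _p(channel: str, relation: str) -> MarkerPredicate:
    return MarkerPredicate(channel, relation)


def _build_default_table() -> list[PhenotypeDefinition]:
    defs: list[PhenotypeDefinition] = []

    def add(name, tube, parent, *preds):
        defs.append(PhenotypeDefinition(name, tube, parent, tuple(preds)))

    # --- TruCOUNT tube -----------------------------------------------------
    # Counting beads: intensely fluorescent on every channel, so CD3+CD19+
    # "double bright" identifies them unambiguously (no cell co-expresses).
    add("beads", TRUCOUNT, None, _p("CD3", "bright"), _p("CD19", "bright"))
    add("leukocytes", TRUCOUNT, None, _p("CD45", "positive"))
    add("neutrophils", TRUCOUNT, "leukocytes",
        _p("SSC", "bright"), _p("CD45", "dim"))
    add("monocytes", TRUCOUNT, "leukocytes",
        _p("SSC", "dim"), _p("CD45", "dim"),
        _p("CD3", "negative"), _p("CD19", "negative"))
    add("cd16neg_monocytes", TRUCOUNT, "monocytes", _p("CD16", "negative"))
    add("cd16pos_monocytes", TRUCOUNT, "monocytes", _p("CD16", "positive"))
    add("lymphocytes", TRUCOUNT, "leukocytes",
        _p("SSC", "negative"), _p("CD45", "bright"))
    add("t_cells", TRUCOUNT, "lymphocytes", _p("CD3", "positive"))
    add("cd56pos_t_cells", TRUCOUNT, "t_cells", _p("CD56", "positive"))
    add("cd4_t_cells", TRUCOUNT, "t_cells",
        _p("CD56", "negative"), _p("CD4", "positive"))
    add("cd8_t_cells", TRUCOUNT, "t_cells",
        _p("CD56", "negative"), _p("CD8", "positive"))
    add("b_cells", TRUCOUNT, "lymphocytes",
        _p("CD3", "negative"), _p("CD19", "positive"))
    add("transitional_b_cells", TRUCOUNT, "b_cells",
        _p("CD38", "bright"), _p("CD27", "negative"))
    add("naive_b_cells", TRUCOUNT, "b_cells",
        _p("CD38", "dim"), _p("CD27", "negative"))
    add("memory_b_cells", TRUCOUNT, "b_cells",
        _p("CD38", "dim"), _p("CD27", "positive"))
    # NK: non-T non-B lymphocytes, subdivided on CD16 x CD56.
    add("nk_cells", TRUCOUNT, "lymphocytes",
        _p("CD3", "negative"), _p("CD19", "negative"))
    add("nk_cd56bright_cd16neg", TRUCOUNT, "nk_cells",
        _p("CD56", "bright"), _p("CD16", "negative"))
    add("nk_cd56dim_cd16pos", TRUCOUNT, "nk_cells",
        _p("CD56", "dim"), _p("CD16", "positive"))
    add("nk_cd56dim_cd16neg", TRUCOUNT, "nk_cells",
        _p("CD56", "dim"), _p("CD16", "negative"))
    add("nk_cd56neg_cd16pos", TRUCOUNT, "nk_cells",
        _p("CD56", "negative"), _p("CD16", "positive"))

    # --- Falcon tube -------------------------------------------------------
    add("t_cells", FALCON, None, _p("CD3", "positive"))
    add("cd4_t_cells", FALCON, "t_cells",
        _p("CD4", "bright"), _p("CD8", "negative"))
    add("cd8_t_cells", FALCON, "t_cells",
        _p("CD8", "bright"), _p("CD4", "negative"))
    for lin in ("cd4", "cd8"):
        parent = f"{lin}_t_cells"
        add(f"{lin}_naive", FALCON, parent,
            _p("CCR7", "positive"), _p("CD45RA", "positive"))
        add(f"{lin}_cm", FALCON, parent,
            _p("CCR7", "positive"), _p("CD45RA", "negative"))
        add(f"{lin}_tem", FALCON, parent,
            _p("CCR7", "negative"), _p("CD45RA", "negative"))
        add(f"{lin}_tem_early", FALCON, f"{lin}_tem",
            _p("CD27", "positive"), _p("CD28", "positive"))
        add(f"{lin}_tem_late", FALCON, f"{lin}_tem",
            _p("CD27", "negative"), _p("CD28", "negative"))
        add(f"{lin}_temra", FALCON, parent,
            _p("CCR7", "negative"), _p("CD45RA", "positive"))
        add(f"{lin}_temra_early", FALCON, f"{lin}_temra",
            _p("CD27", "positive"), _p("CD28", "positive"))
        add(f"{lin}_temra_late", FALCON, f"{lin}_temra",
            _p("CD27", "negative"), _p("CD28", "negative"))
    add("tregs", FALCON, "cd4_t_cells",
        _p("CD25", "positive"), _p("CD127", "negative"))
    add("naive_tregs", FALCON, "tregs", _p("CD45RA", "positive"))
    add("tfh", FALCON, "cd4_t_cells", _p("CXCR5", "positive"))
    return defs


#: Names that are structural (roots / bead gate), not counted subpopulations.
NON_SUBPOPULATIONS = frozenset({"beads", "leukocytes"})


def default_phenotype_table() -> list[PhenotypeDefinition]:
    """The default gating table: 37 subpopulations over two tubes."""
    return _build_default_table()


def subpopulation_names(defs=None) -> list[str]:
    """Distinct subpopulation names, in table order (t_cells etc. once)."""
    defs = default_phenotype_table() if defs is None else defs
    seen, out = set(), []
    for d in defs:
        if d.name in NON_SUBPOPULATIONS or d.name in seen:
            continue
        seen.add(d.name)
        out.append(d.name)
    return out


# Parent used when expressing a subpopulation as a percentage: the major
# lineage, or the CD4/CD8 compartment for CD4/CD8 subsets.
PROPORTION_PARENT: dict[str, str] = {
    "neutrophils": "leukocytes",
    "monocytes": "leukocytes",
    "lymphocytes": "leukocytes",
    "cd16neg_monocytes": "monocytes",
    "cd16pos_monocytes": "monocytes",
    "t_cells": "lymphocytes",
    "b_cells": "lymphocytes",
    "nk_cells": "lymphocytes",
    "cd56pos_t_cells": "t_cells",
    "cd4_t_cells": "t_cells",
    "cd8_t_cells": "t_cells",
    "transitional_b_cells": "b_cells",
    "naive_b_cells": "b_cells",
    "memory_b_cells": "b_cells",
    "nk_cd56bright_cd16neg": "nk_cells",
    "nk_cd56dim_cd16pos": "nk_cells",
    "nk_cd56dim_cd16neg": "nk_cells",
    "nk_cd56neg_cd16pos": "nk_cells",
    **{f"cd4_{s}": "cd4_t_cells" for s in
       ("naive", "cm", "tem", "tem_early", "tem_late",
        "temra", "temra_early", "temra_late")},
    **{f"cd8_{s}": "cd8_t_cells" for s in
       ("naive", "cm", "tem", "tem_early", "tem_late",
        "temra", "temra_early", "temra_late")},
    "tregs": "cd4_t_cells",
    "naive_tregs": "cd4_t_cells",
    "tfh": "cd4_t_cells",
}

# Major-lineage membership, used for debris-exclusion flags: excluding the
# "lymphocyte" or "monocyte" data of a participant blanks these columns.
LINEAGE_MEMBERS: dict[str, list[str]] = {
    "lymphocytes": ["lymphocytes", "t_cells", "b_cells", "nk_cells",
                    "cd56pos_t_cells", "cd4_t_cells", "cd8_t_cells",
                    "transitional_b_cells", "naive_b_cells", "memory_b_cells",
                    "nk_cd56bright_cd16neg", "nk_cd56dim_cd16pos",
                    "nk_cd56dim_cd16neg", "nk_cd56neg_cd16pos",
                    "cd4_naive", "cd4_cm", "cd4_tem", "cd4_tem_early",
                    "cd4_tem_late", "cd4_temra", "cd4_temra_early",
                    "cd4_temra_late", "cd8_naive", "cd8_cm", "cd8_tem",
                    "cd8_tem_early", "cd8_tem_late", "cd8_temra",
                    "cd8_temra_early", "cd8_temra_late",
                    "tregs", "naive_tregs", "tfh"],
    "monocytes": ["monocytes", "cd16neg_monocytes", "cd16pos_monocytes"],
    "neutrophils": ["neutrophils"],
}


def save_phenotype_table(defs, path) -> None:
    payload = [
        {"name": d.name, "tube": d.tube, "parent": d.parent,
         "predicates": [{"channel": p.channel, "relation": p.relation}
                        for p in d.predicates]}
        for d in defs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"phenotypes": payload}, fh, sort_keys=False)


def load_phenotype_table(path) -> list[PhenotypeDefinition]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        PhenotypeDefinition(
            e["name"], e["tube"], e["parent"],
            tuple(MarkerPredicate(p["channel"], p["relation"])
                  for p in e["predicates"]))
        for e in payload["phenotypes"]
    ]
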