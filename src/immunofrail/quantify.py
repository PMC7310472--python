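"""Absolute quantification: gated event counts -> cells/µL.

TruCOUNT tubes contain a known number of counting beads; the ratio of cell
events to bead events converts event counts into concentrations.  The Falcon
tube carries no beads, so its phenotypes are scaled through the CD3+ T-cell
population measured in both tubes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import GatingResult
from .phenotypes import (
    LINEAGE_MEMBERS,
    PROPORTION_PARENT,
    TRUCOUNT,
    subpopulation_names,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrucountCalibration:
    beads_per_tube: float
    bead_events: int
    sample_volume: float  # µL of blood stained in the tube

    def __post_init__(self):
        if self.beads_per_tube <= 0 or self.sample_volume <= 0:
            raise ValueError("beads_per_tube and sample_volume must be > 0")
        if self.bead_events <= 0:
            raise ValueError("no bead events acquired; cannot calibrate")
        if self.bead_events > self.beads_per_tube:
            warnings.warn(
                f"bead_events ({self.bead_events}) exceeds beads_per_tube "
                f"({self.beads_per_tube}); calibration implausible",
                stacklevel=2)


def trucount_concentration(events_in_gate: float,
                           cal: TrucountCalibration) -> float:
    """cells/µL = events x (beads per tube / bead events) / volume."""
    if events_in_gate < 0:
        raise ValueError("negative event count")
    return events_in_gate * (cal.beads_per_tube / cal.bead_events) \
        / cal.sample_volume


def falcon_scaling(falcon_events: float, cd3_events_falcon: float,
                   cd3_conc_trucount: float) -> float:
    """Scale a Falcon-tube gate to cells/µL through the cross-tube CD3 ratio."""
    if cd3_events_falcon <= 0:
        raise ValueError("no CD3+ events in the Falcon tube")
    return falcon_events * (cd3_conc_trucount / cd3_events_falcon)


def participant_concentrations(
        trucount_result: GatingResult,
        falcon_result: GatingResult,
        cal: TrucountCalibration) -> dict[str, float]:
    """Absolute concentration of every subpopulation for one participant.

    Phenotypes gated in both tubes (t_cells, cd4/cd8 totals) are reported
    from the TruCOUNT tube, the direct bead-calibrated measurement.
    Returns NaN for Falcon phenotypes when the Falcon CD3 gate is empty.
    """
    if trucount_result.tube != TRUCOUNT:
        raise ValueError("first argument must be the TruCOUNT tube result")
    conc: dict[str, float] = {}
    for name, n in trucount_result.counts.items():
        if name == "leukocytes":
            continue
        conc[name] = trucount_concentration(n, cal)
    cd3_conc = conc["t_cells"]
    cd3_falcon = falcon_result.counts.get("t_cells", 0)
    for name, n in falcon_result.counts.items():
        if name in conc:
            continue
        if cd3_falcon <= 0:
            conc[name] = float("nan")
        else:
            conc[name] = falcon_scaling(n, cd3_falcon, cd3_conc)
    return conc


def build_count_matrix(per_participant: dict[str, dict[str, float]]
                       ) -> pd.DataFrame:
    """participants x 37 phenotypes matrix of cells/µL."""
    cols = subpopulation_names()
    cm = pd.DataFrame.from_dict(per_participant, orient="index")
    cm.index.name = "participant_id"
    return cm.reindex(columns=cols)


def compute_proportions(cm: pd.DataFrame,
                        parent_map: dict[str, str] | None = None
                        ) -> pd.DataFrame:
    """Each subpopulation as % of its designated parent lineage.

    Top-level lineages (parent ``leukocytes``) have no measured parent
    column and are omitted.  A zero or missing parent yields NaN.
    """
    parent_map = PROPORTION_PARENT if parent_map is None else parent_map
    out = {}
    for child, parent in parent_map.items():
        if child not in cm.columns or parent not in cm.columns:
            continue
        denom = cm[parent].where(cm[parent] > 0)
        out[child] = 100.0 * cm[child] / denom
    return pd.DataFrame(out, index=cm.index)


def apply_exclusions(cm: pd.DataFrame,
                     flags: dict[str, list[str]]) -> pd.DataFrame:
    """Blank lineages judged indistinguishable from debris.

    ``flags`` maps participant id -> list of flagged lineages (keys of
    LINEAGE_MEMBERS); every subpopulation of a flagged lineage is set
    missing for that participant.
    """
    cm = cm.copy()
    n_by_lineage: dict[str, int] = {}
    for pid, lineages in flags.items():
        if pid not in cm.index:
            raise KeyError(f"unknown participant {pid!r}")
        for lineage in lineages:
            if lineage not in LINEAGE_MEMBERS:
                raise KeyError(f"unknown lineage {lineage!r}")
            members = [m for m in LINEAGE_MEMBERS[lineage]
                       if m in cm.columns]
            cm.loc[pid, members] = np.nan
            n_by_lineage[lineage] = n_by_lineage.get(lineage, 0) + 1
    for lineage, n in sorted(n_by_lineage.items()):
        log.info("excluded %s data for %d participant(s)", lineage, n)
    return cm
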