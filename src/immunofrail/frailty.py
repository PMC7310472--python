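"""Deficit-accumulation (Rockwood-type) frailty index over 36 health items.

The index is the mean of 36 deficit items, each scored in [0, 1], so it runs
from 0 (no deficits) to 1 (all deficits present).  A square-root transform
symmetrizes its typically right-skewed distribution for regression use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

N_DEFICITS = 36

#: Minimum number of observed items required to score an incomplete record.
MIN_OBSERVED_ITEMS = 30


def frailty_index(deficits, min_observed: int = MIN_OBSERVED_ITEMS) -> float:
    """Mean of the 36 deficit items (NaN-tolerant up to ``min_observed``).

    Items must lie in [0, 1]; graded severities are allowed.  If fewer than
    ``min_observed`` items are non-missing the index is missing.
    """
    d = np.asarray(deficits, dtype=float)
    if d.shape != (N_DEFICITS,):
        raise ValueError(
            f"expected exactly {N_DEFICITS} deficit items, got {d.shape}")
    observed = ~np.isnan(d)
    if ((d[observed] < 0) | (d[observed] > 1)).any():
        raise ValueError("deficit items must lie in [0, 1]")
    if observed.sum() < min_observed:
        return float("nan")
    return float(d[observed].mean())


def sqrt_transform(index):
    """Square-root of the frailty index: monotone, rank-preserving."""
    return np.sqrt(index)


def analysis_set(cohort: pd.DataFrame) -> pd.DataFrame:
    """Participants eligible for frailty analyses (frailty index observed).

    Sex and CMV association sets are unaffected by this filter; it applies
    only to analyses involving the frailty index.
    """
    if "frailty_index" not in cohort.columns:
        raise KeyError("cohort table lacks a 'frailty_index' column")
    kept = cohort[cohort["frailty_index"].notna()]
    if kept.empty:
        warnings.warn("all participants lack a frailty index; "
                      "frailty analysis set is empty", stacklevel=2)
    return kept
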