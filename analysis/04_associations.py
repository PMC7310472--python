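#!/usr/bin/env python
"""Blocked permutation association studies with BH control at FDR 15%.

Five studies on two scales: subpopulations vs sex (blocked on age x CMV),
vs CMV serostatus per sex (blocked on age), and vs the frailty index per
sex (weighted Spearman, blocked on age x CMV), on absolute counts and on
percentage-of-parent proportions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from immunofrail.association import run_association_study

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20160801
N_PERM = 5000


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv", index_col=0)
    cohort["cmv_status"] = pd.read_csv(
        OUT / "serostatus.csv", index_col=0)["cmv_status"]
    cm = pd.read_csv(OUT / "count_matrix.csv", index_col=0)
    props = pd.read_csv(OUT / "proportions.csv", index_col=0)

    frames = []
    for si, study in enumerate(("sex", "cmv_by_sex", "frailty_by_sex")):
        for ki, (scale, matrix) in enumerate(
                (("absolute", cm), ("proportion", props))):
            seed = int(np.random.SeedSequence(
                entropy=SEED, spawn_key=(3, 10 * si + ki)
            ).generate_state(1)[0] % 2**31)
            frames.append(run_association_study(
                matrix, cohort, study, scale=scale,
                n_perm=N_PERM, fdr_q=0.15, seed=seed,
                phenotypes=list(matrix.columns)))
    assoc = pd.concat(frames, ignore_index=True)
    assoc.to_csv(OUT / "associations.tsv", sep="\t", index=False)

    print(f"ran {assoc[['study', 'scale', 'stratum']].drop_duplicates().shape[0]}"
          f" study-strata x {assoc['phenotype'].nunique()} phenotypes "
          f"({N_PERM} permutations each)")
    hits = assoc[assoc["bh_reject"]]
    for (study, scale, stratum), grp in hits.groupby(
            ["study", "scale", "stratum"]):
        names = ", ".join(
            f"{r.phenotype}"
            + (f" (rho_w={r.weighted_rho:+.2f})"
               if r.weighted_rho is not None and not np.isnan(r.weighted_rho)
               else "")
            for r in grp.itertuples())
        print(f"  {study}/{scale}/{stratum}: BH-significant: {names}")
    if hits.empty:
        print("  no associations passed BH at FDR 15%")
    print(f"wrote {OUT / 'associations.tsv'}")


if __name__ == "__main__":
    main()
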