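#!/usr/bin/env python
"""Check the simulator against the family-genetics expectations: same-trait
offspring-parent PGS correlations near 0.5, near-zero spousal correlations,
and near-zero cross-trait correlations. Writes the full 18 x 18 PGS
correlation table."""
from pathlib import Path

import numpy as np
import pandas as pd

from methnurture import famsim

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pedigree, gt = famsim.simulate_families(
        2000, offspring_per_family=2, p_mz=0.0, n_loci=500, seed=2026
    )
    weights = famsim.draw_weights(gt, seed=2026)
    pgs = famsim.compute_true_pgs(gt, pedigree, weights)
    wide = pgs.pivot_table(index="individual_id", columns="trait", values="value")

    off = pedigree[pedigree["role"] == "offspring"]
    by_role = pedigree.set_index(["family_id", "role"])["individual_id"]
    mo = by_role.xs("mother", level="role").loc[off["family_id"]].to_numpy()
    fa = by_role.xs("father", level="role").loc[off["family_id"]].to_numpy()

    blocks = {
        "offspring": wide.loc[off["individual_id"]].reset_index(drop=True),
        "maternal": wide.loc[mo].reset_index(drop=True),
        "paternal": wide.loc[fa].reset_index(drop=True),
    }
    stacked = pd.concat(
        {role: df for role, df in blocks.items()}, axis=1
    )
    stacked.columns = [f"{t}_{r}" for r, t in stacked.columns]
    corr = stacked.corr()
    RESULTS.mkdir(exist_ok=True)
    corr.round(4).to_csv(RESULTS / "pgs_correlations.tsv", sep="\t")

    om = [corr.loc[f"{t}_offspring", f"{t}_maternal"] for t in famsim.TRAITS]
    op = [corr.loc[f"{t}_offspring", f"{t}_paternal"] for t in famsim.TRAITS]
    mp = [corr.loc[f"{t}_maternal", f"{t}_paternal"] for t in famsim.TRAITS]
    print("same-trait offspring-mother correlations:",
          np.round(om, 3), "mean", round(float(np.mean(om)), 3))
    print("same-trait offspring-father correlations:",
          np.round(op, 3), "mean", round(float(np.mean(op)), 3))
    print("same-trait mother-father (spousal) correlations:",
          np.round(mp, 3), "mean", round(float(np.mean(mp)), 3))
    print(f"wrote {RESULTS / 'pgs_correlations.tsv'}")


if __name__ == "__main__":
    main()
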