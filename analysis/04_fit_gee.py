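#!/usr/bin/env python
"""Fit the per-probe trio-PGS GEE (independence working structure,
family-clustered sandwich SEs) across the analysis-ready probes and write
the full coefficient/SE/p table."""
from pathlib import Path

import pandas as pd

from methnurture import geefit, methprep
from methnurture.pipeline import RunConfig

RUN = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = RunConfig.from_yaml(RUN / "config_resolved.yaml")
    mm = methprep.read_methyl_tsv(RUN / "beta_residualized_selected.tsv",
                                  state="residualized")
    pgs = pd.read_csv(RUN / "pgs_prepared.tsv", sep="\t")
    pedigree = pd.read_csv(RUN / "pedigree.tsv", sep="\t")
    covariates = pd.read_csv(RUN / "covariates.tsv", sep="\t", index_col=0)

    design = geefit.build_design(pgs, pedigree, covariates)
    mm = methprep.MethylMatrix(mm.values.loc[design.X.index], state="residualized")
    results = geefit.fit_all(mm, design, working=cfg.working)
    results.table.to_csv(RUN / "gee_results.tsv", sep="\t")

    print(f"design: {design.X.shape[0]} offspring x {design.X.shape[1]} columns, "
          f"{len(set(design.clusters))} family clusters")
    print(f"fitted {results.n_probes} probes: {results.n_converged} successful, "
          f"{results.n_nonconverged} non-converged")
    print(f"wrote {RUN / 'gee_results.tsv'}")


if __name__ == "__main__":
    main()
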