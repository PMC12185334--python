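#!/usr/bin/env python
"""Prepare the 18 PGS predictors: residualize on platform dummies and 10
genetic PCs, standardize per trait x role, zero-impute missing parental
scores. Reports how many families required imputation."""
from pathlib import Path

import pandas as pd

from methnurture import pgsprep

RUN = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    pgs = pd.read_csv(RUN / "pgs_raw.tsv", sep="\t")
    covariates = pd.read_csv(RUN / "covariates.tsv", sep="\t", index_col=0)
    pgs = pgsprep.residualize_standardize(pgs, covariates)
    pgs = pgsprep.mean_impute_parent(pgs)
    pgs.to_csv(RUN / "pgs_prepared.tsv", sep="\t", index=False)

    imputed_people = pgs.loc[pgs["imputed"], "individual_id"].nunique()
    n_mo = pgs.loc[pgs["imputed"] & (pgs["role"] == "mother"), "individual_id"].nunique()
    n_fa = pgs.loc[pgs["imputed"] & (pgs["role"] == "father"), "individual_id"].nunique()
    print(f"standardized {pgs['trait'].nunique()} traits x 3 roles")
    print(f"zero-imputed PGSs for {imputed_people} parents "
          f"({n_mo} mothers, {n_fa} fathers)")
    print(f"wrote {RUN / 'pgs_prepared.tsv'}")


if __name__ == "__main__":
    main()
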