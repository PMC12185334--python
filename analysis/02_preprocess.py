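#!/usr/bin/env python
"""Preprocess the simulated beta-values: manifest QC, 3xIQR outlier masking,
mean imputation (probes >5% missing dropped), covariate residualization, and
top-10% variance selection. Writes the analysis-ready residual matrix."""
from pathlib import Path

import pandas as pd

from methnurture import methprep
from methnurture.pipeline import RunConfig

RUN = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = RunConfig.from_yaml(RUN / "config_resolved.yaml")
    mm = methprep.read_methyl_tsv(RUN / "beta_raw.tsv")
    manifest = pd.read_csv(RUN / "manifest.tsv", sep="\t")
    covariates = pd.read_csv(RUN / "covariates.tsv", sep="\t", index_col=0)

    n0 = mm.n_probes
    mm = methprep.qc_filter(mm, manifest, min_success=cfg.min_success)
    n_qc = mm.n_probes
    mm, n_masked = methprep.mask_outliers_iqr(mm, k=cfg.iqr_k)
    mm = methprep.impute_missing(mm, max_missing=cfg.max_missing,
                                 method=cfg.impute_method)
    n_imp = mm.n_probes
    mm = methprep.residualize(mm, covariates.loc[mm.values.index],
                              formula=cfg.residualize_covariates)
    mm = methprep.select_top_variance(mm, q=cfg.top_q)
    methprep.write_methyl_tsv(mm, RUN / "beta_residualized_selected.tsv")

    print(f"probes: {n0} raw -> {n_qc} after QC -> {n_imp} after "
          f"missingness filter -> {mm.n_probes} in the top {cfg.top_q:.0%}")
    print(f"masked {n_masked} outlying values (k={cfg.iqr_k})")
    print(f"wrote {RUN / 'beta_residualized_selected.tsv'}")


if __name__ == "__main__":
    main()
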