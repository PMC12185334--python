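#!/usr/bin/env python
"""Effective number of independent tests by spectral decomposition of the
probe correlation matrix, and the resulting Bonferroni threshold."""
from pathlib import Path

import pandas as pd

from methnurture import methprep, multitest
from methnurture.pipeline import RunConfig

RUN = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = RunConfig.from_yaml(RUN / "config_resolved.yaml")
    mm = methprep.read_methyl_tsv(RUN / "beta_residualized_selected.tsv",
                                  state="residualized")
    meff = multitest.effective_tests_nyholt(mm, method=cfg.meff_method)
    alpha = meff.alpha(cfg.global_alpha)

    (RUN / "meff.txt").write_text(
        f"m_probes\t{meff.m_probes}\nm_eff\t{meff.m_eff:.6f}\n"
        f"m_eff_int\t{meff.m_eff_int}\nalpha\t{alpha:.6e}\n"
    )
    pd.DataFrame({"eigenvalue": meff.eigenvalues}).to_csv(
        RUN / "eigenvalues.tsv", sep="\t", index=False
    )
    print(f"{meff.m_probes} correlated probes reduce to "
          f"{meff.m_eff_int} independent tests ({cfg.meff_method})")
    print(f"adjusted significance level: {cfg.global_alpha}/{meff.m_eff_int} "
          f"= {alpha:.2e}")


if __name__ == "__main__":
    main()
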