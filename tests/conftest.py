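import numpy as np
import pandas as pd
import pytest

from methnurture import famsim


@pytest.fixture(scope="session")
def small_families():
    """200 DZ/MZ families, 80 loci — shared across tests that only need a
    plausible pedigree/genotype/PGS/covariate bundle."""
    pedigree, genotypes = famsim.simulate_families(
        200, offspring_per_family=2, p_mz=0.5, n_loci=80, seed=11
    )
    weights = famsim.draw_weights(genotypes, seed=11)
    pgs = famsim.compute_true_pgs(genotypes, pedigree, weights)
    covariates = famsim.simulate_covariates(pedigree, seed=11)
    return {
        "pedigree": pedigree,
        "genotypes": genotypes,
        "weights": weights,
        "pgs": pgs,
        "covariates": covariates,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_manifest(probe_ids, **overrides):
    """All-clean manifest for a list of probes; override columns as needed."""
    m = len(probe_ids)
    man = pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "chromosome": ["1"] * m,
            "position": np.arange(1, m + 1) * 1000,
            "cross_reactive": [False] * m,
            "snp_overlap": [False] * m,
            "sex_chromosome": [False] * m,
            "success_rate": [1.0] * m,
        }
    )
    for k, v in overrides.items():
        man[k] = v
    return man
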