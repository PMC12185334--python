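"""Synthetic nuclear twin-family generator with known direct and indirect effects.

Simulates the family design needed to separate direct genetic effects (the
offspring's own polygenic score, PGS) from genetic nurture (parental PGSs
acting through the rearing environment) on offspring DNA methylation:

* parents drawn in Hardy-Weinberg proportions at unlinked biallelic loci,
  offspring genomes by Mendelian transmission (one allele per locus per
  parent), monozygotic (MZ) co-twins sharing one genome;
* true polygenic scores as weighted dosage sums, standardized within
  generation — under random mating the same-trait parent-offspring PGS
  correlation converges to 0.5;
* covariates mirroring a buccal EPIC-array study (sex, age, epithelial and
  natural-killer cell proportions, array row, bisulfite plate, dataset,
  10 genetic PCs, genotyping-platform dummies);
* methylation beta-values generated as the inverse logit of a Gaussian
  liability carrying sparse direct (delta), maternal (alpha_m) and paternal
  (alpha_p) PGS effects, covariate effects, a family-level random intercept
  (the source of family clustering) and residual noise;
* missing parental PGSs in a configurable subset of families.

All randomness flows from one master seed fanned out into named substreams,
so e.g. adding probes does not perturb genotypes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

TRAITS: tuple[str, ...] = (
    "schizophrenia",
    "smoking_initiation",
    "educational_attainment",
    "social_deprivation",
    "bmi",
    "height",
)
ROLES: tuple[str, ...] = ("offspring", "mother", "father")

#: share of offspring methylation arrays run in each of the three datasets
DATASET_PROBS: tuple[float, float, float] = (0.06, 0.75, 0.19)

#: default marginal probabilities that a family is missing the maternal /
#: paternal PGS, and the joint probability that both are missing
P_MISSING_MOTHER = 0.079
P_MISSING_FATHER = 0.189
P_MISSING_BOTH = 0.051

_STREAMS = {
    "genotypes": 0,
    "weights": 1,
    "covariates": 2,
    "methylation": 3,
    "missingness": 4,
    "manifest": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the master seed (independent per component)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class GenotypeSet:
    """Biallelic dosages for every person at every simulated locus.

    ``loci`` holds one row per locus (locus_id, freq); ``dosages`` is a
    person x locus DataFrame of allele counts in {0, 1, 2}.
    """

    loci: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.loci["locus_id"].is_unique:
            raise ValueError("locus ids must be unique")
        if list(self.dosages.columns) != list(self.loci["locus_id"]):
            raise ValueError("dosage columns must match loci table order")


@dataclass
class EffectSpec:
    """Per-trait effect sizes on the liability scale for a set of causal probes."""

    trait: str
    delta: float = 0.0
    alpha_m: float = 0.0
    alpha_p: float = 0.0
    causal_probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")
        self.causal_probes = tuple(self.causal_probes)


@dataclass
class SimulationTruth:
    """Ground-truth generative parameters, kept for scoring downstream stages."""

    effect_specs: list[EffectSpec] = field(default_factory=list)
    mu: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    family_sd: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_specs"] = [dataclasses.asdict(e) for e in self.effect_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        d = dict(d)
        d["effect_specs"] = [EffectSpec(**e) for e in d.get("effect_specs", [])]
        return cls(**d)


def simulate_families(
    n_families: int,
    offspring_per_family: int = 2,
    p_mz: float = 0.5,
    n_loci: int = 100,
    seed: int = 0,
    allele_freq_range: tuple[float, float] = (0.05, 0.95),
    dataset_probs: tuple[float, float, float] = DATASET_PROBS,
    spousal_assortment: float = 0.0,
) -> tuple[pd.DataFrame, GenotypeSet]:
    """Simulate nuclear twin families: pedigree plus genotype dosages.

    Parents are drawn in Hardy-Weinberg proportions (Binomial(2, freq)) at
    each locus under random mating; each offspring receives one allele per
    locus from each parent, the transmitted allele being a fair draw from the
    parent's two. With probability ``p_mz`` a family's offspring are MZ and
    share the first offspring's genome; otherwise they are DZ siblings.

    ``spousal_assortment`` > 0 copies the mother's dosage into the father at
    that fraction of loci (a crude per-locus assortment knob, default off).

    Returns a pedigree DataFrame (family_id, individual_id, role, zygosity,
    dataset) and a :class:`GenotypeSet`.
    """
    if n_families < 1 or n_loci < 1 or offspring_per_family < 1:
        raise ValueError("n_families, n_loci and offspring_per_family must be >= 1")
    if not 0 <= p_mz <= 1:
        raise ValueError("p_mz must be in [0, 1]")
    if not 0 <= spousal_assortment <= 1:
        raise ValueError("spousal_assortment must be in [0, 1]")

    rng = _rng(seed, "genotypes")
    lo, hi = allele_freq_range
    freqs = rng.uniform(lo, hi, size=n_loci)
    loci = pd.DataFrame(
        {"locus_id": [f"rs{i:06d}" for i in range(n_loci)], "freq": freqs}
    )

    mothers = rng.binomial(2, freqs, size=(n_families, n_loci))
    fathers = rng.binomial(2, freqs, size=(n_families, n_loci))
    if spousal_assortment > 0:
        copy = rng.random((n_families, n_loci)) < spousal_assortment
        fathers = np.where(copy, mothers, fathers)

    zyg_is_mz = rng.random(n_families) < p_mz
    if offspring_per_family < 2:
        zyg_is_mz[:] = False
    datasets = rng.choice([1, 2, 3], size=n_families, p=list(dataset_probs))

    # one allele from each parent; Bernoulli(dosage / 2) is exactly a fair
    # draw of one of the parent's two alleles
    off_dosages = []
    for j in range(offspring_per_family):
        if j == 0 or not zyg_is_mz.any():
            t_m = rng.binomial(1, mothers / 2.0)
            t_f = rng.binomial(1, fathers / 2.0)
            child = t_m + t_f
        else:
            t_m = rng.binomial(1, mothers / 2.0)
            t_f = rng.binomial(1, fathers / 2.0)
            child = np.where(zyg_is_mz[:, None], off_dosages[0], t_m + t_f)
        off_dosages.append(child)

    fam_ids = [f"fam{i:05d}" for i in range(n_families)]
    rows: list[tuple[str, str, str, str, int]] = []
    dosage_rows: list[np.ndarray] = []
    for i, fam in enumerate(fam_ids):
        zyg = "MZ" if zyg_is_mz[i] else ("DZ" if offspring_per_family >= 2 else "NA")
        rows.append((fam, f"{fam}_mo", "mother", "NA", int(datasets[i])))
        dosage_rows.append(mothers[i])
        rows.append((fam, f"{fam}_fa", "father", "NA", int(datasets[i])))
        dosage_rows.append(fathers[i])
        for j in range(offspring_per_family):
            rows.append((fam, f"{fam}_o{j + 1}", "offspring", zyg, int(datasets[i])))
            dosage_rows.append(off_dosages[j][i])

    pedigree = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "role", "zygosity", "dataset"]
    )
    dosages = pd.DataFrame(
        np.asarray(dosage_rows, dtype=np.int8),
        index=pedigree["individual_id"].to_numpy(),
        columns=loci["locus_id"].to_numpy(),
    )
    dosages.index.name = "individual_id"
    return pedigree, GenotypeSet(loci=loci, dosages=dosages)


def draw_weights(
    genotypes: GenotypeSet, traits: tuple[str, ...] = TRAITS, seed: int = 0
) -> pd.DataFrame:
    """Random standard-normal per-locus effect weights, one column per trait."""
    rng = _rng(seed, "weights")
    w = rng.standard_normal((len(genotypes.loci), len(traits)))
    return pd.DataFrame(w, index=genotypes.loci["locus_id"].to_numpy(), columns=list(traits))


def compute_true_pgs(
    genotypes: GenotypeSet, pedigree: pd.DataFrame, weights: pd.DataFrame
) -> pd.DataFrame:
    """Polygenic scores as weighted dosage sums, standardized within generation.

    Returns a long PGS table (individual_id, role, trait, value, missing) with
    z-scored values computed separately for the offspring and the parental
    generation, so each trait x generation cell has mean 0 and unit variance.
    """
    missing_loci = set(genotypes.dosages.columns) - set(weights.index)
    if missing_loci:
        raise ValueError(
            f"weights missing for {len(missing_loci)} loci, e.g. {sorted(missing_loci)[:3]}"
        )
    w = weights.loc[genotypes.dosages.columns]
    raw = genotypes.dosages.to_numpy(dtype=float) @ w.to_numpy()
    roles = pedigree.set_index("individual_id")["role"].loc[genotypes.dosages.index]
    is_offspring = (roles == "offspring").to_numpy()

    scaled = np.empty_like(raw)
    for gen_mask in (is_offspring, ~is_offspring):
        block = raw[gen_mask]
        sd = block.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [w.columns[k] for k in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance PGS cannot be standardized: {bad}")
        scaled[gen_mask] = (block - block.mean(axis=0)) / sd

    out = pd.DataFrame(scaled, index=genotypes.dosages.index, columns=w.columns)
    long = out.reset_index().melt(
        id_vars="individual_id", var_name="trait", value_name="value"
    )
    long["role"] = roles.loc[long["individual_id"]].to_numpy()
    long["missing"] = False
    return long[["individual_id", "role", "trait", "value", "missing"]]


def simulate_covariates(pedigree: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Covariates for every person; methylation-specific ones for offspring only.

    Offspring carry sex, age (years), epithelial and NK cell proportions,
    EPIC array row, bisulfite plate and dataset; everyone carries 10 genetic
    PCs and two genotyping-platform dummies. Parents' methylation covariates
    are left missing (parents have no methylation array in this design).
    """
    if len(pedigree) == 0:
        raise ValueError("pedigree is empty")
    rng = _rng(seed, "covariates")
    ped = pedigree.set_index("individual_id")
    n = len(ped)
    is_off = (ped["role"] == "offspring").to_numpy()
    n_off = int(is_off.sum())

    cov = pd.DataFrame(index=ped.index)
    sex = np.where(ped["role"] == "mother", "F", "M")
    sex[is_off] = np.where(rng.random(n_off) < 0.515, "M", "F")
    cov["sex"] = sex

    age = np.full(n, np.nan)
    age[is_off] = np.clip(rng.normal(10.0, 2.8, n_off), 1.0, 18.0)
    cov["age"] = age

    epi = np.full(n, np.nan)
    nk = np.full(n, np.nan)
    epi[is_off] = rng.beta(20.0, 4.0, n_off)
    nk[is_off] = rng.beta(2.0, 60.0, n_off)
    cov["prop_epithelial"] = epi
    cov["prop_nk"] = nk

    row = np.full(n, None, dtype=object)
    row[is_off] = [f"R{r + 1:02d}" for r in rng.integers(0, 8, n_off)]
    cov["array_row"] = row
    n_plates = max(1, int(np.ceil(n_off / 96)))
    plate = np.full(n, None, dtype=object)
    plate[is_off] = [f"P{p + 1:02d}" for p in rng.integers(0, n_plates, n_off)]
    cov["plate"] = plate
    cov["dataset"] = ped["dataset"].to_numpy()

    for k in range(10):
        cov[f"PC{k + 1}"] = rng.standard_normal(n)
    platform = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])
    cov["platform_2"] = (platform == 2).astype(int)
    cov["platform_3"] = (platform == 3).astype(int)
    cov.index.name = "individual_id"
    return cov


def simulate_manifest(
    probe_ids: list[str],
    seed: int = 0,
    p_cross_reactive: float = 0.02,
    p_snp_overlap: float = 0.03,
    p_sex_chromosome: float = 0.03,
) -> pd.DataFrame:
    """BED-like probe manifest with QC flags and per-probe success rates."""
    rng = _rng(seed, "manifest")
    m = len(probe_ids)
    chrom = rng.integers(1, 23, m).astype(object)
    sex_flag = rng.random(m) < p_sex_chromosome
    chrom[sex_flag] = rng.choice(["X", "Y"], size=int(sex_flag.sum()))
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom.astype(str),
            "position": rng.integers(1, 250_000_000, m),
            "cross_reactive": rng.random(m) < p_cross_reactive,
            "snp_overlap": rng.random(m) < p_snp_overlap,
            "sex_chromosome": sex_flag,
            "success_rate": 1.0 - rng.beta(1.0, 60.0, m),
        }
    )
    return manifest


def simulate_methylation(
    pedigree: pd.DataFrame,
    pgs: pd.DataFrame,
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    n_probes: int,
) -> tuple["MethylMatrix", SimulationTruth]:
    """Offspring beta-value matrix from the liability-scale generative model.

    Per offspring j in family i and probe c the liability is

        L = mu + sum_traits(delta * PGS_off + alpha_m * PGS_mother
                            + alpha_p * PGS_father)        [causal probes only]
            + sum_k beta_k * covariate_k + u_ic + e_ijc

    with u_ic ~ N(0, family_sd^2) shared by co-twins (the family clustering
    the downstream GEE corrects for) and e ~ N(0, noise_sd^2). Beta-values
    are the inverse logit of L, hence strictly inside (0, 1).
    """
    from .methprep import MethylMatrix  # local import to avoid a cycle

    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    probe_index = {p: k for k, p in enumerate(probe_ids)}
    for spec in truth.effect_specs:
        unknown = [p for p in spec.causal_probes if p not in probe_index]
        if unknown:
            raise ValueError(f"effect on unknown probe id(s): {unknown[:5]}")

    off = pedigree[pedigree["role"] == "offspring"]
    fam_of = off.set_index("individual_id")["family_id"]
    wide = pgs.pivot_table(index="individual_id", columns="trait", values="value")

    parent_ids = pedigree[pedigree["role"] != "offspring"].set_index(
        ["family_id", "role"]
    )["individual_id"]
    mother_of = parent_ids.xs("mother", level="role")
    father_of = parent_ids.xs("father", level="role")

    n = len(off)
    liab = np.full((n, n_probes), float(truth.mu))
    for spec in truth.effect_specs:
        if not spec.causal_probes:
            continue
        cols = [probe_index[p] for p in spec.causal_probes]
        contrib = (
            spec.delta * wide.loc[off["individual_id"], spec.trait].to_numpy()
            + spec.alpha_m
            * wide.loc[mother_of.loc[fam_of.loc[off["individual_id"]]].to_numpy(), spec.trait].to_numpy()
            + spec.alpha_p
            * wide.loc[father_of.loc[fam_of.loc[off["individual_id"]]].to_numpy(), spec.trait].to_numpy()
        )
        liab[:, cols] += contrib[:, None]

    for col, coef in truth.covariate_effects.items():
        vals = covariates.loc[off["individual_id"], col].to_numpy(dtype=float)
        liab += coef * vals[:, None]

    rng = _rng(truth.seed, "methylation")
    fams = off["family_id"].unique()
    fam_effects = rng.normal(0.0, truth.family_sd, size=(len(fams), n_probes))
    fam_pos = {f: k for k, f in enumerate(fams)}
    fam_idx = np.array([fam_pos[f] for f in off["family_id"]])
    liab += fam_effects[fam_idx]
    liab += rng.normal(0.0, truth.noise_sd, size=(n, n_probes))

    beta = pd.DataFrame(
        expit(liab), index=off["individual_id"].to_numpy(), columns=probe_ids
    )
    beta.index.name = "sample_id"
    return MethylMatrix(values=beta, state="raw"), truth


def apply_missingness(
    pgs: pd.DataFrame,
    pedigree: pd.DataFrame,
    p_missing_mother: float = P_MISSING_MOTHER,
    p_missing_father: float = P_MISSING_FATHER,
    p_missing_both: float = P_MISSING_BOTH,
    seed: int = 0,
) -> pd.DataFrame:
    """Blank out parental PGSs for a random subset of families.

    ``p_missing_mother`` / ``p_missing_father`` are marginal probabilities and
    ``p_missing_both`` the joint probability that a family lacks both parents'
    scores; masked entries get NaN values and missing=True across all traits.
    Offspring are never masked.
    """
    for p in (p_missing_mother, p_missing_father, p_missing_both):
        if not 0 <= p <= 1:
            raise ValueError("missingness probabilities must be in [0, 1]")
    if p_missing_both > min(p_missing_mother, p_missing_father):
        raise ValueError("p_missing_both cannot exceed either marginal probability")
    p_mo_only = p_missing_mother - p_missing_both
    p_fa_only = p_missing_father - p_missing_both
    p_none = 1.0 - p_mo_only - p_fa_only - p_missing_both
    if p_none < 0:
        raise ValueError("missingness probabilities jointly exceed 1")

    rng = _rng(seed, "missingness")
    fams = pedigree["family_id"].unique()
    cat = rng.choice(4, size=len(fams), p=[p_none, p_mo_only, p_fa_only, p_missing_both])
    mo_missing = set(fams[(cat == 1) | (cat == 3)])
    fa_missing = set(fams[(cat == 2) | (cat == 3)])

    fam_of = pedigree.set_index("individual_id")["family_id"]
    out = pgs.copy()
    fam_col = fam_of.loc[out["individual_id"]].to_numpy()
    mask = ((out["role"] == "mother") & pd.Series(fam_col).isin(mo_missing).to_numpy()) | (
        (out["role"] == "father") & pd.Series(fam_col).isin(fa_missing).to_numpy()
    )
    out.loc[mask, "value"] = np.nan
    out.loc[mask, "missing"] = True
    return out
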