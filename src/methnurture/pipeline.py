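"""End-to-end orchestration: simulate -> preprocess -> pgs-prep -> fit ->
correct -> report, driven by one YAML-serializable configuration.

Every run writes its resolved configuration next to the outputs and logs
probe/sample counts at every stage boundary, so a run directory is a
self-describing record. A single master seed fans out to per-component
substreams; re-running with the same config is bit-identical.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import famsim, geefit, methprep, multitest, pgsprep, report

logger = logging.getLogger("methnurture.pipeline")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # simulation
    n_families: int = 300
    offspring_per_family: int = 2
    p_mz: float = 0.5
    n_loci: int = 200
    n_probes: int = 1000
    family_sd: float = 0.5
    noise_sd: float = 0.5
    causal_trait: str = "schizophrenia"
    n_causal: int = 10
    delta: float = 0.3
    alpha_m: float = 0.2
    alpha_p: float = 0.1
    p_missing_mother: float = famsim.P_MISSING_MOTHER
    p_missing_father: float = famsim.P_MISSING_FATHER
    p_missing_both: float = famsim.P_MISSING_BOTH
    # preprocessing
    min_success: float = 0.95
    iqr_k: float = 3.0
    max_missing: float = 0.05
    impute_method: str = "mean"
    top_q: float = 0.10
    residualize_covariates: tuple = methprep.DEFAULT_RESIDUALIZE_COVARIATES
    # fitting / correction
    working: str = "independence"
    global_alpha: float = 0.05
    meff_method: str = "nyholt"

    def validate(self) -> None:
        if self.n_families < 1 or self.n_loci < 1 or self.n_probes < 1:
            raise ValueError("n_families, n_loci, n_probes must be >= 1")
        if not 0 < self.top_q <= 1:
            raise ValueError("top_q must be in (0, 1]")
        if not 0 < self.max_missing < 1:
            raise ValueError("max_missing must be in (0, 1)")
        if self.iqr_k <= 0:
            raise ValueError("iqr_k must be positive")
        if self.working not in ("independence", "exchangeable"):
            raise ValueError(f"unknown working structure {self.working!r}")
        if self.meff_method not in ("nyholt", "liji"):
            raise ValueError(f"unknown meff method {self.meff_method!r}")
        if not 0 < self.global_alpha < 1:
            raise ValueError("global_alpha must be in (0, 1)")
        if self.causal_trait not in famsim.TRAITS:
            raise ValueError(f"unknown causal trait {self.causal_trait!r}")
        if self.n_causal < 0 or self.n_causal > self.n_probes:
            raise ValueError("n_causal must be in [0, n_probes]")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["residualize_covariates"] = list(self.residualize_covariates)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "residualize_covariates" in d:
            d["residualize_covariates"] = tuple(d["residualize_covariates"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _setup_log(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("methnurture")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def simulate_stage(cfg: RunConfig, out: Path | None = None) -> dict:
    """Generate pedigree, genotypes, PGSs, covariates, manifest, methylation."""
    pedigree, genotypes = famsim.simulate_families(
        cfg.n_families,
        offspring_per_family=cfg.offspring_per_family,
        p_mz=cfg.p_mz,
        n_loci=cfg.n_loci,
        seed=cfg.seed,
    )
    weights = famsim.draw_weights(genotypes, seed=cfg.seed)
    pgs = famsim.compute_true_pgs(genotypes, pedigree, weights)
    covariates = famsim.simulate_covariates(pedigree, seed=cfg.seed)
    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    manifest = famsim.simulate_manifest(probe_ids, seed=cfg.seed)
    # causal probes are chosen among probes that survive QC flags so that
    # ground truth remains in the analysis set
    clean = manifest[
        ~(manifest["cross_reactive"] | manifest["snp_overlap"] | manifest["sex_chromosome"])
        & (manifest["success_rate"] >= cfg.min_success)
    ]["probe_id"].tolist()
    causal = tuple(clean[: cfg.n_causal])
    truth = famsim.SimulationTruth(
        effect_specs=[
            famsim.EffectSpec(
                trait=cfg.causal_trait,
                delta=cfg.delta,
                alpha_m=cfg.alpha_m,
                alpha_p=cfg.alpha_p,
                causal_probes=causal,
            )
        ],
        family_sd=cfg.family_sd,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    meth, truth = famsim.simulate_methylation(
        pedigree, pgs, covariates, truth, n_probes=cfg.n_probes
    )
    pgs = famsim.apply_missingness(
        pgs,
        pedigree,
        p_missing_mother=cfg.p_missing_mother,
        p_missing_father=cfg.p_missing_father,
        p_missing_both=cfg.p_missing_both,
        seed=cfg.seed,
    )
    stage = {
        "pedigree": pedigree,
        "genotypes": genotypes,
        "pgs": pgs,
        "covariates": covariates,
        "manifest": manifest,
        "meth": meth,
        "truth": truth,
    }
    if out is not None:
        pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
        genotypes.dosages.to_csv(out / "dosages.tsv", sep="\t")
        pgs.to_csv(out / "pgs_raw.tsv", sep="\t", index=False)
        covariates.to_csv(out / "covariates.tsv", sep="\t")
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        methprep.write_methyl_tsv(meth, out / "beta_raw.tsv")
        Path(out / "truth.yaml").write_text(yaml.safe_dump(truth.to_dict()))
    logger.info(
        "simulate: %d families, %d persons, %d probes",
        cfg.n_families, len(pedigree), cfg.n_probes,
    )
    return stage


def preprocess_stage(cfg: RunConfig, meth, manifest, covariates, out: Path | None = None):
    """QC-filter, mask outliers, impute, residualize, select top variance."""
    n0 = meth.n_probes
    meth = methprep.qc_filter(meth, manifest, min_success=cfg.min_success)
    logger.info("stage qc_filter: total=%d retained=%d dropped=%d",
                n0, meth.n_probes, n0 - meth.n_probes)
    meth, n_masked = methprep.mask_outliers_iqr(meth, k=cfg.iqr_k)
    logger.info("stage mask_outliers: masked=%d values", n_masked)
    n1 = meth.n_probes
    meth = methprep.impute_missing(meth, max_missing=cfg.max_missing, method=cfg.impute_method)
    logger.info("stage impute: total=%d retained=%d dropped=%d",
                n1, meth.n_probes, n1 - meth.n_probes)
    off_cov = covariates.loc[meth.values.index]
    meth = methprep.residualize(meth, off_cov, formula=cfg.residualize_covariates)
    n2 = meth.n_probes
    meth = methprep.select_top_variance(meth, q=cfg.top_q)
    logger.info("stage select_top_variance: total=%d retained=%d dropped=%d",
                n2, meth.n_probes, n2 - meth.n_probes)
    if out is not None:
        methprep.write_methyl_tsv(meth, out / "beta_residualized_selected.tsv")
    return meth


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns in-memory results and writes the
    run directory (stage TSVs, resolved config, log)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out)
    try:
        cfg.to_yaml(out / "config_resolved.yaml")
        sim = simulate_stage(cfg, out)
        meth = preprocess_stage(
            cfg, sim["meth"], sim["manifest"], sim["covariates"], out
        )
        pgs = pgsprep.residualize_standardize(sim["pgs"], sim["covariates"])
        pgs = pgsprep.mean_impute_parent(pgs)
        pgs.to_csv(out / "pgs_prepared.tsv", sep="\t", index=False)
        logger.info("pgs-prep: %d imputed parental entries", int(pgs["imputed"].sum()))

        design = geefit.build_design(pgs, sim["pedigree"], sim["covariates"])
        results = geefit.fit_all(meth, design, working=cfg.working)
        results.table.to_csv(out / "gee_results.tsv", sep="\t")
        logger.info(
            "fit: total=%d converged=%d nonconverged=%d",
            results.n_probes, results.n_converged, results.n_nonconverged,
        )

        meff = multitest.effective_tests_nyholt(meth, method=cfg.meff_method)
        alpha = meff.alpha(cfg.global_alpha)
        (out / "meff.txt").write_text(
            f"m_probes\t{meff.m_probes}\nm_eff\t{meff.m_eff:.6f}\n"
            f"m_eff_int\t{meff.m_eff_int}\nalpha\t{alpha:.6e}\n"
        )
        pd.DataFrame({"eigenvalue": meff.eigenvalues}).to_csv(
            out / "eigenvalues.tsv", sep="\t", index=False
        )
        logger.info("correct: m_eff=%.2f alpha=%.3e", meff.m_eff, alpha)

        hits = report.classify_hits(results, alpha, sim["manifest"])
        counts = report.count_by_role_trait(hits)
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        (out / "hit_counts.txt").write_text(report.counts_to_text(counts))
        report.chromosome_summary(hits).to_csv(
            out / "hits_by_chromosome.tsv", sep="\t", index=False
        )
        logger.info("report: %d hits (direct=%d indirect=%d)",
                    counts.total, counts.direct, counts.indirect)
        return {
            "config": cfg,
            "truth": sim["truth"],
            "meth": meth,
            "pgs": pgs,
            "design": design,
            "results": results,
            "meff": meff,
            "alpha": alpha,
            "hits": hits,
            "counts": counts,
        }
    finally:
        logging.getLogger("methnurture").removeHandler(handler)
        handler.close()
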