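"""Simulator correctness: Mendelian transmission, PGS calibration, covariate
structure, liability-scale methylation, and parental missingness."""
import numpy as np
import pandas as pd
import pytest

from methnurture import famsim


def _offspring_ids(pedigree):
    return pedigree.loc[pedigree["role"] == "offspring", "individual_id"]


class TestSimulateFamilies:
    def test_mz_twins_share_genome(self):
        pedigree, gt = famsim.simulate_families(
            1, offspring_per_family=2, p_mz=1.0, n_loci=50, seed=0
        )
        o1, o2 = _offspring_ids(pedigree)
        assert (gt.dosages.loc[o1] == gt.dosages.loc[o2]).all()
        assert set(pedigree.loc[pedigree["role"] == "offspring", "zygosity"]) == {"MZ"}

    def test_mendelian_consistency_exhaustive(self):
        """Every offspring dosage must be reachable as one allele from each
        parent — checked by enumerating compatible transmissions."""
        pedigree, gt = famsim.simulate_families(
            40, offspring_per_family=2, p_mz=0.3, n_loci=25, seed=5
        )
        ped = pedigree.set_index("individual_id")
        for fam, grp in pedigree.groupby("family_id"):
            mo = grp.loc[grp["role"] == "mother", "individual_id"].iloc[0]
            fa = grp.loc[grp["role"] == "father", "individual_id"].iloc[0]
            dm = gt.dosages.loc[mo].to_numpy()
            df_ = gt.dosages.loc[fa].to_numpy()
            for off in grp.loc[grp["role"] == "offspring", "individual_id"]:
                do = gt.dosages.loc[off].to_numpy()
                for m, f, o in zip(dm, df_, do):
                    tm = {0, 1} if m == 1 else {m // 2}
                    tf = {0, 1} if f == 1 else {f // 2}
                    assert o in {a + b for a in tm for b in tf}

    def test_offspring_allele_frequency_matches_parents(self):
        """Transmission is unbiased sampling: pooled offspring frequency per
        locus stays within 3 binomial SEs of the parental frequency."""
        pedigree, gt = famsim.simulate_families(
            2000, offspring_per_family=2, p_mz=0.0, n_loci=100, seed=2
        )
        is_off = pedigree.set_index("individual_id")["role"] == "offspring"
        off = gt.dosages.loc[is_off.to_numpy()]
        par = gt.dosages.loc[(~is_off).to_numpy()]
        f_par = par.mean(axis=0) / 2
        f_off = off.mean(axis=0) / 2
        n_alleles = 2 * len(off)
        se = np.sqrt(f_par * (1 - f_par) / n_alleles)
        frac_outside = np.mean(np.abs(f_off - f_par) > 3 * se)
        assert frac_outside < 0.05  # ~0.3% expected at 3 SE

    def test_dz_cotwin_dosage_correlation_half(self):
        """DZ siblings share half their alleles; per-locus dosage correlation
        approaches 0.5. Oracle: brute-force resampling of sibling pairs with
        the same transmission primitive at a fixed allele frequency."""
        pedigree, gt = famsim.simulate_families(
            2000, offspring_per_family=2, p_mz=0.0, n_loci=60, seed=3
        )
        off = gt.dosages.loc[_offspring_ids(pedigree)].to_numpy(dtype=float)
        twin1, twin2 = off[0::2], off[1::2]
        cors = [
            np.corrcoef(twin1[:, j], twin2[:, j])[0, 1] for j in range(off.shape[1])
        ]
        # independent brute-force oracle at p = 0.5
        r = np.random.default_rng(99)
        m = r.binomial(2, 0.5, 200_000)
        f = r.binomial(2, 0.5, 200_000)
        s1 = r.binomial(1, m / 2) + r.binomial(1, f / 2)
        s2 = r.binomial(1, m / 2) + r.binomial(1, f / 2)
        oracle = np.corrcoef(s1, s2)[0, 1]
        assert oracle == pytest.approx(0.5, abs=0.01)
        assert np.mean(cors) == pytest.approx(oracle, abs=0.02)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            famsim.simulate_families(0, n_loci=10)
        with pytest.raises(ValueError):
            famsim.simulate_families(5, n_loci=0)
        with pytest.raises(ValueError):
            famsim.simulate_families(5, n_loci=5, p_mz=1.5)

    def test_same_seed_bit_identical(self):
        a = famsim.simulate_families(30, n_loci=15, seed=42)
        b = famsim.simulate_families(30, n_loci=15, seed=42)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1].dosages, b[1].dosages)


class TestComputeTruePgs:
    def test_zero_weights_raise_on_scaling(self, small_families):
        gt = small_families["genotypes"]
        w = small_families["weights"] * 0.0
        with pytest.raises(ValueError, match="zero-variance"):
            famsim.compute_true_pgs(gt, small_families["pedigree"], w)

    def test_offspring_parent_correlation_half(self):
        """Parent transmits half the offspring genome, so same-trait
        parent-offspring PGS correlation converges to 0.5 under random mating."""
        pedigree, gt = famsim.simulate_families(
            1500, offspring_per_family=2, p_mz=0.0, n_loci=300, seed=8
        )
        w = famsim.draw_weights(gt, seed=8)
        pgs = famsim.compute_true_pgs(gt, pedigree, w)
        wide = pgs.pivot_table(index="individual_id", columns="trait", values="value")
        off = pedigree[pedigree["role"] == "offspring"]
        mo = pedigree[pedigree["role"] == "mother"].set_index("family_id")[
            "individual_id"
        ]
        trait = famsim.TRAITS[0]
        x = wide.loc[off["individual_id"], trait].to_numpy()
        y = wide.loc[mo.loc[off["family_id"]], trait].to_numpy()
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.5, abs=0.04)

    def test_spousal_correlation_null_under_random_mating(self, small_families):
        """Mother-father PGS correlation is compatible with the permutation
        null distribution of zero correlation."""
        pedigree, gt = famsim.simulate_families(
            1000, offspring_per_family=1, p_mz=0.0, n_loci=200, seed=9
        )
        w = famsim.draw_weights(gt, seed=9)
        pgs = famsim.compute_true_pgs(gt, pedigree, w)
        wide = pgs.pivot_table(index="individual_id", columns="trait", values="value")
        mo = pedigree[pedigree["role"] == "mother"].set_index("family_id")["individual_id"]
        fa = pedigree[pedigree["role"] == "father"].set_index("family_id")["individual_id"]
        trait = famsim.TRAITS[1]
        x = wide.loc[mo, trait].to_numpy()
        y = wide.loc[fa.loc[mo.index], trait].to_numpy()
        obs = np.corrcoef(x, y)[0, 1]
        r = np.random.default_rng(7)
        null = [np.corrcoef(x, r.permutation(y))[0, 1] for _ in range(500)]
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo < obs < hi

    def test_mz_cotwins_identical_pgs(self):
        pedigree, gt = famsim.simulate_families(
            20, offspring_per_family=2, p_mz=1.0, n_loci=40, seed=4
        )
        w = famsim.draw_weights(gt, seed=4)
        pgs = famsim.compute_true_pgs(gt, pedigree, w)
        wide = pgs.pivot_table(index="individual_id", columns="trait", values="value")
        off = _offspring_ids(pedigree).to_numpy()
        np.testing.assert_allclose(
            wide.loc[off[0::2]].to_numpy(), wide.loc[off[1::2]].to_numpy()
        )

    def test_standardized_within_generation(self, small_families):
        pgs = small_families["pgs"]
        for (trait, role), grp in pgs.groupby(["trait", "role"]):
            if role == "offspring":
                assert grp["value"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_locus_mismatch_raises(self, small_families):
        gt = small_families["genotypes"]
        w = small_families["weights"].iloc[:-5]
        with pytest.raises(ValueError, match="weights missing"):
            famsim.compute_true_pgs(gt, small_families["pedigree"], w)


class TestSimulateCovariates:
    def test_deterministic(self, small_families):
        ped = small_families["pedigree"]
        a = famsim.simulate_covariates(ped, seed=5)
        b = famsim.simulate_covariates(ped, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_cell_proportions_in_unit_interval(self, small_families):
        cov = small_families["covariates"]
        off = cov.dropna(subset=["prop_epithelial"])
        assert off["prop_epithelial"].between(0, 1).all()
        assert off["prop_nk"].between(0, 1).all()

    def test_offspring_carry_all_methylation_covariates(self, small_families):
        ped = small_families["pedigree"].set_index("individual_id")
        cov = small_families["covariates"]
        off = cov.loc[ped["role"] == "offspring"]
        for c in ["sex", "age", "prop_epithelial", "prop_nk", "array_row", "plate"]:
            assert off[c].notna().all()
        for c in [f"PC{i}" for i in range(1, 11)] + ["platform_2", "platform_3"]:
            assert cov[c].notna().all()

    def test_dataset_shares_match_multinomial(self):
        """Family dataset assignment follows the (0.06, 0.75, 0.19) mixture;
        empirical shares stay within 3 multinomial SEs at n = 10^4."""
        pedigree, _ = famsim.simulate_families(
            10_000, offspring_per_family=1, p_mz=0, n_loci=1, seed=6
        )
        fams = pedigree.drop_duplicates("family_id")
        n = len(fams)
        for ds, p in zip((1, 2, 3), famsim.DATASET_PROBS):
            share = (fams["dataset"] == ds).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(share - p) < 3 * se


class TestSimulateMethylation:
    def _meth(self, truth, n_probes=40, n_fam=150, seed=10):
        pedigree, gt = famsim.simulate_families(
            n_fam, offspring_per_family=2, p_mz=0.0, n_loci=30, seed=seed
        )
        w = famsim.draw_weights(gt, seed=seed)
        pgs = famsim.compute_true_pgs(gt, pedigree, w)
        cov = famsim.simulate_covariates(pedigree, seed=seed)
        return famsim.simulate_methylation(pedigree, pgs, cov, truth, n_probes)

    def test_null_model_gives_half(self):
        truth = famsim.SimulationTruth(family_sd=0.0, noise_sd=0.0, mu=0.0, seed=1)
        meth, _ = self._meth(truth)
        np.testing.assert_allclose(meth.values.to_numpy(), 0.5)

    def test_beta_values_strictly_inside_unit_interval(self):
        truth = famsim.SimulationTruth(family_sd=2.0, noise_sd=3.0, mu=1.0, seed=2)
        meth, _ = self._meth(truth)
        v = meth.values.to_numpy()
        assert (v > 0).all() and (v < 1).all()

    def test_within_family_liability_icc(self):
        """family_sd = noise_sd = 0.5 gives liability ICC = 0.25/(0.25+0.25)
        = 0.5; recovered from the logit of the beta-values."""
        truth = famsim.SimulationTruth(family_sd=0.5, noise_sd=0.5, seed=3)
        meth, _ = self._meth(truth, n_probes=150, n_fam=400)
        liab = np.log(meth.values / (1 - meth.values)).to_numpy()
        t1, t2 = liab[0::2].ravel(), liab[1::2].ravel()
        icc = np.corrcoef(t1, t2)[0, 1]
        assert icc == pytest.approx(0.5, abs=0.05)

    def test_unknown_causal_probe_raises(self):
        truth = famsim.SimulationTruth(
            effect_specs=[
                famsim.EffectSpec("height", delta=0.5, causal_probes=("cg99999999",))
            ],
            seed=4,
        )
        with pytest.raises(ValueError, match="unknown probe"):
            self._meth(truth, n_probes=10)

    def test_truth_round_trip(self):
        truth = famsim.SimulationTruth(
            effect_specs=[famsim.EffectSpec("bmi", delta=0.2, causal_probes=("cg00000001",))],
            family_sd=0.4,
            seed=5,
        )
        again = famsim.SimulationTruth.from_dict(truth.to_dict())
        assert again == truth


class TestApplyMissingness:
    def test_zero_probabilities_identity(self, small_families):
        pgs, ped = small_families["pgs"], small_families["pedigree"]
        out = famsim.apply_missingness(pgs, ped, 0, 0, 0, seed=1)
        pd.testing.assert_frame_equal(out, pgs)

    def test_both_missing_probability_one(self, small_families):
        pgs, ped = small_families["pgs"], small_families["pedigree"]
        out = famsim.apply_missingness(pgs, ped, 1, 1, 1, seed=1)
        parents = out[out["role"].isin(["mother", "father"])]
        assert parents["missing"].all()
        assert parents["value"].isna().all()
        off = out[out["role"] == "offspring"]
        assert not off["missing"].any()

    def test_both_present_fraction_matches_study_design(self):
        """Marginals 7.9% / 18.9% with joint both-missing 5.1% imply 78.3% of
        families have both parental PGSs, within 3 binomial SEs at n=10^4."""
        pedigree, gt = famsim.simulate_families(
            10_000, offspring_per_family=1, p_mz=0, n_loci=2, seed=12
        )
        w = famsim.draw_weights(gt, seed=12)
        pgs = famsim.compute_true_pgs(gt, pedigree, w)
        out = famsim.apply_missingness(pgs, pedigree, 0.079, 0.189, 0.051, seed=12)
        fam_of = pedigree.set_index("individual_id")["family_id"]
        parents = out[out["role"].isin(["mother", "father"])].copy()
        parents["family_id"] = fam_of.loc[parents["individual_id"]].to_numpy()
        both_present = (~parents.groupby("family_id")["missing"].any()).mean()
        expected = 1 - 0.079 - 0.189 + 0.051
        assert expected == pytest.approx(0.783, abs=1e-9)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(both_present - expected) < 3 * se

    def test_invalid_probabilities(self, small_families):
        pgs, ped = small_families["pgs"], small_families["pedigree"]
        with pytest.raises(ValueError):
            famsim.apply_missingness(pgs, ped, -0.1, 0.2, 0.0)
        with pytest.raises(ValueError):
            famsim.apply_missingness(pgs, ped, 0.1, 0.2, 0.15)
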