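"""Generator tests: founder draws, meiosis, PGIs, SES/rGE, outcomes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import famgxe as fg
from famgxe.cohort import (
    CITO_MU,
    CITO_SIGMA,
    CohortStructureError,
    assign_ses,
    compute_pgis,
    generate_outcomes,
    meiose_children,
    read_cohort,
    simulate_cohort,
    simulate_parents,
    validate_mendelian,
    write_cohort,
)
from famgxe.config import ConfigError


def gcols(cfg):
    return [f"g{l:03d}" for l in range(cfg.n_loci)]


class TestParents:
    def test_dosage_moments_at_half_frequency(self):
        # Binomial(2, 0.5): mean 1, variance 0.5
        cfg = fg.CohortConfig(
            n_families=2000, n_loci=1000, maf_low=0.5, maf_high=0.5, seed=1
        )
        par = simulate_parents(cfg)
        G = par[gcols(cfg)].to_numpy()
        n, L = G.shape
        mc_se_mean = np.sqrt(0.5 / n)
        # grand mean across loci, and per-locus 3-SE exceedances at the
        # multiplicity-expected rate (~0.3% of 1000 loci)
        assert abs(G.mean() - 1.0) < 3 * mc_se_mean / np.sqrt(L)
        assert np.mean(np.abs(G.mean(axis=0) - 1.0) > 3 * mc_se_mean) < 0.01
        mc_se_var = np.sqrt(2 * 0.25 / (n - 1))
        assert abs(G.var(axis=0).mean() - 0.5) < 3 * mc_se_var / np.sqrt(L)
        assert np.mean(np.abs(G.var(axis=0) - 0.5) > 3 * mc_se_var) < 0.01

    def test_degenerate_frequency_range_accepted(self):
        cfg = fg.CohortConfig(n_families=5, n_loci=3, maf_low=0.3, maf_high=0.3, seed=0)
        par = simulate_parents(cfg)
        assert len(par) == 10

    def test_empty_cohort_keeps_schema(self):
        cfg = fg.CohortConfig(n_families=0, seed=0)
        par = simulate_parents(cfg)
        assert len(par) == 0
        assert {"person_id", "family_id", "role", "zygosity"} <= set(par.columns)
        full = simulate_cohort(cfg)
        assert len(full) == 0 and "cito_z" in full.columns

    @pytest.mark.parametrize(
        "bad",
        [
            {"maf_low": 0.0},
            {"maf_low": 0.4, "maf_high": 0.2},
            {"maf_high": 0.6},
            {"ses_base_rate": 1.0},
            {"missing_genotype_rate": 1.0},
            {"rge_strength": -0.1},
            {"zygosity_mix": {"mz": 0.5, "dz": 0.4}},
        ],
    )
    def test_invalid_config_names_violated_bound(self, bad):
        with pytest.raises(ConfigError):
            fg.CohortConfig(seed=0, **bad).validate()


class TestMeiosis:
    def test_forced_transmission_from_homozygote(self):
        cfg = fg.CohortConfig(
            n_families=50, n_loci=5, missing_genotype_rate=0.0, seed=3
        )
        par = simulate_parents(cfg)
        # force father dosage 0 at locus 0: every child's paternal allele is 0
        par.loc[par["role"] == "father", "g000"] = 0.0
        par.loc[par["role"] == "mother", "g000"] = 0.0
        kids = meiose_children(par, cfg)
        assert (kids["g000"] == 0).all()

    def test_mz_pairs_share_genotype_dz_do_not_necessarily(self, nomiss_cohort):
        ch = nomiss_cohort
        gc = [c for c in ch.columns if c.startswith("g") and c[1:].isdigit()]
        twins = ch[ch["role"].isin(["twin1", "twin2"])]
        for zyg, same in (("MZ", True),):
            sub = twins[twins["zygosity"] == zyg]
            for _, grp in sub.groupby("family_id"):
                assert (
                    np.array_equal(grp[gc].iloc[0].to_numpy(), grp[gc].iloc[1].to_numpy())
                    == same
                )

    def test_dz_cotwin_genotypic_correlation_half(self):
        # kinship closed form: E[corr] = 0.5 for full sibs under random mating
        cfg = fg.CohortConfig(
            n_families=10000,
            n_loci=1000,
            maf_low=0.5,
            maf_high=0.5,
            zygosity_mix={"dz": 1.0},
            missing_genotype_rate=0.0,
            seed=11,
        )
        par = simulate_parents(cfg)
        kids = meiose_children(par, cfg)
        gc = gcols(cfg)
        t1 = kids[kids["role"] == "twin1"].sort_values("family_id")[gc].to_numpy()
        t2 = kids[kids["role"] == "twin2"].sort_values("family_id")[gc].to_numpy()
        # per-locus correlation across families, averaged
        r = [np.corrcoef(t1[:, l], t2[:, l])[0, 1] for l in range(0, 1000, 50)]
        mc_se = (1 - 0.25) / np.sqrt(len(t1) * len(r))
        assert abs(np.mean(r) - 0.5) < 3 * mc_se

    def test_missing_parent_raises_structural_error(self):
        cfg = fg.CohortConfig(n_families=3, n_loci=2, seed=0)
        par = simulate_parents(cfg)
        par = par[~((par["family_id"] == 1) & (par["role"] == "mother"))]
        with pytest.raises(CohortStructureError):
            meiose_children(par, cfg)

    def test_mendelian_consistency_holds_on_simulated_cohorts(self, nomiss_cohort):
        validate_mendelian(nomiss_cohort)  # raises on violation

    def test_mendelian_validator_detects_violation(self, nomiss_cohort):
        bad = nomiss_cohort.copy()
        kid_idx = bad.index[bad["role"] == "twin1"][0]
        fam = bad.loc[kid_idx, "family_id"]
        bad.loc[bad["family_id"] == fam, "g000"] = 0.0
        bad.loc[kid_idx, "g000"] = 2.0
        with pytest.raises(CohortStructureError):
            validate_mendelian(bad)


class TestPgis:
    def test_child_reference_standardisation(self, small_cohort):
        kids = small_cohort[
            small_cohort["role"].isin(["twin1", "twin2", "sibling"])
            & small_cohort["genotyped"]
        ]
        for col in ("pgi_cog", "pgi_noncog"):
            assert abs(kids[col].mean()) < 1e-8
            assert abs(kids[col].var(ddof=0) - 1.0) < 1e-8

    def test_missing_genotype_gives_missing_pgi(self, small_cohort):
        masked = small_cohort[~small_cohort["genotyped"]]
        assert masked["pgi_cog"].isna().all()
        assert masked["pgi_cog_true"].notna().all()

    def test_mz_twins_identical_pgis(self, nomiss_cohort):
        mz = nomiss_cohort[
            (nomiss_cohort["zygosity"] == "MZ")
            & nomiss_cohort["role"].isin(["twin1", "twin2"])
        ]
        nun = mz.groupby("family_id")["pgi_cog"].nunique()
        assert (nun == 1).all()

    def test_child_midparent_correlation_root_half(self):
        # cov(child, midparent) = sigma^2/2, var(midparent) = sigma^2/2
        cfg = fg.CohortConfig(
            n_families=8000, n_loci=300, missing_genotype_rate=0.0, seed=23
        )
        ch = simulate_cohort(cfg, check_mendelian=False)
        par = ch[ch["role"].isin(["father", "mother"])].pivot(
            index="family_id", columns="role", values="pgi_cog_true",
        )
        mid = (par["father"] + par["mother"]) / 2
        t1 = ch[ch["role"] == "twin1"].set_index("family_id")["pgi_cog_true"]
        r = np.corrcoef(t1, mid.reindex(t1.index))[0, 1]
        mc_se = (1 - 0.5) / np.sqrt(len(t1))
        assert abs(r - 1 / np.sqrt(2)) < 3 * mc_se

    def test_zero_weight_vector_rejected(self, nomiss_cohort):
        cfg = fg.default_config(seed=0).replace(pgi_weights_scale=0.0)
        with pytest.raises(ConfigError):
            cfg.validate()


class TestSes:
    def test_no_rge_channel_gives_zero_pgi_ses_correlation(self):
        cfg = fg.CohortConfig(
            n_families=4000, rge_strength=0.0, missing_genotype_rate=0.0,
            n_loci=100, seed=5,
        )
        ch = simulate_cohort(cfg, check_mendelian=False)
        kids = ch[ch["role"] == "twin1"]
        r = np.corrcoef(kids["pgi_cog_true"], kids["ses"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(kids))

    def test_rge_induces_correlation_blocked_by_parental_pgis(self):
        # positive marginal child-PGI/SES correlation, but ~zero partial
        # association given both parents' PGIs (the trio identification
        # property: transmission is random conditional on parents)
        cfg = fg.CohortConfig(
            n_families=6000, rge_strength=0.5, missing_genotype_rate=0.0,
            n_loci=100, seed=6,
        )
        ch = simulate_cohort(cfg, check_mendelian=False)
        kids = ch[ch["role"] == "twin1"].set_index("family_id")
        par = ch[ch["role"].isin(["father", "mother"])]
        for pgi in ("pgi_cog_true", "pgi_noncog_true"):
            for role in ("father", "mother"):
                kids[f"{pgi}_{role}"] = (
                    par[par["role"] == role].set_index("family_id")[pgi]
                    .reindex(kids.index)
                )
        r_marg = np.corrcoef(kids["pgi_cog_true"], kids["ses"])[0, 1]
        assert r_marg > 0.08
        # partial: residualise both on the four parental PGIs
        Z = np.column_stack(
            [np.ones(len(kids))]
            + [kids[f"{p}_{r}"] for p in ("pgi_cog_true", "pgi_noncog_true")
               for r in ("father", "mother")]
        )
        def resid(v):
            b = np.linalg.lstsq(Z, v, rcond=None)[0]
            return v - Z @ b
        rp = np.corrcoef(
            resid(kids["pgi_cog_true"].to_numpy()),
            resid(kids["ses"].to_numpy()),
        )[0, 1]
        assert abs(rp) < 3 / np.sqrt(len(kids))

    def test_rge_dial_monotone(self):
        rs = []
        for strength in (0.0, 0.25, 0.5, 1.0):
            cfg = fg.CohortConfig(
                n_families=4000, rge_strength=strength,
                missing_genotype_rate=0.0, n_loci=60, seed=77,
            )
            ch = simulate_cohort(cfg, check_mendelian=False)
            kids = ch[ch["role"] == "twin1"]
            rs.append(np.corrcoef(kids["pgi_cog_true"], kids["ses"])[0, 1])
        assert all(b >= a - 0.01 for a, b in zip(rs, rs[1:]))

    def test_high_ses_share_matches_target_rate(self):
        cfg = fg.CohortConfig(
            n_families=8000, ses_base_rate=0.41, missing_genotype_rate=0.0,
            n_loci=60, seed=8,
        )
        ch = simulate_cohort(cfg, check_mendelian=False)
        share = ch.groupby("family_id")["ses"].first().mean()
        assert abs(share - 0.41) < 3 * np.sqrt(0.41 * 0.59 / 8000)

    def test_dominance_rule(self, small_cohort):
        assert (
            small_cohort["ses"]
            == np.maximum(small_cohort["educ_father"], small_cohort["educ_mother"])
        ).all()


class TestOutcomes:
    def test_null_model_outcomes_independent_of_pgi_and_ses(self):
        eff = {
            k: fg.OutcomeEffects(
                beta_cog=0, beta_noncog=0, beta_ses=0, gamma_cog=0,
                gamma_noncog=0, family_sd=0.0, noise_sd=1.0,
            )
            for k in fg.OUTCOMES
        }
        cfg = fg.CohortConfig(
            n_families=4000, effects=eff, missing_genotype_rate=0.0,
            n_loci=60, seed=9,
        )
        ch = simulate_cohort(cfg, check_mendelian=False)
        kids = ch[ch["role"] == "twin1"]
        for col in ("cito_z", "math7"):
            r = np.corrcoef(kids["pgi_cog_true"], kids[col])[0, 1]
            assert abs(r) < 3 / np.sqrt(len(kids))

    def test_cito_calibration_mean_and_sd(self):
        cfg = fg.default_config(scale=2.0, seed=10)
        ch = simulate_cohort(cfg, check_mendelian=False)
        kids = ch[ch["role"].isin(["twin1", "twin2", "sibling"])]
        assert abs(kids["cito_raw"].mean() - 538.9) < 0.25
        assert abs(kids["cito_raw"].std() - 9.0) < 0.25
        assert kids["cito_raw"].between(501, 550).all()

    def test_grade_scale_and_dispersion(self):
        cfg = fg.default_config(scale=2.0, seed=10)
        ch = simulate_cohort(cfg, check_mendelian=False)
        kids = ch[ch["role"].isin(["twin1", "twin2", "sibling"])]
        for g in ("math7", "read7", "math10", "read10"):
            assert set(kids[g].unique()) <= {1.0, 2.0, 3.0, 4.0, 5.0}
            assert abs(kids[g].std() - 0.9) < 0.05

    def test_binary_prevalences_near_targets(self):
        cfg = fg.default_config(scale=2.0, seed=10)
        ch = simulate_cohort(cfg, check_mendelian=False)
        kids = ch[ch["role"].isin(["twin1", "twin2", "sibling"])]
        assert abs(kids["track"].mean() - 0.5) < 0.03
        assert abs(kids["attain"].mean() - 0.35) < 0.03

    def test_nonfinite_effect_rejected(self):
        eff = fg.default_effects()
        eff["track"] = dataclasses.replace(eff["track"], beta_cog=float("nan"))
        with pytest.raises(ConfigError):
            fg.CohortConfig(effects=eff, seed=0).validate()


class TestReproducibilityAndIO:
    def test_identical_config_bitwise_identical_cohort(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        assert a.equals(b)

    def test_cohort_roundtrip(self, tmp_path, small_cohort):
        p = tmp_path / "cohort.tsv"
        write_cohort(small_cohort, p)
        back = read_cohort(p)
        assert len(back) == len(small_cohort)
        pd.testing.assert_frame_equal(
            back[["pgi_cog", "ses", "cito_z"]],
            small_cohort[["pgi_cog", "ses", "cito_z"]].reset_index(drop=True),
        )

    def test_scenario_roundtrip(self, tmp_path, small_config):
        p = tmp_path / "scenario.yaml"
        fg.write_scenario(small_config, p)
        back = fg.read_scenario(p)
        assert back == small_config
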