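"""Replication funnel, directional tests, twin LMM and conditional analysis."""

import numpy as np
import pandas as pd
import pytest

from meqtl import PlantedTruth, SimulationConfig, simulate_genotypes, simulate_probesets
from meqtl.lmm import CollinearityError, TwinLMM, conditional_scan, lmm_scan, lrt
from meqtl.replication import (
    ReplicationStudy,
    directional_test,
    find_proxy,
    harmonize_direction,
    match_probes,
    replication_rate_test,
)
from meqtl.simulate import make_funnel_fixture, simulate_twin_cohort
from meqtl.stats import ols_fit


def _twin_data(seed=21, n_pairs=40, noise_sd=0.3, family_sd=0.3, mz_extra_sd=0.2, n_probesets=4,
               maf_range=(0.3, 0.3), n_snps=30):
    cfg = SimulationConfig(
        n_snps=n_snps,
        n_probesets=n_probesets,
        seed=seed,
        chrom_length_bp=n_probesets * 1_100_000,
        noise_sd=noise_sd,
        family_sd=family_sd,
        mz_extra_sd=mz_extra_sd,
        n_replication_pairs=n_pairs,
        n_replication_unpaired=1,
        maf_range=maf_range,
    )
    panel = simulate_genotypes(cfg, n_samples=cfg.n_replication, sample_prefix="T")
    probesets, _ = simulate_probesets(cfg)
    betas, pheno = simulate_twin_cohort(panel, PlantedTruth({}), cfg, probesets)
    covs = pheno[["age", "batch", "bsc_conc", "bsc_eff"]].astype(float)
    return cfg, panel, probesets, betas, pheno, covs


class TestMatchProbes:
    @staticmethod
    def _hits():
        return pd.DataFrame(
            {"chrom": ["1"], "start": [10_000], "end": [10_200], "snp": ["lead1"], "beta": [0.1]},
            index=pd.Index(["PS1"], name="probeset"),
        )

    def test_closed_threshold_at_one_kb(self):
        cpgs = pd.DataFrame({"chrom": ["1"], "pos": [11_200]}, index=["cg1"])
        matched = match_probes(self._hits(), cpgs, max_dist=1000)
        assert list(matched.index) == ["PS1"]
        cpgs_far = pd.DataFrame({"chrom": ["1"], "pos": [11_201]}, index=["cg1"])
        assert len(match_probes(self._hits(), cpgs_far, max_dist=1000)) == 0

    def test_nearest_selected(self):
        cpgs = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [11_100, 10_300]}, index=["far", "near"]
        )
        matched = match_probes(self._hits(), cpgs)
        assert matched.loc["PS1", "cpg"] == "near"
        assert matched.loc["PS1", "distance"] == 100


class TestFindProxy:
    def test_lead_present_returned_directly(self):
        fx = make_funnel_fixture(0)
        hit = fx["hits"].iloc[0]
        snp, r2 = find_proxy(hit["snp"], fx["replication_panel"], fx["reference_panel"], hit)
        assert snp == hit["snp"] and r2 == 1.0

    def test_duplicate_column_proxy_found(self):
        fx = make_funnel_fixture(0)
        hit = fx["hits"].iloc[12]  # lead absent, perfect proxy present
        snp, r2 = find_proxy(hit["snp"], fx["replication_panel"], fx["reference_panel"], hit)
        assert snp is not None and snp != hit["snp"]
        assert r2 == pytest.approx(1.0)

    def test_low_ld_panel_returns_none(self):
        fx = make_funnel_fixture(0)
        hit = fx["hits"].iloc[20]  # only an uncorrelated SNP nearby
        snp, r2 = find_proxy(hit["snp"], fx["replication_panel"], fx["reference_panel"], hit)
        assert snp is None and r2 < 0.8


class TestDirectionalTest:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.0203, 0.0031, 2.91e-11), (0.0352, 0.007, 2.47e-07)],
    )
    def test_reported_concordant_pairs(self, beta, se, expected):
        assert directional_test(beta, se, +1) == pytest.approx(expected, rel=5e-3)

    def test_zero_effect_gives_half(self):
        assert directional_test(0.0, 0.1, +1) == 0.5
        assert directional_test(0.0, 0.1, -1) == 0.5

    def test_two_directions_sum_to_one(self, rng):
        for _ in range(20):
            b, s = rng.normal(), rng.uniform(0.01, 1)
            assert directional_test(b, s, +1) + directional_test(b, s, -1) == pytest.approx(
                1.0, abs=1e-15
            )

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            directional_test(0.1, 0.0, 1)


class TestHarmonization:
    def test_swapped_alleles_flip_direction(self):
        assert harmonize_direction(("A", "G"), ("A", "G"), +1) == +1
        assert harmonize_direction(("A", "G"), ("G", "A"), +1) == -1

    def test_strand_flip_resolved(self):
        assert harmonize_direction(("A", "G"), ("T", "C"), +1) == +1
        assert harmonize_direction(("A", "G"), ("C", "T"), +1) == -1

    def test_ambiguous_snp_needs_frequency_match(self):
        assert harmonize_direction(("A", "T"), ("A", "T"), +1) is None
        assert harmonize_direction(("A", "T"), ("A", "T"), +1, 0.2, 0.22) == +1
        assert harmonize_direction(("C", "G"), ("C", "G"), +1, 0.2, 0.45) is None

    def test_flip_invariance_of_replication_call(self):
        beta, se = 0.03, 0.01
        p_same = directional_test(beta, se, harmonize_direction(("A", "G"), ("A", "G"), +1))
        p_flip = directional_test(-beta, se, harmonize_direction(("A", "G"), ("G", "A"), +1))
        assert p_same == pytest.approx(p_flip, abs=1e-15)


class TestReplicationRate:
    def test_reported_binomial_p(self):
        assert replication_rate_test(5, 19) == pytest.approx(2.01e-3, rel=5e-3)

    def test_extremes(self):
        assert replication_rate_test(0, 19) == 1.0
        assert replication_rate_test(19, 19) == pytest.approx(0.05**19, rel=1e-9)


class TestFunnel:
    def test_deterministic_149_27_19(self):
        fx = make_funnel_fixture(0)
        res = ReplicationStudy(
            fx["hits"], fx["cpg_positions"], fx["replication_panel"], fx["reference_panel"]
        ).fit()
        assert res.funnel == (149, 27, 19)
        res2 = ReplicationStudy(
            fx["hits"], fx["cpg_positions"], fx["replication_panel"], fx["reference_panel"]
        ).fit()
        assert res2.funnel == res.funnel
        assert "149" in res.summary() and "27" in res.summary() and "19" in res.summary()


class TestTwinLMM:
    def test_zero_variance_components_match_ols_likelihood_ratio(self):
        """Singleton families (random effects vanish): LMM LRT equals OLS LR."""
        cfg, panel, probesets, betas, pheno, covs = _twin_data(
            family_sd=0.0, mz_extra_sd=0.0, seed=31
        )
        y = betas.values_frame.iloc[0].to_numpy()
        snp = panel.snps.index[0]
        exog = covs.copy()
        exog["dosage"] = panel.dosages[snp].to_numpy()
        # every sample its own family: the mixed model degenerates to OLS
        fam = np.arange(len(y)).astype(str)
        zyg = np.array(["DZ"] * len(y))
        full = TwinLMM(y, exog, fam, zyg).fit()
        null = TwinLMM(y, covs, fam, zyg).fit()
        stat, p = lrt(full, null)

        n = len(y)
        X0 = np.column_stack([np.ones(n), covs.to_numpy()])
        X1 = np.column_stack([X0, exog["dosage"].to_numpy()])
        rss0 = float(np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2))
        rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
        oracle = n * np.log(rss0 / rss1)
        assert stat == pytest.approx(oracle, abs=1e-6)

    def test_matches_general_mixed_model_software(self):
        """Family-intercept model agrees with statsmodels MixedLM under ML."""
        import statsmodels.api as sm

        cfg, panel, probesets, betas, pheno, covs = _twin_data(
            seed=32, family_sd=0.4, mz_extra_sd=0.0, noise_sd=0.3
        )
        y = betas.values_frame.iloc[1].to_numpy()
        exog = covs.copy()
        exog["dosage"] = panel.dosages[panel.snps.index[3]].to_numpy()
        zyg_all_dz = np.array(["DZ"] * len(y))
        ours = TwinLMM(y, exog, pheno["family"].to_numpy(), zyg_all_dz).fit()

        X = sm.add_constant(exog.to_numpy())
        ref = sm.MixedLM(y, X, groups=pheno["family"].to_numpy()).fit(reml=False)
        assert ours.params["dosage"] == pytest.approx(ref.params[5], abs=1e-4)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-3)
        assert ours.vcomp["family"] == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-3)

    def test_null_lrt_close_to_chisq1(self):
        """Quick null calibration; the full-scale check runs in acceptance."""
        stats_ = []
        for seed in range(2):
            cfg, panel, probesets, betas, pheno, covs = _twin_data(
                seed=40 + seed, n_probesets=4, n_snps=100, n_pairs=60
            )
            fam = pheno["family"].to_numpy()
            zyg = pheno["zygosity"].to_numpy()
            for i in range(4):
                y = betas.values_frame.iloc[i].to_numpy()
                null = TwinLMM(y, covs, fam, zyg).fit()
                for snp in panel.snps.index[:25]:
                    exog = covs.copy()
                    exog["dosage"] = panel.dosages[snp].to_numpy()
                    stat, _ = lrt(TwinLMM(y, exog, fam, zyg).fit(), null)
                    stats_.append(stat)
        q95 = np.quantile(stats_, 0.95)
        assert 2.8 <= q95 <= 5.2  # wide band for 200 tests; chi2(1) gives 3.84

    def test_planted_effect_detected_by_scan(self):
        detected = 0
        n_runs = 10
        for seed in range(n_runs):
            cfg, panel, probesets, betas, pheno, covs = _twin_data(
                seed=60 + seed, n_snps=12, n_probesets=1, noise_sd=0.3
            )
            snp = panel.snps.index[5]
            y = betas.values_frame.iloc[0].to_numpy() + 0.9 * panel.dosages[snp].to_numpy()
            table, n_failed = lmm_scan(
                y, panel, covs, pheno["family"].to_numpy(), pheno["zygosity"].to_numpy()
            )
            row = table.set_index("snp").loc[snp]
            detected += bool(row["significant"])
        assert detected >= int(0.95 * n_runs)

    def test_nonconvergent_or_constant_snps_flagged(self):
        cfg, panel, probesets, betas, pheno, covs = _twin_data(seed=33, n_snps=5)
        dosages = panel.dosages.copy()
        dosages[panel.snps.index[0]] = 1.0  # constant dosage cannot be tested
        from meqtl import GenotypePanel

        panel2 = GenotypePanel(panel.snps.copy(), dosages)
        y = betas.values_frame.iloc[0].to_numpy()
        table, n_failed = lmm_scan(
            y, panel2, covs, pheno["family"].to_numpy(), pheno["zygosity"].to_numpy()
        )
        assert n_failed >= 1
        assert panel.snps.index[0] not in set(table["snp"])


class TestConditionalScan:
    def test_duplicate_snp_collinearity_error(self):
        cfg, panel, probesets, betas, pheno, covs = _twin_data(seed=34)
        from meqtl import GenotypePanel

        snps = panel.snps.iloc[:2].copy()
        dosages = panel.dosages[snps.index].copy()
        dosages[snps.index[1]] = dosages[snps.index[0]]
        panel2 = GenotypePanel(snps, dosages)
        y = betas.values_frame.iloc[0].to_numpy()
        with pytest.raises(CollinearityError):
            conditional_scan(
                y, panel2, snps.index[0], snps.index[1], covs,
                pheno["family"].to_numpy(), pheno["zygosity"].to_numpy(),
            )

    def test_causal_survives_conditioning_null_does_not(self):
        cfg, panel, probesets, betas, pheno, covs = _twin_data(seed=35, n_snps=30)
        r2 = np.corrcoef(
            panel.dosages[panel.snps.index[0]], panel.dosages[panel.snps.index[-1]]
        )[0, 1] ** 2
        assert r2 < 0.2  # far apart: effectively independent
        a, b = panel.snps.index[0], panel.snps.index[-1]
        y = betas.values_frame.iloc[0].to_numpy() + 0.8 * panel.dosages[a].to_numpy()
        out = conditional_scan(
            y, panel, a, b, covs, pheno["family"].to_numpy(), pheno["zygosity"].to_numpy()
        )
        assert out[a]["p"] < 1e-4
        assert out[b]["p"] > 0.05

    def test_two_proxies_of_one_causal_mask_each_other(self):
        wins = 0
        for seed in range(5):
            cfg, panel, probesets, betas, pheno, covs = _twin_data(seed=70 + seed, n_snps=40)
            # build two highly correlated proxies of a latent causal dosage
            rng = np.random.default_rng(seed)
            n = len(pheno)
            causal = rng.binomial(2, 0.4, size=n).astype(float)
            proxy_a = causal.copy()
            proxy_b = causal.copy()
            # force a fixed number of discordant genotypes so r^2 ~ 0.9
            flip_idx = rng.choice(n, size=6, replace=False)
            proxy_b[flip_idx] = (causal[flip_idx] + 1) % 3
            from meqtl import GenotypePanel

            snps = pd.DataFrame(
                {"chrom": "1", "pos": [100, 200], "ref": "A", "alt": "G", "info": 1.0},
                index=["pa", "pb"],
            )
            panel2 = GenotypePanel(
                snps, pd.DataFrame({"pa": proxy_a, "pb": proxy_b}, index=pheno.index)
            )
            # effect sized to the beta-value scale: marginally detectable but
            # with little unique signal in either proxy beyond the other
            y = betas.values_frame.iloc[0].to_numpy() + 0.03 * causal
            out = conditional_scan(
                y, panel2, "pa", "pb", covs,
                pheno["family"].to_numpy(), pheno["zygosity"].to_numpy(),
            )
            if out["pa"]["p"] > 0.001 and out["pb"]["p"] > 0.001:
                wins += 1
        assert wins >= 4


class TestEndToEndReplication:
    def test_directional_calls_computed_from_twin_lmm(self):
        cfg, panel, probesets, betas, pheno, covs = _twin_data(
            seed=36, n_probesets=3, n_snps=60
        )
        # treat the probe sets as primary hits with leads inside the panel
        leads = [panel.snps.index[5], panel.snps.index[25], panel.snps.index[50]]
        hits = pd.DataFrame(
            {
                "chrom": probesets["chrom"],
                "start": probesets["start"],
                "end": probesets["end"],
                "snp": leads,
                "beta": [0.2, -0.1, 0.3],
            },
            index=probesets.index,
        )
        cpgs = pd.DataFrame(
            {"chrom": probesets["chrom"].to_numpy(), "pos": probesets["end"].to_numpy() + 300},
            index=pd.Index([f"cg{i}" for i in range(3)], name="cpg"),
        )
        meth = betas.values_frame.copy()
        meth.index = [f"cg{i}" for i in range(3)]
        res = ReplicationStudy(
            hits, cpgs, panel, panel, methylation=meth, phenotypes=pheno
        ).fit()
        assert res.funnel == (3, 3, 3)
        assert res.n_replicated is not None
        assert res.pairs["one_sided_p"].between(0, 1).all()
        assert res.rate_p == replication_rate_test(res.n_replicated, 3)
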