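"""End-to-end statistical calibration of the pipeline on synthetic cohorts.

These routines re-run whole pipeline stages under known conditions —
pure-null scans, planted cis effects, null twin cohorts — and measure
false-discovery behaviour, parameter recovery and test-statistic
calibration.  They back both the test suite and the reproduction
script.

Problem sizes default to desk-scale stand-ins for the study designs:
null scans use 2,000 probe sets with ~40-50 cis SNPs each at n = 38;
twin null calibration uses 2,000 likelihood-ratio tests at n = 181.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .lmm import TwinLMM, lrt
from .phenotype import _encode
from .scan import CisMeqtlScan
from .simulate import (
    PlantedTruth,
    SimulationConfig,
    simulate_genotypes,
    simulate_methylation,
    simulate_phenotypes,
    simulate_probesets,
    simulate_twin_cohort,
)

__all__ = [
    "null_scan_fdr",
    "planted_recovery",
    "lmm_lrt_null",
    "ols_oracle_max_delta",
    "storey_pi0_uniform_rate",
]

_COVARIATES = ["age", "sex", "metsyn"]


def _covariate_frame(pheno: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({c: _encode(pheno[c]) for c in _COVARIATES}, index=pheno.index)


def _scan_once(seed: int, n_probesets: int, n_snps: int, truth: PlantedTruth | None = None,
               noise_sd: float = 0.1, maf_range=(0.05, 0.5), planted_beta: float = 0.0,
               n_planted: int = 0):
    cfg = SimulationConfig(
        n_snps=n_snps, n_probesets=n_probesets, seed=seed, noise_sd=noise_sd,
        maf_range=maf_range,
    )
    panel = simulate_genotypes(cfg)
    probesets, _ = simulate_probesets(cfg)
    if truth is None:
        truth = (
            PlantedTruth.random(probesets, panel, n_planted, planted_beta, cfg)
            if n_planted
            else PlantedTruth({})
        )
    meth = simulate_methylation(panel, probesets, truth, cfg)
    pheno = simulate_phenotypes(cfg)
    res = CisMeqtlScan(
        meth, probesets, panel.emac_filtered(), covariates=_covariate_frame(pheno)
    ).fit()
    return res, truth


def null_scan_fdr(
    n_seeds: int = 50, n_probesets: int = 2000, n_snps: int = 100_000, base_seed: int = 0
) -> dict:
    """Empirical FDR of q <= 0.05 calls over pure-null genome scans.

    With no planted effects every discovery is false, so the empirical
    FDR over replicates is the fraction of scans reporting any hit.
    Under a complete null that event has probability ~ the FDR level
    itself (pooled BH/Storey rejects anything with probability ~ alpha),
    so a large replicate count is needed for a stable estimate; 50
    replicates is the default.
    """
    runs_with_hits = 0
    total_hits = 0
    for i in range(n_seeds):
        res, _ = _scan_once((base_seed + i) % 2**31, n_probesets, n_snps)
        runs_with_hits += int(len(res.hits) > 0)
        total_hits += len(res.hits)
    return {
        "empirical_fdr": runs_with_hits / n_seeds,
        "runs_with_hits": runs_with_hits,
        "total_false_hits": total_hits,
        "n_seeds": n_seeds,
    }


def planted_recovery(
    n_replicates: int = 100,
    n_planted: int = 5,
    noise_sd: float = 0.1,
    effect_multiple: float = 1.5,
    base_seed: int = 0,
) -> dict:
    """Coverage of the truth by +/- 2 se around the scan's estimate.

    Plants cis effects of ``effect_multiple * noise_sd`` at MAF-0.3
    SNPs in an n = 38 cohort and checks, per replicate, whether the
    association record of the planted (probe set, SNP) pair covers the
    true beta within two standard errors.
    """
    covered = total = 0
    beta = effect_multiple * noise_sd
    for i in range(n_replicates):
        res, truth = _scan_once(
            (base_seed + 10_000 + i) % 2**31, n_probesets=30, n_snps=1500,
            noise_sd=noise_sd, maf_range=(0.3, 0.3), planted_beta=beta,
            n_planted=n_planted,
        )
        assoc = res.associations.set_index(["probeset", "snp"])
        for ps, (snp, b_true) in truth.items():
            if (ps, snp) in assoc.index:
                rec = assoc.loc[(ps, snp)]
                total += 1
                covered += int(abs(rec["beta"] - b_true) <= 2 * rec["se"])
    return {"coverage": covered / total, "n_pairs": total}


def lmm_lrt_null(n_tests: int = 2000, n_pairs: int = 90, base_seed: int = 0) -> dict:
    """Null distribution of the twin-LMM likelihood-ratio statistic.

    Simulates twin cohorts with real family structure but no SNP
    effect, fits full/null mixed models per test and summarises the
    LRT statistics against the chi-square(1) reference.
    """
    per_cohort = 100
    n_cohorts = int(np.ceil(n_tests / per_cohort))
    lrts: list[float] = []
    for c in range(n_cohorts):
        cfg = SimulationConfig(
            n_snps=per_cohort, n_probesets=per_cohort, seed=(base_seed + 20_000 + c) % 2**31,
            chrom_length_bp=per_cohort * 1_100_000, noise_sd=0.3,
            n_replication_pairs=n_pairs, n_replication_unpaired=1, maf_range=(0.3, 0.3),
        )
        panel = simulate_genotypes(cfg, n_samples=cfg.n_replication, sample_prefix="T")
        probesets, _ = simulate_probesets(cfg)
        betas, pheno = simulate_twin_cohort(panel, PlantedTruth({}), cfg, probesets)
        covs = pheno[["age", "batch", "bsc_conc", "bsc_eff"]].astype(float)
        fam = pheno["family"].to_numpy()
        zyg = pheno["zygosity"].to_numpy()
        Y = betas.values_frame.to_numpy()
        snps = list(panel.snps.index)
        for i in range(per_cohort):
            if len(lrts) >= n_tests:
                break
            null_fit = TwinLMM(Y[i], covs, fam, zyg).fit()
            exog = covs.copy()
            exog["dosage"] = panel.dosages[snps[i]].to_numpy()
            full_fit = TwinLMM(Y[i], exog, fam, zyg).fit()
            stat, _ = lrt(full_fit, null_fit)
            lrts.append(stat)
    arr = np.asarray(lrts)
    return {
        "q95": float(np.quantile(arr, 0.95)),
        "mean": float(arr.mean()),
        "n_tests": int(arr.size),
    }


def ols_oracle_max_delta(n_designs: int = 1000, base_seed: int = 0) -> dict:
    """Max |beta difference| between ols_fit and a pseudoinverse oracle."""
    rng = np.random.default_rng(base_seed + 30_000)
    worst = 0.0
    for _ in range(n_designs):
        n = int(rng.integers(8, 40))
        k = int(rng.integers(0, 4))
        y = rng.normal(size=n)
        x = rng.normal(size=n)
        covs = rng.normal(size=(n, k)) if k else None
        fit = stats.ols_fit(y, x, covs)
        X = np.column_stack([np.ones(n), x] + ([covs] if covs is not None else []))
        beta_oracle = (np.linalg.pinv(X.T @ X) @ (X.T @ y))[1]
        worst = max(worst, abs(fit.beta - beta_oracle))
    return {"max_abs_delta_beta": worst, "n_designs": n_designs}


def storey_pi0_uniform_rate(
    n_runs: int = 100, m: int = 10_000, base_seed: int = 0
) -> dict:
    """Fraction of uniform-p runs whose pi0 estimate lands in [0.9, 1.0]."""
    in_range = 0
    pi0s = []
    for i in range(n_runs):
        rng = np.random.default_rng((base_seed + 40_000 + i) % 2**31)
        res = stats.storey_qvalues(rng.random(m))
        pi0s.append(res.pi0)
        in_range += int(0.9 <= res.pi0 <= 1.0)
    return {"rate_in_range": in_range / n_runs, "mean_pi0": float(np.mean(pi0s)), "n_runs": n_runs}
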