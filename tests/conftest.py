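"""Shared fixtures: one small synthetic primary cohort reused across tests."""

import numpy as np
import pandas as pd
import pytest

from meqtl import (
    CisMeqtlScan,
    PlantedTruth,
    SimulationConfig,
    simulate_genotypes,
    simulate_methylation,
    simulate_phenotypes,
    simulate_probesets,
)
from meqtl.phenotype import _encode


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_snps=600, n_probesets=20, seed=11, chrom_length_bp=22_000_000, noise_sd=0.1
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cfg = small_config
    panel = simulate_genotypes(cfg)
    probesets, probes = simulate_probesets(cfg)
    truth = PlantedTruth.random(probesets, panel, 3, 0.3, cfg, min_maf=0.1)
    meth = simulate_methylation(panel, probesets, truth, cfg)
    pheno = simulate_phenotypes(cfg)
    covs = pd.DataFrame(
        {c: _encode(pheno[c]) for c in ["age", "sex", "metsyn"]}, index=pheno.index
    )
    return {
        "config": cfg,
        "panel": panel,
        "probesets": probesets,
        "probes": probes,
        "truth": truth,
        "meth": meth,
        "pheno": pheno,
        "covs": covs,
    }


@pytest.fixture(scope="session")
def small_scan(small_cohort):
    return CisMeqtlScan(
        small_cohort["meth"],
        small_cohort["probesets"],
        small_cohort["panel"].emac_filtered(),
        covariates=small_cohort["covs"],
    ).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
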