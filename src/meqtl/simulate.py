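"""Synthetic cohort generator.

Emulates the two study designs the pipeline expects without any real
data: a 38-sample case/control cohort assayed in duplicate on DMH
chips (with 0%/100% calibration chips and chip-internal controls) and
a 181-sample female twin cohort with Illumina-27k-style beta values.
Genotypes carry block-LD via a sliding Gaussian copula; cis effects are
planted as dosage x beta shifts of the latent probe-set methylation.

Every stochastic operation derives its generator from the config seed
plus a stage-specific offset, so a fixed seed reproduces the cohorts
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import Chip, IntensityExperiment, MethylationMatrix
from .scan import GenotypePanel, cis_snps

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "ConfigurationError",
    "simulate_genotypes",
    "simulate_probesets",
    "simulate_phenotypes",
    "simulate_methylation",
    "simulate_dmh_experiment",
    "simulate_twin_cohort",
    "simulate_expression",
    "make_funnel_fixture",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# rng stage offsets: one independent stream per generation stage
_STAGE = {
    "genotypes": 0,
    "probesets": 1,
    "phenotypes": 2,
    "methylation": 3,
    "dmh": 4,
    "twin": 5,
    "expression": 6,
    "truth": 7,
}


@dataclass
class SimulationConfig:
    """Study-scale parameters for the synthetic cohorts.

    Defaults mirror the designs the pipeline targets: 38 unrelated
    primary samples (19 MetSyn cases / 19 controls), ~90 twin pairs
    plus one unpaired individual (181 replication samples), a ±500 kb
    cis window, and probe sets of 4-12 probes.
    """

    n_primary: int = 38
    n_replication_pairs: int = 90
    n_replication_unpaired: int = 1
    n_snps: int = 2000
    n_probesets: int = 100
    n_probes_per_set: int = 8
    window_bp: int = 500_000
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    ld_decay_bp: float = 20_000.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    noise_sd: float = 0.1
    batch_effects: dict[str, float] = field(
        default_factory=lambda: {"B1": 0.0, "B2": 0.02, "B3": -0.02}
    )
    seed: int = 0
    # geometry
    chrom: str = "1"
    chrom_length_bp: int | None = None
    # twin-cohort variance structure and fixed effects
    mz_fraction: float = 0.5
    family_sd: float = 0.3
    mz_extra_sd: float = 0.2
    twin_age_effect: float = 0.002
    twin_bsc_conc_effect: float = 0.001
    twin_bsc_eff_effect: float = 0.2
    # DMH intensity back-generation
    control_intensity: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "n_primary",
            "n_replication_pairs",
            "n_snps",
            "n_probesets",
            "n_probes_per_set",
            "window_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 4 <= self.n_probes_per_set <= 12:
            raise ConfigurationError("n_probes_per_set must be in [4, 12]")
        if self.ld_decay_bp < 0 or self.noise_sd < 0:
            raise ConfigurationError("ld_decay_bp and noise_sd must be non-negative")
        if self.chrom_length_bp is None:
            self.chrom_length_bp = max(self.n_probesets, 1) * 1_100_000

    @property
    def n_replication(self) -> int:
        return 2 * self.n_replication_pairs + self.n_replication_unpaired

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng((int(self.seed) + _STAGE[stage] * 1_000_003) % 2**31)


@dataclass
class PlantedTruth:
    """Ground truth: probe set -> (causal SNP, beta on the score scale)."""

    effects: dict[str, tuple[str, float]]

    def direction(self, probeset: str) -> int:
        return 1 if self.effects[probeset][1] >= 0 else -1

    def items(self):
        return self.effects.items()

    def validate(self, probesets: pd.DataFrame, panel: GenotypePanel, window: int) -> None:
        """Every planted SNP must lie within the cis window of its probe set."""
        for ps, (snp, _) in self.effects.items():
            if ps not in probesets.index:
                raise KeyError(f"unknown probe set {ps!r} in planted truth")
            if snp not in panel.snps.index:
                raise KeyError(f"unknown SNP {snp!r} in planted truth")
            if snp not in cis_snps(probesets.loc[ps], panel, window):
                raise ValueError(f"planted SNP {snp!r} outside cis window of {ps!r}")

    @classmethod
    def random(
        cls,
        probesets: pd.DataFrame,
        panel: GenotypePanel,
        n_effects: int,
        beta: float,
        config: SimulationConfig,
        min_maf: float = 0.0,
    ) -> "PlantedTruth":
        """Plant ``n_effects`` cis effects of size ``beta`` at random probe sets."""
        rng = config.rng("truth")
        effects: dict[str, tuple[str, float]] = {}
        maf = panel.maf
        candidates = list(probesets.index)
        rng.shuffle(candidates)
        for ps in candidates:
            if len(effects) >= n_effects:
                break
            snps = [s for s in cis_snps(probesets.loc[ps], panel, config.window_bp) if maf[s] >= min_maf]
            if snps:
                effects[ps] = (snps[rng.integers(len(snps))], float(beta))
        return cls(effects)


def simulate_genotypes(
    config: SimulationConfig, n_samples: int | None = None, sample_prefix: str = "S"
) -> GenotypePanel:
    """Dosage panel with copula LD decaying over ``ld_decay_bp``.

    Two latent haplotype Gaussians per sample follow an AR process along
    the chromosome with correlation exp(-d / ld_decay_bp) between
    neighbours; thresholding at the allele-frequency quantile yields
    0/1 alleles whose sum is the dosage.  Info scores are Uniform(0.3, 1].
    """
    rng = config.rng("genotypes")
    n = config.n_primary if n_samples is None else int(n_samples)
    m = config.n_snps
    pos = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=int(m * 1.05) + 8))
    while pos.size < m:  # top up on the rare collision-heavy draw
        pos = np.unique(np.concatenate([pos, rng.integers(1, config.chrom_length_bp + 1, size=m)]))
    pos = np.sort(rng.choice(pos, size=m, replace=False))
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    if config.ld_decay_bp > 0:
        rho = np.exp(-np.diff(pos) / config.ld_decay_bp)
    else:
        rho = np.zeros(m - 1)
    eps = rng.standard_normal((2 * n, m))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    sq = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        z[:, j] = rho[j - 1] * z[:, j - 1] + sq[j - 1] * eps[:, j]
    from scipy.stats import norm

    thresh = norm.ppf(maf)
    alleles = (z < thresh).astype(float)
    dosage = alleles[:n] + alleles[n:]

    width = len(str(m))
    snp_ids = [f"snp{str(i + 1).zfill(width)}" for i in range(m)]
    letters = np.array(list("ACGT"))
    ref = letters[rng.integers(0, 4, size=m)]
    alt = np.array([letters[(list(letters).index(r) + rng.integers(1, 4)) % 4] for r in ref])
    info = 1.0 - rng.uniform(0.0, 0.7, size=m)  # (0.3, 1.0]
    snps = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos, "ref": ref, "alt": alt, "info": info},
        index=pd.Index(snp_ids, name="snp"),
    )
    samples = [f"{sample_prefix}{str(i + 1).zfill(len(str(n)))}" for i in range(n)]
    dosages = pd.DataFrame(dosage, index=pd.Index(samples, name="sample"), columns=snp_ids)
    return GenotypePanel(snps, dosages)


def simulate_probesets(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-set intervals spread evenly along the chromosome, plus probes.

    Returns (probesets indexed by id with chrom/start/end/cls, probes
    indexed by probe id with probeset/chrom/pos).
    """
    rng = config.rng("probesets")
    P = config.n_probesets
    spacing = config.chrom_length_bp / P
    classes = np.array(["promoter", "gene_body", "dm_gene"])
    weights = np.array([13500.0, 13650.0, 430.0])
    rows, probe_rows = [], []
    width = len(str(P))
    for i in range(P):
        span = int(rng.integers(150, 251))
        center = int((i + 0.5) * spacing + rng.integers(-int(spacing // 10), int(spacing // 10) + 1))
        start = max(1, center - span // 2)
        end = start + span - 1
        ps_id = f"PS{str(i + 1).zfill(width)}"
        cls = classes[rng.choice(3, p=weights / weights.sum())]
        rows.append({"id": ps_id, "chrom": config.chrom, "start": start, "end": end, "cls": cls})
        ppos = np.sort(rng.choice(np.arange(start, end + 1), size=config.n_probes_per_set, replace=False))
        for k, p in enumerate(ppos):
            probe_rows.append(
                {"probe": f"{ps_id}_p{k + 1}", "probeset": ps_id, "chrom": config.chrom, "pos": int(p)}
            )
    probesets = pd.DataFrame(rows).set_index("id")
    probes = pd.DataFrame(probe_rows).set_index("probe")
    return probesets, probes


def simulate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Primary-cohort covariates: age, sex, MetSyn status, BMI.

    Half the cohort are MetSyn cases; ages ~ N(49, 5) in both groups,
    BMI higher in cases (N(32.4, 5.6)) than controls (N(26.6, 4.5)).
    """
    rng = config.rng("phenotypes")
    n = config.n_primary
    samples = [f"S{str(i + 1).zfill(len(str(n)))}" for i in range(n)]
    metsyn = np.zeros(n, dtype=int)
    metsyn[: n // 2] = 1
    sex = np.array(["M", "F"] * (n // 2 + 1))[:n]
    age = np.round(rng.normal(49, 5, size=n)).astype(int)
    bmi = np.where(metsyn == 1, rng.normal(32.4, 5.6, size=n), rng.normal(26.6, 4.5, size=n))
    return pd.DataFrame(
        {"age": age, "sex": sex, "metsyn": metsyn, "bmi": np.round(bmi, 1)},
        index=pd.Index(samples, name="sample"),
    )


def _baseline_levels(rng: np.random.Generator, n_probesets: int) -> np.ndarray:
    """Bimodal hypo/hyper baseline on the calibrated score scale."""
    hyper = rng.random(n_probesets) < 0.55
    return np.where(
        hyper, rng.normal(0.85, 0.05, n_probesets), rng.normal(0.15, 0.05, n_probesets)
    )


def simulate_methylation(
    panel: GenotypePanel,
    probesets: pd.DataFrame,
    truth: PlantedTruth,
    config: SimulationConfig,
    phenotype_effects: dict[str, tuple[pd.Series, float]] | None = None,
) -> MethylationMatrix:
    """Latent calibrated-scale methylation scores with planted cis effects.

    score = bimodal baseline + beta * dosage (planted pairs)
            [+ covariate effects] + N(0, noise_sd).
    """
    truth.validate(probesets, panel, config.window_bp)
    rng = config.rng("methylation")
    samples = list(panel.dosages.index)
    base = _baseline_levels(rng, len(probesets))
    M = base[:, None] + rng.normal(0.0, config.noise_sd, size=(len(probesets), len(samples)))
    idx = {ps: i for i, ps in enumerate(probesets.index)}
    for ps, (snp, beta) in truth.items():
        M[idx[ps]] += beta * panel.dosages[snp].to_numpy()
    if phenotype_effects:
        for ps, (values, beta) in phenotype_effects.items():
            M[idx[ps]] += beta * values.loc[samples].to_numpy(dtype=float)
    frame = pd.DataFrame(M, index=probesets.index, columns=samples)
    return MethylationMatrix(frame, stage="calibrated")


def simulate_dmh_experiment(
    panel: GenotypePanel,
    truth: PlantedTruth,
    config: SimulationConfig,
    probesets: pd.DataFrame | None = None,
    probes: pd.DataFrame | None = None,
    latent: MethylationMatrix | None = None,
) -> tuple[IntensityExperiment, pd.DataFrame, pd.DataFrame, MethylationMatrix]:
    """Back-generate duplicate-chip probe intensities from latent scores.

    Each probe set receives raw-score anchors (the 0% and 100% chip
    levels); a sample's raw score is anchor0 + span * latent + batch
    offset, and probe intensities are control_intensity * 2**raw with
    multiplicative log-normal noise of sd ``noise_sd`` (log2 scale).
    With noise_sd = 0 the two replicate chips of a sample are identical
    and the 0% chip is dimmer than the 100% chip at every probe.

    Returns (experiment, probesets, probes, latent matrix).
    """
    if probesets is None or probes is None:
        probesets, probes = simulate_probesets(config)
    if latent is None:
        latent = simulate_methylation(panel, probesets, truth, config)
    rng = config.rng("dmh")
    P = len(probesets)
    anchor0 = rng.normal(-0.2, 0.05, size=P)
    span = np.clip(rng.normal(1.6, 0.1, size=P), 0.5, None)
    anchor0_s = pd.Series(anchor0, index=probesets.index)
    span_s = pd.Series(span, index=probesets.index)

    batches = sorted(config.batch_effects) or ["B1"]
    probe_sets_of = probes["probeset"]
    n_controls = 20
    chips: list[Chip] = []

    def make_chip(chip_id, sample_id, replicate, batch, level: pd.Series, calibration=None):
        raw = anchor0_s + span_s * level + config.batch_effects.get(batch, 0.0)
        per_probe = raw.loc[probe_sets_of].to_numpy()
        noise = rng.normal(0.0, config.noise_sd, size=len(per_probe))
        intensities = config.control_intensity * 2.0 ** (per_probe + noise)
        ctrl = config.control_intensity * 2.0 ** rng.normal(0.0, config.noise_sd, size=n_controls)
        return Chip(
            chip_id=chip_id,
            sample_id=sample_id,
            replicate=replicate,
            batch=batch,
            probe_intensities=pd.Series(intensities, index=probes.index),
            control_intensities=ctrl,
            calibration=calibration,
        )

    # both replicate chips of a sample share a batch, so replicates are
    # exact duplicates when noise_sd = 0; samples rotate across batches
    for si, sample in enumerate(latent.samples):
        level = latent.values_frame[sample]
        batch = batches[si % len(batches)]
        for rep in (1, 2):
            chips.append(make_chip(f"{sample}_r{rep}", sample, rep, batch, level))
    zeros = pd.Series(0.0, index=probesets.index)
    ones = pd.Series(1.0, index=probesets.index)
    chips.append(make_chip("chip_0pct", None, 1, batches[0], zeros, calibration="0%"))
    chips.append(make_chip("chip_100pct", None, 1, batches[0], ones, calibration="100%"))
    return IntensityExperiment(chips), probesets, probes, latent


def simulate_twin_cohort(
    panel_rep: GenotypePanel,
    truth: PlantedTruth,
    config: SimulationConfig,
    probesets: pd.DataFrame | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Female twin replication cohort: beta values plus covariate table.

    The latent (logit-scale) score per probe set and sample is
    fixed covariate effects + family random intercept + an extra shared
    intercept for MZ pairs + planted SNP effect + residual noise; beta
    values are the logistic squashing of latent + a bimodal baseline
    offset.  One individual is unpaired, making the cohort size odd.
    """
    if probesets is None:
        probesets, _ = simulate_probesets(config)
    truth.validate(probesets, panel_rep, config.window_bp)
    rng = config.rng("twin")
    samples = list(panel_rep.dosages.index)
    n = len(samples)
    expected = config.n_replication
    if n != expected:
        raise ConfigurationError(
            f"replication panel has {n} samples, config implies {expected}"
        )

    n_pairs = config.n_replication_pairs
    family, zygosity, age = [], [], []
    fam_width = len(str(n_pairs + config.n_replication_unpaired))
    pair_age = np.round(rng.normal(61.1, 7.6, size=n_pairs + config.n_replication_unpaired))
    mz = rng.random(n_pairs) < config.mz_fraction
    for i in range(n_pairs):
        fid = f"F{str(i + 1).zfill(fam_width)}"
        z = "MZ" if mz[i] else "DZ"
        family += [fid, fid]
        zygosity += [z, z]
        age += [pair_age[i], pair_age[i]]
    for j in range(config.n_replication_unpaired):
        family.append(f"F{str(n_pairs + 1 + j).zfill(fam_width)}")
        zygosity.append("DZ")
        age.append(pair_age[n_pairs + j])

    batch = rng.integers(1, 4, size=n)
    bsc_conc = rng.normal(50.0, 10.0, size=n)
    bsc_eff = rng.uniform(0.85, 1.0, size=n)
    pheno = pd.DataFrame(
        {
            "age": np.asarray(age, dtype=float),
            "batch": batch,
            "bsc_conc": np.round(bsc_conc, 2),
            "bsc_eff": np.round(bsc_eff, 3),
            "family": family,
            "zygosity": zygosity,
        },
        index=pd.Index(samples, name="sample"),
    )

    P = len(probesets)
    baseline = np.where(rng.random(P) < 0.55, 2.0, -2.0)  # logit-scale bimodal baseline
    fixed = (
        config.twin_age_effect * (pheno["age"] - pheno["age"].mean())
        + config.batch_effects.get("B2", 0.02) * (pheno["batch"] - 2)
        + config.twin_bsc_conc_effect * (pheno["bsc_conc"] - 50.0)
        + config.twin_bsc_eff_effect * (pheno["bsc_eff"] - pheno["bsc_eff"].mean())
    ).to_numpy()

    fam_codes, fam_idx = np.unique(family, return_inverse=True)
    is_mz_family = np.zeros(len(fam_codes), dtype=bool)
    for code, z in zip(fam_idx, zygosity):
        if z == "MZ":
            is_mz_family[code] = True

    fam_int = rng.normal(0.0, config.family_sd, size=(P, len(fam_codes)))
    mz_int = rng.normal(0.0, config.mz_extra_sd, size=(P, len(fam_codes))) * is_mz_family
    latent = (
        baseline[:, None]
        + fixed[None, :]
        + fam_int[:, fam_idx]
        + mz_int[:, fam_idx]
        + rng.normal(0.0, config.noise_sd if config.noise_sd > 0 else 0.0, size=(P, n))
    )
    idx = {ps: i for i, ps in enumerate(probesets.index)}
    for ps, (snp, beta) in truth.items():
        latent[idx[ps]] += beta * panel_rep.dosages[snp].to_numpy()
    betas = expit(latent)
    frame = pd.DataFrame(betas, index=probesets.index, columns=samples)
    return MethylationMatrix(frame, stage="beta"), pheno


def simulate_expression(
    meth: MethylationMatrix,
    probesets: pd.DataFrame,
    config: SimulationConfig,
    links: dict[str, tuple[float, float]] | None = None,
    n_transcripts: int | None = None,
    expr_noise_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Transcript expression with planted negative methylation links.

    ``links`` maps probe-set id -> (slope > 0, intercept); a linked
    transcript's expression is intercept - slope * methylation + noise,
    and its TSS is placed just outside the probe set so nearest-TSS
    matching recovers the link.  Unlinked transcripts are independent
    noise at random TSS positions.

    Returns (expression transcripts x samples, transcript table with
    chrom/tss/strand, probe set -> transcript map).
    """
    rng = config.rng("expression")
    samples = meth.samples
    links = links or {}
    n_transcripts = n_transcripts if n_transcripts is not None else 2 * len(probesets)
    n_extra = max(n_transcripts - len(links), 0)
    rows, data, mapping = [], [], {}
    t = 0
    for ps, (slope, intercept) in links.items():
        t += 1
        tid = f"TX{t:05d}"
        mapping[ps] = tid
        row = probesets.loc[ps]
        tss = int(row["end"]) + int(rng.integers(200, 2000))
        rows.append({"transcript": tid, "chrom": row["chrom"], "tss": tss, "strand": "+"})
        m = meth.values_frame.loc[ps].to_numpy(dtype=float)
        data.append(intercept - slope * m + rng.normal(0.0, expr_noise_sd, size=len(samples)))
    for _ in range(n_extra):
        t += 1
        tid = f"TX{t:05d}"
        tss = int(rng.integers(1, config.chrom_length_bp))
        rows.append({"transcript": tid, "chrom": config.chrom, "tss": tss, "strand": "+"})
        data.append(rng.normal(8.0, 1.0) + rng.normal(0.0, expr_noise_sd, size=len(samples)))
    transcripts = pd.DataFrame(rows).set_index("transcript")
    expr = pd.DataFrame(np.asarray(data), index=transcripts.index, columns=samples)
    return expr, transcripts, mapping


def make_funnel_fixture(seed: int = 0):
    """Deterministic replication-funnel fixture.

    Builds a synthetic primary study with 149 FDR hits of which 27 probe
    sets have a target-array CpG within 1 kb, and of those 27 exactly 19
    have genotype support in the replication panel (12 lead SNPs present
    directly, 7 through a proxy with r^2 > 0.8, 8 with best available
    r^2 well below 0.8).  Returns a dict of the pieces a
    ReplicationStudy needs.
    """
    rng = np.random.default_rng(seed)
    n_hits, n_matched, n_direct, n_proxy = 149, 27, 12, 7
    spacing = 1_000_000
    rows, cpg_rows = [], []
    lead_ids = []
    for i in range(n_hits):
        start = 10_000 + i * spacing
        end = start + 200
        ps = f"PS{i + 1:03d}"
        lead = f"lead{i + 1:03d}"
        lead_ids.append(lead)
        rows.append(
            {
                "probeset": ps,
                "chrom": "1",
                "start": start,
                "end": end,
                "snp": lead,
                "pos": start + 100,
                "beta": float(rng.choice([-1, 1]) * rng.uniform(0.05, 0.3)),
            }
        )
        # one CpG within 1 kb for the first n_matched hits, a distant one otherwise
        near = i < n_matched
        cpg_rows.append(
            {
                "cpg": f"cg{i + 1:05d}",
                "chrom": "1",
                "pos": end + (500 if near else 5000),
            }
        )
    hits = pd.DataFrame(rows).set_index("probeset")
    cpgs = pd.DataFrame(cpg_rows).set_index("cpg")

    # reference dosages for LD: leads are columns; replication panel carries
    # the lead itself, a duplicated (r^2 = 1) proxy, or an uncorrelated SNP
    n_ref = 60
    ref_cols, rep_cols = {}, {}
    rep_meta, ref_meta = [], []
    for i, lead in enumerate(lead_ids):
        d = rng.binomial(2, 0.3, size=n_ref).astype(float)
        ref_cols[lead] = d
        ref_meta.append({"snp": lead, "chrom": "1", "pos": 10_000 + i * spacing + 100,
                         "ref": "A", "alt": "G", "info": 1.0})
        if i >= n_matched:
            continue
        pos = 10_000 + i * spacing + 150
        if i < n_direct:
            rep_cols[lead] = d
            rep_meta.append({"snp": lead, "chrom": "1", "pos": pos - 50, "ref": "A", "alt": "G", "info": 1.0})
        elif i < n_direct + n_proxy:
            rep_cols[f"proxy{i + 1:03d}"] = d.copy()
            rep_meta.append({"snp": f"proxy{i + 1:03d}", "chrom": "1", "pos": pos, "ref": "A", "alt": "G", "info": 1.0})
        else:
            rep_cols[f"far{i + 1:03d}"] = rng.binomial(2, 0.3, size=n_ref).astype(float)
            rep_meta.append({"snp": f"far{i + 1:03d}", "chrom": "1", "pos": pos, "ref": "A", "alt": "G", "info": 1.0})
    ref_samples = [f"R{j + 1:02d}" for j in range(n_ref)]
    reference_panel = GenotypePanel(
        pd.DataFrame(ref_meta).set_index("snp"),
        pd.DataFrame(ref_cols, index=ref_samples),
    )
    replication_panel = GenotypePanel(
        pd.DataFrame(rep_meta).set_index("snp"),
        pd.DataFrame(rep_cols, index=ref_samples),
    )
    return {
        "hits": hits,
        "cpg_positions": cpgs,
        "reference_panel": reference_panel,
        "replication_panel": replication_panel,
        "expected_funnel": (n_hits, n_matched, n_direct + n_proxy),
    }
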