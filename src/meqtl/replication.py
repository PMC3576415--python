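"""Cross-platform replication of primary meQTL hits in a twin cohort.

Primary-study hits are funnelled through (i) probe matching — the
nearest target-array CpG within 1 kb of the probe-set interval, (ii)
genotype support — the lead SNP itself or a proxy with r^2 > 0.8 in the
replication panel, (iii) a one-tailed Gaussian test in the direction of
the primary association, and (iv) a binomial test of the replication
rate against the 5% chance expectation.  A mixed-model cis scan and
conditional analysis (in :mod:`meqtl.lmm`) probe each replicated region
further.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm as lmm_mod
from . import stats
from .scan import GenotypePanel, cis_snps, snp_probeset_distance

__all__ = [
    "ReplicationPair",
    "match_probes",
    "find_proxy",
    "harmonize_direction",
    "directional_test",
    "replication_rate_test",
    "ReplicationStudy",
    "ReplicationResults",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ReplicationPair:
    """A primary hit paired with its target-array CpG and testable SNP."""

    probeset: str
    cpg: str
    cpg_pos: int
    distance: int
    lead_snp: str
    replication_snp: str | None
    r2_to_lead: float
    primary_direction: int


def match_probes(
    hits: pd.DataFrame, cpg_positions: pd.DataFrame, max_dist: int = 1000
) -> pd.DataFrame:
    """Nearest target CpG within ``max_dist`` bp of each hit's probe set.

    ``hits`` is indexed by probe set with chrom/start/end (plus lead-SNP
    columns); ``cpg_positions`` is indexed by CpG id with chrom/pos.
    Distance is to the probe-set boundary (0 inside) and the threshold
    is closed.  One row per matched hit.
    """
    rows = []
    for ps, row in hits.iterrows():
        sub = cpg_positions[cpg_positions["chrom"] == row["chrom"]]
        if not len(sub):
            continue
        pos = sub["pos"].to_numpy()
        dist = np.maximum(0, np.maximum(row["start"] - pos, pos - row["end"]))
        best = np.lexsort((pos, dist))[0]
        if dist[best] <= max_dist:
            rows.append(
                {
                    "probeset": ps,
                    "cpg": sub.index[best],
                    "cpg_pos": int(pos[best]),
                    "distance": int(dist[best]),
                }
            )
    return pd.DataFrame(rows, columns=["probeset", "cpg", "cpg_pos", "distance"]).set_index(
        "probeset"
    )


def find_proxy(
    lead_snp: str,
    replication_panel: GenotypePanel,
    reference_panel: GenotypePanel,
    probeset=None,
    window: int = 500_000,
    r2_min: float = 0.8,
) -> tuple[str | None, float]:
    """The lead SNP if genotyped in the replication panel, else the best proxy.

    LD is computed from ``reference_panel`` dosages (which must carry
    the lead SNP).  Candidate proxies are replication-panel SNPs that
    are also in the reference panel, restricted to the cis window of
    ``probeset`` when given; the max-r^2 candidate is returned if its
    r^2 exceeds ``r2_min``, otherwise (None, best r^2).
    """
    if lead_snp in replication_panel.snps.index:
        return lead_snp, 1.0
    if lead_snp not in reference_panel.snps.index:
        return None, 0.0
    lead_dos = reference_panel.dosages[lead_snp]
    if probeset is not None:
        candidates = cis_snps(probeset, replication_panel, window)
    else:
        candidates = list(replication_panel.snps.index)
    best_snp, best_r2 = None, 0.0
    for s in candidates:
        # LD from the reference dosages when the candidate is genotyped
        # there, else from samples shared between the two panels
        if s in reference_panel.snps.index:
            a, b = lead_dos, reference_panel.dosages[s]
        else:
            shared = reference_panel.dosages.index.intersection(replication_panel.dosages.index)
            if len(shared) < 3:
                continue
            a = lead_dos.loc[shared]
            b = replication_panel.dosages.loc[shared, s]
        try:
            r2 = stats.ld_r2(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
        except stats.DegenerateFitError:
            continue
        if r2 > best_r2:
            best_snp, best_r2 = s, r2
    if best_r2 > r2_min:
        return best_snp, best_r2
    return None, best_r2


def harmonize_direction(
    primary_alleles: tuple[str, str],
    replication_alleles: tuple[str, str],
    primary_direction: int,
    maf_primary: float | None = None,
    maf_replication: float | None = None,
    maf_tol: float = 0.1,
) -> int | None:
    """Sign to apply to the primary direction so both cohorts code the
    same effect allele.

    Handles swapped ref/alt coding and strand flips; strand-ambiguous
    A/T and C/G SNPs are resolved by frequency matching when MAFs are
    supplied (|dMAF| < ``maf_tol``), otherwise flagged untestable
    (returns None).
    """
    pr = tuple(a.upper() for a in primary_alleles)
    rr = tuple(a.upper() for a in replication_alleles)
    ambiguous = {pr[0], pr[1]} in ({"A", "T"}, {"C", "G"})
    if ambiguous:
        if maf_primary is None or maf_replication is None:
            return None
        if abs(maf_primary - maf_replication) >= maf_tol:
            return None
        # frequencies agree: same-label coding is taken at face value
        if rr == pr:
            return primary_direction
        if rr == (pr[1], pr[0]):
            return -primary_direction
        return None
    flipped = tuple(_COMPLEMENT.get(a, "?") for a in pr)
    if rr == pr or rr == flipped:
        return primary_direction
    if rr == (pr[1], pr[0]) or rr == (flipped[1], flipped[0]):
        return -primary_direction
    return None


def directional_test(beta_rep: float, se_rep: float, primary_direction: int) -> float:
    """One-sided Gaussian p for the replication effect in the primary direction."""
    if se_rep <= 0:
        raise ValueError("se_rep must be positive")
    z = beta_rep / se_rep
    return stats.gaussian_upper_tail(z if primary_direction > 0 else -z)


def replication_rate_test(k_replicated: int, n_tested: int, alpha: float = 0.05) -> float:
    """Exact binomial P(X >= k) of observing ``k_replicated`` chance successes."""
    return stats.binomial_upper_tail(k_replicated, n_tested, alpha)


@dataclass
class ReplicationResults:
    """Funnel counts, per-pair directional tests and the rate test."""

    pairs: pd.DataFrame
    funnel: tuple[int, int, int]
    n_replicated: int | None = None
    rate_p: float | None = None
    alpha: float = 0.05

    def summary(self) -> str:
        h, m, t = self.funnel
        lines = [
            "Replication study",
            "=" * 40,
            f"primary hits:                 {h}",
            f"target CpG within 1 kb:       {m}",
            f"genotype-supported pairs:     {t}",
        ]
        if self.n_replicated is not None:
            lines.append(f"replicated (one-tailed {self.alpha:g}): {self.n_replicated}")
            lines.append(f"binomial rate p-value:        {self.rate_p:.3g}")
        return "\n".join(lines)


class ReplicationStudy:
    """Replication funnel for a set of primary meQTL hits.

    Parameters
    ----------
    hits : DataFrame indexed by probe set with chrom/start/end, lead
        ``snp`` id and primary ``beta``.
    cpg_positions : target-array CpG coordinates (index CpG id,
        columns chrom/pos).
    replication_panel : genotypes of the replication cohort.
    reference_panel : dosage reference carrying the lead SNPs, used for
        proxy LD.
    methylation / phenotypes : optional replication beta values
        (CpG x sample) and covariate table (age, batch, bsc_conc,
        bsc_eff, family, zygosity); when given, each testable pair is
        fitted with the twin mixed model and tested one-tailed.
    """

    def __init__(
        self,
        hits: pd.DataFrame,
        cpg_positions: pd.DataFrame,
        replication_panel: GenotypePanel,
        reference_panel: GenotypePanel,
        methylation=None,
        phenotypes: pd.DataFrame | None = None,
        max_dist: int = 1000,
        r2_min: float = 0.8,
        window: int = 500_000,
        alpha: float = 0.05,
    ):
        self.hits = hits
        self.cpg_positions = cpg_positions
        self.replication_panel = replication_panel
        self.reference_panel = reference_panel
        self.methylation = getattr(methylation, "values_frame", methylation)
        self.phenotypes = phenotypes
        self.max_dist = max_dist
        self.r2_min = r2_min
        self.window = window
        self.alpha = alpha

    def fit(self) -> ReplicationResults:
        matched = match_probes(self.hits, self.cpg_positions, self.max_dist)
        rows = []
        for ps, m in matched.iterrows():
            hit = self.hits.loc[ps]
            snp, r2 = find_proxy(
                hit["snp"],
                self.replication_panel,
                self.reference_panel,
                probeset=hit,
                window=self.window,
                r2_min=self.r2_min,
            )
            rows.append(
                {
                    "probeset": ps,
                    "cpg": m["cpg"],
                    "cpg_pos": m["cpg_pos"],
                    "distance": m["distance"],
                    "lead_snp": hit["snp"],
                    "replication_snp": snp,
                    "r2_to_lead": r2,
                    "primary_direction": 1 if hit["beta"] >= 0 else -1,
                }
            )
        pairs = pd.DataFrame(
            rows,
            columns=[
                "probeset", "cpg", "cpg_pos", "distance", "lead_snp",
                "replication_snp", "r2_to_lead", "primary_direction",
            ],
        ).set_index("probeset")
        testable = pairs[pairs["replication_snp"].notna()]
        funnel = (len(self.hits), len(matched), len(testable))

        n_rep = rate_p = None
        if self.methylation is not None and self.phenotypes is not None and len(testable):
            betas, ses, pvals, flags = [], [], [], []
            samples = list(self.phenotypes.index)
            covs = self.phenotypes[["age", "batch", "bsc_conc", "bsc_eff"]].astype(float)
            fam = self.phenotypes["family"].to_numpy()
            zyg = self.phenotypes["zygosity"].to_numpy()
            for ps, pair in testable.iterrows():
                y = self.methylation.loc[pair["cpg"], samples].to_numpy(dtype=float)
                exog = covs.copy()
                exog["dosage"] = self.replication_panel.dosages.loc[
                    samples, pair["replication_snp"]
                ].to_numpy(dtype=float)
                fit = lmm_mod.TwinLMM(y, exog, fam, zyg).fit()
                beta, se = float(fit.params["dosage"]), float(fit.bse["dosage"])
                p = directional_test(beta, se, int(pair["primary_direction"]))
                betas.append(beta)
                ses.append(se)
                pvals.append(p)
                flags.append(p < self.alpha)
            pairs["beta_rep"] = np.nan
            pairs["se_rep"] = np.nan
            pairs["one_sided_p"] = np.nan
            pairs["replicated"] = pd.Series(pd.NA, index=pairs.index, dtype="boolean")
            pairs.loc[testable.index, "beta_rep"] = betas
            pairs.loc[testable.index, "se_rep"] = ses
            pairs.loc[testable.index, "one_sided_p"] = pvals
            pairs.loc[testable.index, "replicated"] = flags
            n_rep = int(sum(flags))
            rate_p = replication_rate_test(n_rep, len(testable), self.alpha)
        return ReplicationResults(pairs, funnel, n_rep, rate_p, self.alpha)
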