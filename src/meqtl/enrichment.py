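"""Enrichment of meQTL SNPs for prior GWAS signal, and GO over-representation.

The GWAS test asks whether the meQTL SNPs carry unusually small GWAS
p-values for a trait, against a null of random SNPs matched on MAF,
distance to the nearest gene and local recombination rate.  The
statistic is the sum over test SNPs of the rank of their GWAS p within
the annotated pool (small p = small rank), compared with its
distribution over matched permutations; enrichment is one-sided
(unusually small rank sums).

GO over-representation is a per-term hypergeometric upper tail with
FDR adjustment across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats

__all__ = [
    "SnpAnnotation",
    "EnrichmentResult",
    "matched_pool",
    "GwasEnrichment",
    "gwas_enrichment",
    "go_hypergeometric",
]

_MATCH_COLS = ("maf", "gene_dist", "rec_rate")


def validate_annotation(annotation: pd.DataFrame) -> None:
    for col in _MATCH_COLS:
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks required column {col!r}")
    if (annotation["maf"] < 0).any() or (annotation["maf"] > 0.5).any():
        raise ValueError("annotation MAF must lie in [0, 0.5]")
    if (annotation["rec_rate"] < 0).any():
        raise ValueError("recombination rates must be non-negative")


# Backwards-friendly alias used in type hints/docs: the per-SNP annotation
# table (MAF, distance to nearest gene, recombination rate, GWAS p per trait).
SnpAnnotation = pd.DataFrame


def matched_pool(
    snp: str,
    annotation: pd.DataFrame,
    test_snps,
    tol_maf: float = 0.05,
    tol_dist: float = 500_000.0,
    tol_rec: float = 1.0,
) -> list[str]:
    """Candidate SNPs matched to ``snp`` on MAF, gene distance and
    recombination rate (closed tolerances), excluding every test SNP."""
    row = annotation.loc[snp]
    excl = set(test_snps) | {snp}
    mask = (
        (np.abs(annotation["maf"] - row["maf"]) <= tol_maf)
        & (np.abs(annotation["gene_dist"] - row["gene_dist"]) <= tol_dist)
        & (np.abs(annotation["rec_rate"] - row["rec_rate"]) <= tol_rec)
    )
    return [s for s in annotation.index[mask] if s not in excl]


@dataclass
class EnrichmentResult:
    """Observed rank-sum, its matched-permutation null and the empirical p."""

    trait: str
    observed: float
    perm_mean: float
    perm_sd: float
    empirical_p: float
    n_permutations: int
    n_test_snps: int
    n_relaxed: int = 0

    def summary(self) -> str:
        return "\n".join(
            [
                f"GWAS enrichment: {self.trait}",
                "=" * 40,
                f"test SNPs:            {self.n_test_snps}",
                f"observed rank sum:    {self.observed:.1f}",
                f"permutation mean/sd:  {self.perm_mean:.1f} / {self.perm_sd:.1f}",
                f"empirical p:          {self.empirical_p:.4g}  ({self.n_permutations} permutations)",
            ]
        )


class GwasEnrichment:
    """Matched-SNP permutation test of GWAS-signal enrichment.

    Parameters
    ----------
    test_snps : the meQTL lead SNPs.
    annotation : genome-wide SNP table with maf, gene_dist, rec_rate
        and one GWAS p-value column per trait.
    trait : name of the GWAS p-value column to test.
    """

    def __init__(
        self,
        test_snps,
        annotation: pd.DataFrame,
        trait: str,
        tol_maf: float = 0.05,
        tol_dist: float = 500_000.0,
        tol_rec: float = 1.0,
    ):
        validate_annotation(annotation)
        self.test_snps = list(test_snps)
        missing = [s for s in self.test_snps if s not in annotation.index]
        if missing:
            raise ValueError(f"test SNP(s) not annotated: {missing[:5]}")
        if trait not in annotation.columns:
            raise ValueError(f"no GWAS p-value column {trait!r} in the annotation")
        if annotation.loc[self.test_snps, trait].isna().any():
            bad = [s for s in self.test_snps if pd.isna(annotation.loc[s, trait])]
            raise ValueError(f"test SNP(s) lack a {trait} GWAS p-value: {bad[:5]}")
        self.annotation = annotation
        self.trait = trait
        self.tols = (tol_maf, tol_dist, tol_rec)

    def _pools(self) -> tuple[list[np.ndarray], int]:
        """Per-test-SNP matched candidate pools, relaxing tolerances
        (doubling, then unbounded) for SNPs with no match."""
        idx = pd.Index(self.annotation.index)
        pools, n_relaxed = [], 0
        for snp in self.test_snps:
            factor = 1.0
            cand: list[str] = []
            while True:
                if np.isinf(factor):
                    excl = set(self.test_snps) | {snp}
                    cand = [s for s in idx if s not in excl]
                else:
                    cand = matched_pool(
                        snp, self.annotation, self.test_snps,
                        self.tols[0] * factor, self.tols[1] * factor, self.tols[2] * factor,
                    )
                if cand:
                    break
                factor = factor * 2.0 if factor < 16 else np.inf
            if factor > 1.0:
                n_relaxed += 1
                warnings.warn(
                    f"SNP {snp}: matched pool empty at nominal tolerances; "
                    f"relaxed by factor {factor}", stacklevel=3,
                )
            pools.append(idx.get_indexer(cand))
        return pools, n_relaxed

    def fit(self, n_perm: int = 10_000, seed: int = 0) -> EnrichmentResult:
        p = self.annotation[self.trait].to_numpy(dtype=float)
        ranks = sps.rankdata(p)  # smaller p => smaller rank
        test_idx = pd.Index(self.annotation.index).get_indexer(self.test_snps)
        observed = float(ranks[test_idx].sum())
        pools, n_relaxed = self._pools()
        rng = np.random.default_rng(seed)
        perm_stats = np.empty(n_perm)
        for b in range(n_perm):
            used: set[int] = set()
            total = 0.0
            for pool in pools:
                pick = int(pool[rng.integers(len(pool))])
                if pick in used:
                    free = pool[~np.isin(pool, list(used))]
                    pick = int(free[rng.integers(len(free))]) if len(free) else pick
                used.add(pick)
                total += ranks[pick]
            perm_stats[b] = total
        emp_p = float((1 + np.sum(perm_stats <= observed)) / (n_perm + 1))
        return EnrichmentResult(
            trait=self.trait,
            observed=observed,
            perm_mean=float(perm_stats.mean()),
            perm_sd=float(perm_stats.std()),
            empirical_p=emp_p,
            n_permutations=n_perm,
            n_test_snps=len(self.test_snps),
            n_relaxed=n_relaxed,
        )


def gwas_enrichment(
    test_snps,
    annotation: pd.DataFrame,
    trait: str,
    n_perm: int = 10_000,
    seed: int = 0,
    tol_maf: float = 0.05,
    tol_dist: float = 500_000.0,
    tol_rec: float = 1.0,
) -> EnrichmentResult:
    """Functional wrapper around :class:`GwasEnrichment`."""
    model = GwasEnrichment(test_snps, annotation, trait, tol_maf, tol_dist, tol_rec)
    return model.fit(n_perm=n_perm, seed=seed)


def go_hypergeometric(
    hit_genes,
    universe_genes,
    term_to_genes: dict[str, set],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-GO-term hypergeometric over-representation of the hit genes.

    For each term with K genes in a universe of M, and N hit genes, the
    p-value is the upper tail P(overlap >= k).  Term genes absent from
    the universe are dropped with a warning.  q-values (FDR) are
    computed across terms.
    """
    universe = set(universe_genes)
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes must be a subset of the universe")
    M, N = len(universe), len(hits)
    rows = []
    for term, genes in term_to_genes.items():
        genes = set(genes)
        dropped = genes - universe
        if dropped:
            warnings.warn(
                f"term {term}: {len(dropped)} gene(s) absent from the universe dropped",
                stacklevel=2,
            )
            genes &= universe
        K = len(genes)
        k = len(genes & hits)
        p = float(sps.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"term": term, "term_size": K, "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("term")
    if len(out):
        out["q"] = stats.storey_qvalues(out["p"].to_numpy()).qvalues
        out["significant"] = out["q"] <= fdr
    return out
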