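"""Genome-wide cis-meQTL discovery.

The scan regresses the methylation score of each probe set on the
allelic dosage of every SNP within a +/-500 kb cis window, adjusting
for covariates (age, sex, MetSyn status in the primary study design),
pools the resulting p-values into Storey q-values and reports one lead
SNP per probe set at the requested FDR.

The model/results split follows the statsmodels convention:
``CisMeqtlScan(...).fit()`` returns a :class:`MeqtlScanResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import stats

__all__ = [
    "GenotypePanel",
    "MeqtlHit",
    "emac_filter",
    "cis_snps",
    "CisMeqtlScan",
    "MeqtlScanResults",
    "distance_summary",
]


@dataclass
class GenotypePanel:
    """Per-SNP records plus a samples x SNPs dosage matrix.

    ``snps`` is indexed by SNP id with columns ``chrom``, ``pos``
    (1-based), ``ref``, ``alt`` and ``info`` (imputation quality in
    [0, 1]).  ``dosages`` is indexed by sample id with one column per
    SNP; entries lie in [0, 2] (NaN allowed for missing).  SNPs are kept
    sorted by position within chromosome.
    """

    snps: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.snps.index) != set(self.dosages.columns):
            raise ValueError("snp table and dosage columns do not match")
        order = self.snps.sort_values(["chrom", "pos"], kind="mergesort").index
        self.snps = self.snps.loc[order]
        self.dosages = self.dosages.loc[:, order]
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.snps.shape[0]

    @property
    def maf(self) -> pd.Series:
        """Folded minor-allele frequency, mean dosage / 2 folded at 0.5."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def restrict(self, snp_ids) -> "GenotypePanel":
        wanted = set(snp_ids)
        ids = [s for s in self.snps.index if s in wanted]
        return GenotypePanel(self.snps.loc[ids].copy(), self.dosages.loc[:, ids].copy())

    def emac_filtered(self, threshold: float = 5.0, n: int | None = None) -> "GenotypePanel":
        """Drop SNPs failing the effective-minor-allele-count QC filter."""
        n_eff = self.n_samples if n is None else n
        keep = emac_filter(self.maf.to_numpy(), self.snps["info"].to_numpy(), n_eff, threshold)
        return self.restrict(self.snps.index[keep])


@dataclass(frozen=True)
class MeqtlHit:
    """A probe set whose lead cis SNP passes the FDR threshold."""

    probeset: str
    snp: str
    beta: float
    se: float
    tstat: float
    df: int
    p: float
    q: float
    n: int
    distance: int


def emac_filter(maf, info, n, threshold: float = 5.0):
    """Keep a SNP iff its effective minor allele count 2*MAF*info*n > threshold.

    The effective count discounts the sample size by the imputation
    info score; with perfect imputation and n = 38 the filter reduces to
    requiring a minor allele count above 5.
    """
    maf = np.asarray(maf, dtype=float)
    info = np.asarray(info, dtype=float)
    return 2.0 * maf * info * n > threshold


def _interval(probeset):
    """chrom/start/end from a mapping, Series or namedtuple-like."""
    if isinstance(probeset, pd.Series):
        return probeset["chrom"], int(probeset["start"]), int(probeset["end"])
    if isinstance(probeset, dict):
        return probeset["chrom"], int(probeset["start"]), int(probeset["end"])
    return probeset.chrom, int(probeset.start), int(probeset.end)


def cis_snps(probeset, panel: GenotypePanel, window: int = 500_000) -> list[str]:
    """SNP ids with pos in [start - window, end + window], closed at both ends."""
    chrom, start, end = _interval(probeset)
    sub = panel.snps[panel.snps["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    lo = np.searchsorted(pos, start - window, side="left")
    hi = np.searchsorted(pos, end + window, side="right")
    return list(sub.index[lo:hi])


def snp_probeset_distance(pos: int, start: int, end: int) -> int:
    """bp from a SNP to the nearest probe-set boundary; 0 if inside."""
    return max(0, start - pos, pos - end)


def distance_summary(hits: pd.DataFrame) -> float:
    """Median |SNP - probe set| distance in bp over the hits."""
    if len(hits) == 0:
        raise ValueError("no hits: distance summary undefined")
    return float(np.median(hits["distance"].to_numpy()))


class CisMeqtlScan:
    """Cis-window dosage-regression scan of a methylation matrix.

    Parameters
    ----------
    methylation : DataFrame (probe sets x samples) or MethylationMatrix
        Methylation scores; rows are probe sets, columns samples.
    probesets : DataFrame indexed by probe-set id with chrom/start/end.
    panel : GenotypePanel, already EMAC-filtered.
    covariates : DataFrame (samples x covariates), numeric, or None.
    window : cis half-window in bp around the probe-set interval.
    fdr : q-value threshold for calling hits.
    pooled_fdr : correct over all probe-SNP tests pooled (default) or
        per probe set.
    """

    def __init__(
        self,
        methylation,
        probesets: pd.DataFrame,
        panel: GenotypePanel,
        covariates: pd.DataFrame | None = None,
        window: int = 500_000,
        fdr: float = 0.05,
        pooled_fdr: bool = True,
    ):
        values = getattr(methylation, "values_frame", None)
        self.meth = values if values is not None else methylation
        self.probesets = probesets
        self.panel = panel
        self.covariates = covariates
        self.window = int(window)
        self.fdr = float(fdr)
        self.pooled_fdr = pooled_fdr
        self._check_alignment()

    def _check_alignment(self) -> None:
        samples = list(self.meth.columns)
        dos = set(self.panel.dosages.index)
        mismatches = sorted(set(samples) ^ dos)
        if self.covariates is not None:
            mismatches += sorted(set(samples) ^ set(self.covariates.index))
        if mismatches:
            raise ValueError(f"sample ids misaligned across inputs: {sorted(set(mismatches))}")
        self.samples = samples

    def fit(self) -> "MeqtlScanResults":
        n = len(self.samples)
        ps_ids = [p for p in self.probesets.index if p in self.meth.index]
        probesets = self.probesets.loc[ps_ids]
        Y = self.meth.loc[ps_ids, self.samples].to_numpy(dtype=float)  # P x n
        D = self.panel.dosages.loc[self.samples].to_numpy(dtype=float)  # n x S
        if self.covariates is not None:
            C = np.column_stack(
                [np.ones(n), self.covariates.loc[self.samples].to_numpy(dtype=float)]
            )
        else:
            C = np.ones((n, 1))
        q_cols = C.shape[1]
        df = n - (q_cols + 1)
        if df < 1:
            raise stats.InsufficientDataError("not enough samples for the scan model")

        missing = np.isnan(D).any()
        Qc, _ = np.linalg.qr(C)
        Yr = Y.T - Qc @ (Qc.T @ Y.T)  # n x P residualized methylation
        if not missing:
            Dr = D - Qc @ (Qc.T @ D)  # n x S residualized dosages
            xx = np.einsum("ij,ij->j", Dr, Dr)
        snp_pos = self.panel.snps["pos"].to_numpy()
        snp_ids = np.asarray(self.panel.snps.index)
        snp_chroms = self.panel.snps["chrom"].to_numpy()
        # per-chromosome [offset, offset+len) slices of the sorted SNP table
        chrom_slices: dict = {}
        for chrom in pd.unique(snp_chroms):
            mask = snp_chroms == chrom
            offs = np.flatnonzero(mask)
            chrom_slices[chrom] = (int(offs[0]), snp_pos[mask]) if offs.size else (0, snp_pos[:0])

        cols: dict[str, list] = {k: [] for k in
                                 ("probeset", "snp", "chrom", "pos", "beta", "se", "t", "df", "p", "n", "distance")}
        n_degenerate = 0
        starts = probesets["start"].to_numpy()
        ends = probesets["end"].to_numpy()
        chroms = probesets["chrom"].to_numpy()
        for pi, ps_id in enumerate(probesets.index):
            if chroms[pi] not in chrom_slices:
                continue
            offset, cpos = chrom_slices[chroms[pi]]
            lo = np.searchsorted(cpos, starts[pi] - self.window, side="left")
            hi = np.searchsorted(cpos, ends[pi] + self.window, side="right")
            if hi <= lo:
                continue
            idx = np.arange(offset + lo, offset + hi)
            if missing:
                recs = self._fit_slow(Y[pi], idx, C)
            else:
                recs = self._fit_fast(Yr[:, pi], Dr, xx, idx, df)
            if recs is None:
                continue
            keep, beta, se, tval, dfs, pval, nn = recs
            idx = idx[keep]
            n_degenerate += (~keep).sum()
            dist = np.maximum(
                0, np.maximum(starts[pi] - snp_pos[idx], snp_pos[idx] - ends[pi])
            ).astype(int)
            k = idx.size
            cols["probeset"].append(np.repeat(ps_id, k))
            cols["snp"].append(snp_ids[idx])
            cols["chrom"].append(np.repeat(chroms[pi], k))
            cols["pos"].append(snp_pos[idx])
            cols["beta"].append(beta)
            cols["se"].append(se)
            cols["t"].append(tval)
            cols["df"].append(np.broadcast_to(dfs, (k,)) if np.ndim(dfs) == 0 else dfs)
            cols["p"].append(pval)
            cols["n"].append(np.broadcast_to(nn, (k,)) if np.ndim(nn) == 0 else nn)
            cols["distance"].append(dist)
        if not cols["probeset"]:
            assoc = pd.DataFrame(
                columns=["probeset", "snp", "chrom", "pos", "beta", "se", "t", "df", "p", "n", "distance"]
            )
            assoc["q"] = []
            return MeqtlScanResults(assoc, assoc.iloc[0:0], np.nan, self.fdr, self.window, 0)

        assoc = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
        if not missing:
            # one pooled Student-t tail call over every test (fast path
            # defers the p-value; the slow path computed it per fit)
            tall = assoc["t"].to_numpy()
            assoc["p"] = np.maximum(2.0 * _sps.t.sf(np.abs(tall), df), 5e-324)
        if self.pooled_fdr:
            res = stats.storey_qvalues(assoc["p"].to_numpy())
            assoc["q"] = res.qvalues
            pi0 = res.pi0
        else:
            assoc["q"] = np.nan
            for ps_id, grp in assoc.groupby("probeset"):
                assoc.loc[grp.index, "q"] = stats.storey_qvalues(grp["p"].to_numpy()).qvalues
            pi0 = np.nan

        leads = (
            assoc.sort_values(["p", "distance", "pos"], kind="mergesort")
            .groupby("probeset", sort=False)
            .head(1)
        )
        hits = leads[leads["q"] <= self.fdr].reset_index(drop=True)
        return MeqtlScanResults(assoc, hits, pi0, self.fdr, self.window, int(n_degenerate))

    def _fit_fast(self, yr, Dr, xx, idx, df):
        x2 = xx[idx]
        keep = x2 > 1e-12
        if not keep.any():
            return None
        x2k = x2[keep]
        Xr = Dr[:, idx[keep]]
        xy = Xr.T @ yr
        beta = xy / x2k
        yy = float(yr @ yr)
        rss = np.maximum(yy - beta * xy, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / x2k)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        # p-values are filled in one pooled call by the caller
        return keep, beta, se, tval, df, np.full(beta.shape, np.nan), yr.shape[0]

    def _fit_slow(self, y, idx, C):
        covs = C[:, 1:] if C.shape[1] > 1 else None
        out = {"keep": [], "beta": [], "se": [], "t": [], "df": [], "p": [], "n": []}
        D = self.panel.dosages.loc[self.samples].to_numpy(dtype=float)
        for j in idx:
            try:
                fit = stats.ols_fit(y, D[:, j], covs)
            except (stats.DegenerateFitError, stats.InsufficientDataError):
                out["keep"].append(False)
                continue
            out["keep"].append(True)
            out["beta"].append(fit.beta)
            out["se"].append(fit.se)
            out["t"].append(fit.tstat)
            out["df"].append(fit.df)
            out["p"].append(fit.p)
            out["n"].append(fit.n)
        keep = np.asarray(out["keep"], dtype=bool)
        if not keep.any():
            return None
        return (
            keep,
            np.asarray(out["beta"]),
            np.asarray(out["se"]),
            np.asarray(out["t"]),
            np.asarray(out["df"]),
            np.asarray(out["p"]),
            np.asarray(out["n"]),
        )


@dataclass
class MeqtlScanResults:
    """Full association table, FDR hits and scan-level diagnostics."""

    associations: pd.DataFrame
    hits: pd.DataFrame
    pi0: float
    fdr: float
    window: int
    n_degenerate_snps: int = 0

    @property
    def n_tests(self) -> int:
        return len(self.associations)

    def median_distance(self) -> float:
        return distance_summary(self.hits)

    def hit_records(self) -> list[MeqtlHit]:
        return [
            MeqtlHit(
                r.probeset, r.snp, r.beta, r.se, r.t, int(r.df), r.p, r.q, int(r.n), int(r.distance)
            )
            for r in self.hits.itertuples()
        ]

    def summary(self) -> str:
        lines = [
            "Cis-meQTL scan",
            "=" * 40,
            f"tests (probe set x SNP pairs): {self.n_tests}",
            f"probe sets with >=1 cis SNP:   {self.associations['probeset'].nunique()}",
            f"pi0 estimate:                  {self.pi0:.3f}" if np.isfinite(self.pi0) else "pi0: per-probe FDR",
            f"hits at q <= {self.fdr:g}:           {len(self.hits)}",
        ]
        if len(self.hits):
            lines.append(f"median lead-SNP distance (bp): {self.median_distance():.0f}")
        return "\n".join(lines)
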