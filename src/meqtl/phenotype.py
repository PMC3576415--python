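"""Probe-wise association of methylation with phenotypes.

Each probe set's methylation score is regressed on one phenotype
(MetSyn status, BMI, age or sex) with the study's covariate adjustment,
and the observed -log10 p QQ curve is compared with a pointwise 95%
band obtained by permuting the methylation sample labels.  The sex scan
is restricted to autosomal probe sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats

__all__ = ["PhenotypeScan", "PhenotypeScanResults", "permutation_envelope", "COVARIATE_MAP"]

# phenotype -> adjustment covariates (study design)
COVARIATE_MAP = {
    "metsyn": ["age", "sex"],
    "bmi": ["age", "sex"],
    "age": ["bmi", "sex"],
    "sex": ["bmi", "age"],
}

_SEX_CHROMS = {"X", "Y", "CHRX", "CHRY", "23", "24"}


def _encode(col: pd.Series) -> np.ndarray:
    """Numeric coding for a phenotype/covariate column (F/M -> 1/0)."""
    if col.dtype == object or str(col.dtype) == "category":
        vals = col.astype(str).str.upper()
        uniq = sorted(vals.unique())
        if set(uniq) <= {"F", "M", "FEMALE", "MALE"}:
            return vals.str.startswith("F").astype(float).to_numpy()
        return pd.Categorical(vals).codes.astype(float)
    return col.to_numpy(dtype=float)


def _mass_ols(Y: np.ndarray, x: np.ndarray, C: np.ndarray):
    """OLS of every row of ``Y`` (P x n) on ``x`` adjusting for ``C`` (n x q).

    Uses the partialled-out (Frisch-Waugh) form, exactly equivalent to
    the full design fit.  Returns (beta, se, t, p, df).
    """
    n = x.shape[0]
    Qc, _ = np.linalg.qr(C)
    xr = x - Qc @ (Qc.T @ x)
    Yr = Y.T - Qc @ (Qc.T @ Y.T)  # n x P
    xx = float(xr @ xr)
    if xx <= 1e-12:
        raise stats.DegenerateFitError("phenotype is collinear with the covariates")
    df = n - (C.shape[1] + 1)
    xy = Yr.T @ xr
    beta = xy / xx
    yy = np.einsum("ij,ij->j", Yr, Yr)
    rss = np.maximum(yy - beta * xy, 0.0)
    se = np.sqrt(rss / df / xx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.maximum(2.0 * sps.t.sf(np.abs(t), df), 5e-324)
    return beta, se, t, p, df


@dataclass
class PhenotypeScanResults:
    """Per-probe association records plus the permutation QQ band."""

    records: pd.DataFrame
    envelope: pd.DataFrame | None
    phenotype: str
    pi0: float

    def n_significant(self, fdr: float = 0.05) -> int:
        return int((self.records["q"] <= fdr).sum())

    def summary(self) -> str:
        lines = [
            f"Phenotype scan: {self.phenotype}",
            "=" * 40,
            f"probe sets tested: {len(self.records)}",
            f"pi0 estimate:      {self.pi0:.3f}",
            f"significant at q <= 0.05: {self.n_significant()}",
        ]
        return "\n".join(lines)

    def plot_qq(self, ax=None):
        """QQ plot of observed -log10 p against uniform, with the band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = np.sort(self.records["p"].to_numpy())
        m = p.size
        exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        ax.plot(exp, -np.log10(p)[::1], "k.", ms=3)
        if self.envelope is not None:
            ax.fill_between(
                self.envelope["expected"], self.envelope["lower"], self.envelope["upper"],
                color="grey", alpha=0.4, lw=0,
            )
        ax.plot([0, exp.max()], [0, exp.max()], "r--", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(f"{self.phenotype} association")
        return ax


class PhenotypeScan:
    """Association scan of methylation against one phenotype.

    Covariate sets follow the study design (see ``COVARIATE_MAP``); the
    sex scan drops X/Y probe sets before testing, which requires the
    probe-set table.
    """

    def __init__(
        self,
        methylation,
        phenotypes: pd.DataFrame,
        phenotype: str,
        probesets: pd.DataFrame | None = None,
    ):
        values = getattr(methylation, "values_frame", None)
        self.meth = values if values is not None else methylation
        self.phenotypes = phenotypes
        if phenotype not in COVARIATE_MAP:
            raise ValueError(
                f"unknown phenotype {phenotype!r}; expected one of {sorted(COVARIATE_MAP)}"
            )
        self.phenotype = phenotype
        if phenotype == "sex" and probesets is None:
            raise ValueError("sex scan needs the probe-set table to drop X/Y probe sets")
        self.probesets = probesets
        samples = list(self.meth.columns)
        missing = [s for s in samples if s not in phenotypes.index]
        if missing:
            raise ValueError(f"samples missing from phenotype table: {missing}")
        self.samples = samples

    def _design(self):
        tab = self.phenotypes.loc[self.samples]
        x = _encode(tab[self.phenotype])
        covs = np.column_stack([_encode(tab[c]) for c in COVARIATE_MAP[self.phenotype]])
        C = np.column_stack([np.ones(len(self.samples)), covs])
        meth = self.meth
        if self.phenotype == "sex":
            if self.probesets is None:
                raise ValueError("sex scan needs the probe-set table to drop X/Y probe sets")
            auto = [
                p for p in meth.index
                if str(self.probesets.loc[p, "chrom"]).upper() not in _SEX_CHROMS
            ]
            meth = meth.loc[auto]
        return meth, x, C

    def fit(self, n_perm: int = 0, seed: int = 0) -> PhenotypeScanResults:
        meth, x, C = self._design()
        Y = meth.loc[:, self.samples].to_numpy(dtype=float)
        beta, se, t, p, df = _mass_ols(Y, x, C)
        qres = stats.storey_qvalues(p)
        records = pd.DataFrame(
            {
                "beta": beta, "se": se, "t": t, "df": df, "p": p,
                "q": qres.qvalues, "n": len(self.samples),
            },
            index=meth.index,
        )
        env = None
        if n_perm:
            env = permutation_envelope(Y, x, C, n_perm=n_perm, seed=seed)
        return PhenotypeScanResults(records, env, self.phenotype, qres.pi0)


def permutation_envelope(
    Y: np.ndarray, x: np.ndarray, C: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Pointwise 95% band of the sorted -log10 p curve under permutation.

    The methylation matrix columns (sample labels) are permuted jointly
    across probes, preserving inter-probe correlation; per permutation
    the sorted -log10 p vector is retained and the band is the
    pointwise 2.5/97.5 percentile.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for a stable 95% band")
    rng = np.random.default_rng(seed)
    m = Y.shape[0]
    n = Y.shape[1]
    curves = np.empty((n_perm, m))
    for b in range(n_perm):
        perm = rng.permutation(n)
        _, _, _, p, _ = _mass_ols(Y[:, perm], x, C)
        curves[b] = np.sort(-np.log10(p))[::-1]
    lower = np.percentile(curves, 2.5, axis=0)
    upper = np.percentile(curves, 97.5, axis=0)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return pd.DataFrame(
        {"expected": expected, "lower": lower, "upper": upper}
    )
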