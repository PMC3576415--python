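"""Maximum-likelihood linear mixed model for twin cohorts.

The marginal covariance is block diagonal over families: every family
contributes a shared random intercept (variance s2_family) and
monozygotic pairs an additional shared intercept (s2_mz), on top of
i.i.d. residual noise.  Because family blocks are at most 2 x 2 the
profile log-likelihood has a closed form, which makes thousands of
likelihood-ratio SNP tests cheap; fixed effects are estimated by GLS at
the optimised variance ratios and the SNP effect is tested with
-2 log(likelihood ratio) against chi-square(1).

Cross-validated against general-purpose mixed-model software in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from . import stats

__all__ = ["TwinLMM", "TwinLMMResults", "lmm_scan", "conditional_scan", "CollinearityError"]


class CollinearityError(ValueError):
    """Two predictors are perfectly collinear (e.g. r^2 = 1 SNPs)."""


@dataclass
class TwinLMMResults:
    """ML fit of a twin mixed model.

    ``params``/``bse`` cover the fixed effects; ``vcomp`` holds the
    family, MZ-extra and residual variance components; ``llf`` is the
    maximised log-likelihood.
    """

    params: pd.Series
    bse: pd.Series
    vcomp: dict[str, float]
    llf: float
    converged: bool
    n: int

    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary(self) -> str:
        lines = ["Twin LMM (ML)", "=" * 44, f"n = {self.n}, logLik = {self.llf:.4f}"]
        lines.append(f"{'term':<16}{'coef':>10}{'se':>10}")
        for name in self.params.index:
            lines.append(f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}")
        lines.append("variance components:")
        for k, v in self.vcomp.items():
            lines.append(f"  {k:<14}{v:>10.5f}")
        return "\n".join(lines)


class TwinLMM:
    """y = X b + family intercept + MZ-pair intercept + e, fitted by ML.

    Parameters
    ----------
    endog : response vector (n,).
    exog : DataFrame or array (n, k) of fixed-effect columns; an
        intercept column is prepended unless ``add_intercept=False``.
    family : length-n family labels (twins share a label).
    zygosity : length-n labels; entries equal to ``mz_label`` mark
        members of monozygotic pairs.
    """

    def __init__(self, endog, exog, family, zygosity, add_intercept=True, mz_label="MZ"):
        self.y = np.asarray(endog, dtype=float)
        n = self.y.shape[0]
        if isinstance(exog, pd.DataFrame):
            names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            names = [f"x{i}" for i in range(X.shape[1])]
        if add_intercept:
            X = np.column_stack([np.ones(n), X])
            names = ["intercept"] + names
        self.X = X
        self.names = names
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise CollinearityError("fixed-effect design is rank deficient")

        family = np.asarray(family)
        zyg = np.asarray(zygosity)
        if family.shape[0] != n or zyg.shape[0] != n:
            raise ValueError("family/zygosity must have one entry per sample")
        order: dict = {}
        for i, f in enumerate(family):
            order.setdefault(f, []).append(i)
        pair_idx, single_idx, pair_mz = [], [], []
        for f, idx in order.items():
            if len(idx) == 2:
                pair_idx.append(idx)
                pair_mz.append(zyg[idx[0]] == mz_label)
            elif len(idx) == 1:
                single_idx.append(idx[0])
            else:
                raise ValueError(f"family {f!r} has {len(idx)} members; twin model expects <= 2")
        self.p1 = np.array([a for a, _ in pair_idx], dtype=int)
        self.p2 = np.array([b for _, b in pair_idx], dtype=int)
        self.pmz = np.array(pair_mz, dtype=bool)
        self.sing = np.array(single_idx, dtype=int)
        self.smz = np.zeros(len(single_idx), dtype=bool)

    # -- profile likelihood over variance ratios ------------------------
    def _profile(self, gf: float, gmz: float):
        """GLS at variance ratios (gamma_f, gamma_mz) relative to s2e.

        Returns (beta, XtWX_inv, sigma2e_hat, minus2llf).
        """
        y, X = self.y, self.X
        n, k = X.shape
        tau_p = gf + gmz * self.pmz          # per-pair between ratio
        tau_s = gf + gmz * self.smz          # singleton ratio
        a = 1.0 + tau_p
        b = tau_p
        det = a * a - b * b                  # = 1 + 2 tau
        waa = a / det
        wab = -b / det
        ws = 1.0 / (1.0 + tau_s)

        X1, X2 = X[self.p1], X[self.p2]
        y1, y2 = y[self.p1], y[self.p2]
        XtWX = (
            np.einsum("p,pi,pj->ij", waa, X1, X1)
            + np.einsum("p,pi,pj->ij", waa, X2, X2)
            + np.einsum("p,pi,pj->ij", wab, X1, X2)
            + np.einsum("p,pi,pj->ij", wab, X2, X1)
        )
        XtWy = (
            np.einsum("p,pi,p->i", waa, X1, y1)
            + np.einsum("p,pi,p->i", waa, X2, y2)
            + np.einsum("p,pi,p->i", wab, X1, y2)
            + np.einsum("p,pi,p->i", wab, X2, y1)
        )
        if self.sing.size:
            Xs, ys = X[self.sing], y[self.sing]
            XtWX += np.einsum("p,pi,pj->ij", ws, Xs, Xs)
            XtWy += np.einsum("p,pi,p->i", ws, Xs, ys)
        XtWX_inv = np.linalg.inv(XtWX)
        beta = XtWX_inv @ XtWy
        r = y - X @ beta
        r1, r2 = r[self.p1], r[self.p2]
        quad = float(np.sum(waa * (r1 * r1 + r2 * r2) + 2.0 * wab * r1 * r2))
        logdet = float(np.sum(np.log(det)))
        if self.sing.size:
            rs = r[self.sing]
            quad += float(np.sum(ws * rs * rs))
            logdet += float(np.sum(np.log(1.0 + tau_s)))
        s2e = quad / n
        minus2llf = n * math.log(2.0 * math.pi * s2e) + logdet + n
        return beta, XtWX_inv, s2e, minus2llf

    def fit(self) -> TwinLMMResults:
        def objective(g):
            return self._profile(g[0], g[1])[3]

        best = None
        for x0 in ((0.5, 0.5), (0.02, 0.02)):
            res = optimize.minimize(
                objective, x0=np.asarray(x0), method="L-BFGS-B",
                bounds=[(0.0, 1e4), (0.0, 1e4)],
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        gf, gmz = best.x
        beta, XtWX_inv, s2e, minus2llf = self._profile(gf, gmz)
        bse = np.sqrt(np.diag(XtWX_inv) * s2e)
        return TwinLMMResults(
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(bse, index=self.names),
            vcomp={"family": gf * s2e, "mz_extra": gmz * s2e, "residual": s2e},
            llf=-0.5 * minus2llf,
            converged=bool(best.success),
            n=self.y.shape[0],
        )


def lrt(full: TwinLMMResults, null: TwinLMMResults) -> tuple[float, float]:
    """-2 log(likelihood ratio) and its chi-square(1 df) p-value."""
    stat = max(-2.0 * (null.llf - full.llf), 0.0)
    return stat, float(sps.chi2.sf(stat, 1))


def lmm_scan(
    beta_values,
    panel,
    fixed_covs: pd.DataFrame,
    family,
    zygosity,
    snp_ids=None,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """LRT mixed-model scan of one probe's methylation across cis SNPs.

    ``beta_values`` is the response vector (one probe, all samples,
    aligned with ``fixed_covs``/``family``/``zygosity`` and the panel's
    sample order).  The null model (covariates only) is fitted once;
    each SNP adds a dosage fixed effect.  q-values are computed over the
    probe's cis scan.  Returns (results table, number of non-converged
    SNP fits excluded from the FDR).
    """
    y = np.asarray(beta_values, dtype=float)
    snp_ids = list(panel.snps.index) if snp_ids is None else list(snp_ids)
    null_fit = TwinLMM(y, fixed_covs, family, zygosity).fit()
    rows, n_failed = [], 0
    for snp in snp_ids:
        exog = fixed_covs.copy()
        exog["dosage"] = panel.dosages[snp].to_numpy(dtype=float)
        if exog["dosage"].nunique() < 2:
            n_failed += 1
            continue
        try:
            full_fit = TwinLMM(y, exog, family, zygosity).fit()
        except (CollinearityError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not full_fit.converged:
            n_failed += 1
            continue
        stat, p = lrt(full_fit, null_fit)
        rows.append(
            {
                "snp": snp,
                "beta": float(full_fit.params["dosage"]),
                "se": float(full_fit.bse["dosage"]),
                "lrt": stat,
                "p": p,
                "vc_family": full_fit.vcomp["family"],
                "vc_mz": full_fit.vcomp["mz_extra"],
                "vc_resid": full_fit.vcomp["residual"],
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = stats.storey_qvalues(table["p"].to_numpy()).qvalues
        table["significant"] = table["q"] <= fdr
    return table, n_failed


def conditional_scan(
    beta_values,
    panel,
    snp_a: str,
    snp_b: str,
    fixed_covs: pd.DataFrame,
    family,
    zygosity,
) -> dict[str, dict[str, float]]:
    """Each SNP's mixed-model effect conditional on the other.

    Fits the full model with both dosages and, per SNP, a null dropping
    only that SNP; reports the conditional LRT p-values.  Perfectly
    correlated SNPs raise :class:`CollinearityError`.
    """
    da = panel.dosages[snp_a].to_numpy(dtype=float)
    db = panel.dosages[snp_b].to_numpy(dtype=float)
    if stats.ld_r2(da, db) > 1.0 - 1e-12:
        raise CollinearityError(f"{snp_a} and {snp_b} are perfectly correlated")
    y = np.asarray(beta_values, dtype=float)
    exog_full = fixed_covs.copy()
    exog_full[snp_a] = da
    exog_full[snp_b] = db
    full = TwinLMM(y, exog_full, family, zygosity).fit()
    out = {}
    for focal, other in ((snp_a, snp_b), (snp_b, snp_a)):
        exog_null = fixed_covs.copy()
        exog_null[other] = exog_full[other]
        null = TwinLMM(y, exog_null, family, zygosity).fit()
        stat, p = lrt(full, null)
        out[focal] = {
            "beta": float(full.params[focal]),
            "se": float(full.bse[focal]),
            "lrt": stat,
            "p": p,
        }
    return out
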