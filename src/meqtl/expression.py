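"""Methylation-expression integration.

Probe sets are matched to the transcript with the nearest TSS (strand
resolved: gene start on +, gene end on -); expression is then regressed
on methylation (and meQTL SNP dosages on expression) with the primary
study's covariate adjustment, using the sample intersection between the
assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "ExpressionMatrix",
    "tss_from_interval",
    "nearest_tss",
    "match_nearest_tss",
    "meth_expr_assoc",
    "eqtl_test",
]


@dataclass
class ExpressionMatrix:
    """Summarised log-scale expression plus transcript TSS annotation.

    ``values_frame`` is transcripts x samples; ``transcripts`` is
    indexed by transcript id with chrom, tss and strand columns.
    """

    values_frame: pd.DataFrame
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values_frame.index.is_unique:
            raise ValueError("duplicate transcript ids")
        if not np.all(np.isfinite(self.values_frame.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")


def tss_from_interval(start: int, end: int, strand: str) -> int:
    """The transcription start site of a gene interval: start on '+', end on '-'."""
    return int(start) if strand == "+" else int(end)


def nearest_tss(probeset, transcripts: pd.DataFrame) -> tuple[str | None, int | None]:
    """Transcript whose TSS is closest to the probe-set boundary.

    Distance is |TSS - nearest probe-set boundary| (0 inside the
    interval); ties break to the lower TSS position.  Returns
    (None, None) when the chromosome carries no transcript.
    """
    chrom, start, end = probeset["chrom"], int(probeset["start"]), int(probeset["end"])
    sub = transcripts[transcripts["chrom"] == chrom]
    if not len(sub):
        return None, None
    tss = sub["tss"].to_numpy()
    dist = np.maximum(0, np.maximum(start - tss, tss - end))
    best = np.lexsort((tss, dist))[0]
    return sub.index[best], int(dist[best])


def match_nearest_tss(probesets: pd.DataFrame, transcripts: pd.DataFrame) -> pd.DataFrame:
    """Nearest-TSS transcript per probe set; unmatched sets are flagged."""
    rows = []
    for ps, row in probesets.iterrows():
        t, d = nearest_tss(row, transcripts)
        rows.append({"probeset": ps, "transcript": t, "tss_distance": d})
    return pd.DataFrame(rows).set_index("probeset")


def _paired_ols(y_frame, x_frame, pairs, covariates, y_col, x_col):
    samples = [s for s in y_frame.columns if s in set(x_frame.columns)]
    if covariates is not None:
        samples = [s for s in samples if s in covariates.index]
        n_min = covariates.shape[1] + 3
    else:
        n_min = 3
    if len(samples) == 0:
        raise ValueError("no samples shared between the assays")
    if len(samples) < n_min:
        raise stats.InsufficientDataError(
            f"only {len(samples)} shared samples; need at least {n_min}"
        )
    covs = covariates.loc[samples].to_numpy(dtype=float) if covariates is not None else None
    rows = []
    for _, pair in pairs.iterrows():
        yk, xk = pair[y_col], pair[x_col]
        if yk is None or xk is None or yk not in y_frame.index or xk not in x_frame.index:
            continue
        y = y_frame.loc[yk, samples].to_numpy(dtype=float)
        x = x_frame.loc[xk, samples].to_numpy(dtype=float)
        try:
            fit = stats.ols_fit(y, x, covs)
        except (stats.DegenerateFitError, stats.InsufficientDataError):
            continue
        rows.append(
            {
                y_col: yk, x_col: xk, "beta": fit.beta, "se": fit.se,
                "t": fit.tstat, "df": fit.df, "p": fit.p, "n": fit.n,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = stats.storey_qvalues(out["p"].to_numpy()).qvalues
    return out


def meth_expr_assoc(
    expression: ExpressionMatrix,
    methylation,
    pairs: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expression ~ methylation for matched (probe set, transcript) pairs.

    ``pairs`` comes from :func:`match_nearest_tss` (columns ``transcript``,
    index probe set).  Covariates (age, sex, MetSyn) are numeric per
    sample.  q-values are computed within the tested run, so the full
    probe list and a hit subset get their own corrections.
    """
    meth = getattr(methylation, "values_frame", methylation)
    p = pairs.reset_index().rename(columns={"index": "probeset"})
    return _paired_ols(
        expression.values_frame, meth, p, covariates, y_col="transcript", x_col="probeset"
    )


def eqtl_test(
    expression: ExpressionMatrix,
    panel,
    pairs: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expression ~ allelic dosage for (transcript, SNP) pairs.

    ``pairs`` must carry ``transcript`` and ``snp`` columns (typically
    the meQTL lead SNPs matched to the probe sets' nearest transcripts).
    """
    dosage_frame = panel.dosages.T  # snp x sample
    p = pairs.reset_index()
    return _paired_ols(
        expression.values_frame, dosage_frame, p, covariates, y_col="transcript", x_col="snp"
    )
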