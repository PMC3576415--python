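"""DMH intensity preprocessing.

Raw chip intensities -> replicate-averaged pseudo-chips -> per-probe-set
methylation scores (median log2 probe intensity minus median log2
chip-internal control intensity) -> calibration against the 0% / 100%
methylated reference chips -> quantile normalisation across samples ->
exclusion of probe sets whose probes overlap common SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Chip",
    "IntensityExperiment",
    "MethylationMatrix",
    "average_replicates",
    "methylation_score",
    "score_experiment",
    "calibrate_scores",
    "quantile_normalize",
    "filter_probesets_by_snp",
    "qc_patterns",
    "QCReport",
]


@dataclass
class Chip:
    """One hybridised microarray: probe intensities plus control probes.

    ``calibration`` is None for a biological sample, or "0%" / "100%"
    for the fully un-/methylated reference chips.
    """

    chip_id: str
    sample_id: str | None
    replicate: int
    batch: str
    probe_intensities: pd.Series
    control_intensities: np.ndarray
    calibration: str | None = None

    def __post_init__(self) -> None:
        self.control_intensities = np.asarray(self.control_intensities, dtype=float)
        if (self.probe_intensities <= 0).any() or (self.control_intensities <= 0).any():
            raise ValueError(f"chip {self.chip_id}: intensities must be strictly positive")


@dataclass
class IntensityExperiment:
    """A set of chips; every biological sample appears on two replicates."""

    chips: list[Chip]

    def sample_chips(self) -> dict[str, list[Chip]]:
        out: dict[str, list[Chip]] = {}
        for c in self.chips:
            if c.calibration is None:
                out.setdefault(c.sample_id, []).append(c)
        return out

    def calibration_chip(self, which: str) -> Chip:
        for c in self.chips:
            if c.calibration == which:
                return c
        raise KeyError(f"no {which} calibration chip present")


_STAGES = ("raw", "calibrated", "normalized", "beta")


@dataclass
class MethylationMatrix:
    """Probe-set x sample methylation scores with a processing-stage tag.

    Scores on the calibrated scale sit near 0 for unmethylated and 1 for
    fully methylated loci but may legitimately fall outside [0, 1];
    stage "beta" marks Illumina-style beta values constrained to [0, 1].
    """

    values_frame: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.all(np.isfinite(self.values_frame.to_numpy(dtype=float))):
            raise ValueError("methylation matrix contains non-finite values")

    @property
    def samples(self) -> list[str]:
        return list(self.values_frame.columns)

    @property
    def probesets(self) -> list[str]:
        return list(self.values_frame.index)


def average_replicates(experiment: IntensityExperiment) -> IntensityExperiment:
    """Collapse each sample's two replicate chips into one pseudo-chip.

    Averaging is the arithmetic mean on the raw intensity scale and
    precedes any log transform.  Calibration chips pass through.
    """
    chips: list[Chip] = []
    for sample, reps in experiment.sample_chips().items():
        if len(reps) != 2:
            raise ValueError(f"sample {sample!r} has {len(reps)} chips, expected 2")
        a, b = reps
        if not a.probe_intensities.index.equals(b.probe_intensities.index):
            b = replace(b, probe_intensities=b.probe_intensities.reindex(a.probe_intensities.index))
        chips.append(
            Chip(
                chip_id=f"{sample}_avg",
                sample_id=sample,
                replicate=0,
                batch=a.batch,
                probe_intensities=(a.probe_intensities + b.probe_intensities) / 2.0,
                control_intensities=(a.control_intensities + b.control_intensities) / 2.0,
            )
        )
    chips.extend(c for c in experiment.chips if c.calibration is not None)
    return IntensityExperiment(chips)


def methylation_score(probe_intensities, control_intensities) -> float:
    """median(log2 probe-set intensities) - median(log2 control intensities)."""
    p = np.asarray(probe_intensities, dtype=float)
    c = np.asarray(control_intensities, dtype=float)
    if p.size == 0 or c.size == 0:
        raise ValueError("need at least one probe and one control intensity")
    if np.any(p <= 0) or np.any(c <= 0):
        raise ValueError("intensities must be strictly positive")
    return float(np.median(np.log2(p)) - np.median(np.log2(c)))


def score_experiment(
    experiment: IntensityExperiment, probes: pd.DataFrame
) -> tuple[MethylationMatrix, pd.Series, pd.Series]:
    """Raw methylation scores for every sample plus the 0%/100% chip scores.

    ``probes`` maps probe id -> probe-set id (column ``probeset``).
    Expects one chip per sample, i.e. replicates already averaged.
    """
    groups = probes.groupby("probeset").groups
    sample_chips = experiment.sample_chips()
    for sample, reps in sample_chips.items():
        if len(reps) != 1:
            raise ValueError(f"sample {sample!r} has {len(reps)} chips; average replicates first")

    def chip_scores(chip: Chip) -> pd.Series:
        logp = np.log2(chip.probe_intensities)
        ctrl = float(np.median(np.log2(chip.control_intensities)))
        return pd.Series(
            {ps: float(np.median(logp.loc[list(ids)])) - ctrl for ps, ids in groups.items()}
        )

    cols = {s: chip_scores(reps[0]) for s, reps in sample_chips.items()}
    raw = MethylationMatrix(pd.DataFrame(cols), stage="raw")
    chip0 = chip_scores(experiment.calibration_chip("0%"))
    chip100 = chip_scores(experiment.calibration_chip("100%"))
    return raw, chip0, chip100


def calibrate_scores(
    raw: MethylationMatrix, chip0_scores: pd.Series, chip100_scores: pd.Series
) -> tuple[MethylationMatrix, list[str]]:
    """Affine-map each probe set so the 0% chip scores 0 and the 100% chip 1.

    Probe sets whose two anchors coincide are uncalibratable and are
    dropped with a warning; their ids are returned alongside the matrix.
    Calibrated values may fall outside [0, 1].
    """
    if raw.stage != "raw":
        raise ValueError("calibration applies to a raw matrix")
    idx = raw.values_frame.index
    missing = [p for p in idx if p not in chip0_scores.index or p not in chip100_scores.index]
    if missing:
        raise ValueError(f"calibration chips lack scores for probe sets: {missing[:5]}")
    m0 = chip0_scores.loc[idx]
    m100 = chip100_scores.loc[idx]
    span = m100 - m0
    bad = span == 0
    dropped = list(idx[bad])
    if dropped:
        warnings.warn(
            f"{len(dropped)} probe set(s) uncalibratable (identical 0%/100% anchors); dropped",
            stacklevel=2,
        )
    good = idx[~bad]
    calibrated = raw.values_frame.loc[good].sub(m0.loc[good], axis=0).div(span.loc[good], axis=0)
    return MethylationMatrix(calibrated, stage="calibrated"), dropped


def quantile_normalize(matrix) -> "pd.DataFrame | MethylationMatrix":
    """Force every sample (column) onto the mean-of-sorted reference distribution.

    Ties within a sample receive the mean of the reference quantiles
    they span; within-sample rank order is preserved.  Accepts a plain
    DataFrame or a MethylationMatrix (stage advances to "normalized").
    """
    wrapped = isinstance(matrix, MethylationMatrix)
    df = matrix.values_frame if wrapped else matrix
    X = df.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing values are not allowed")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    m = X.shape[0]
    for j in range(X.shape[1]):
        ranks = sps.rankdata(X[:, j], method="average")  # 1..m, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    if wrapped:
        return MethylationMatrix(res, stage="normalized")
    return res


def filter_probesets_by_snp(
    probesets: pd.DataFrame,
    probes: pd.DataFrame,
    snps: pd.DataFrame,
    maf_threshold: float = 0.05,
    probe_length: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude probe sets whose probe footprints contain a common SNP.

    A probe's genomic footprint is [pos, pos + probe_length - 1].  A
    probe set is excluded iff any reference SNP with MAF strictly above
    ``maf_threshold`` lands inside any of its footprints — this curbs
    allele-specific hybridisation bias without discarding sets over
    rare variants.

    Parameters
    ----------
    probesets : DataFrame indexed by probe-set id (chrom, start, end).
    probes : DataFrame with columns probeset, chrom, pos (one row per probe).
    snps : DataFrame with columns chrom, pos, maf, indexed by SNP id.

    Returns (kept probe sets, exclusion report with offending SNPs).
    """
    if len(snps):
        probe_chroms = set(probes["chrom"].unique())
        snp_chroms = set(snps["chrom"].unique())
        unmatched = sorted(probe_chroms - snp_chroms)
        if unmatched:
            raise ValueError(f"chromosomes absent from SNP panel: {unmatched}")
    common = snps[snps["maf"] > maf_threshold]
    records = []
    excluded: set[str] = set()
    for chrom, chrom_snps in common.groupby("chrom"):
        pos = chrom_snps["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        ids = chrom_snps.index.to_numpy()[order]
        sub = probes[probes["chrom"] == chrom]
        starts = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + probe_length - 1, side="right")
        for (probe_row, l, h) in zip(sub.itertuples(), lo, hi):
            for snp_i in range(l, h):
                records.append(
                    {
                        "probeset": probe_row.probeset,
                        "probe": probe_row.Index,
                        "snp": ids[snp_i],
                        "maf": float(common.loc[ids[snp_i], "maf"]),
                    }
                )
                excluded.add(probe_row.probeset)
    report = pd.DataFrame(records, columns=["probeset", "probe", "snp", "maf"])
    kept = probesets.loc[[p for p in probesets.index if p not in excluded]]
    return kept, report


@dataclass
class QCReport:
    """Advisory sanity checks on a processed methylation matrix."""

    bimodality_stat: float
    bimodality_p: float
    hemimethylated_fraction_female_x: float
    tss_profile: pd.DataFrame  # columns: distance, median_score
    notes: list[str] = field(default_factory=list)


def _bimodality_gmm(values: np.ndarray, n_boot: int = 50, seed: int = 0) -> tuple[float, float]:
    """Bootstrap likelihood-ratio test of 2 vs 1 Gaussian components.

    Returns (LRT statistic, parametric-bootstrap p-value).  Serves as
    the bimodality check on the global score distribution.
    """
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(seed)
    x = values.reshape(-1, 1)
    if len(x) > 5000:
        x = x[rng.choice(len(x), 5000, replace=False)]
    g1 = GaussianMixture(1, random_state=0).fit(x)
    g2 = GaussianMixture(2, n_init=3, random_state=0).fit(x)
    stat = 2.0 * (g2.score(x) - g1.score(x)) * len(x)
    mu, sd = float(x.mean()), float(x.std())
    null_stats = []
    for _ in range(n_boot):
        xb = rng.normal(mu, sd, size=len(x)).reshape(-1, 1)
        b1 = GaussianMixture(1, random_state=0).fit(xb)
        b2 = GaussianMixture(2, n_init=2, random_state=0).fit(xb)
        null_stats.append(2.0 * (b2.score(xb) - b1.score(xb)) * len(xb))
    p = (1 + sum(s >= stat for s in null_stats)) / (n_boot + 1)
    return float(stat), float(p)


def qc_patterns(
    matrix,
    probesets: pd.DataFrame,
    sex: pd.Series | None = None,
    tss_positions: pd.DataFrame | None = None,
    window_bp: int = 300,
    max_tss_dist: int = 5000,
    seed: int = 0,
) -> QCReport:
    """Check the processed matrix against expected methylation patterns.

    (i) bimodality of the global score distribution (hypo/hyper modes),
    (ii) the fraction of female X-chromosome near-TSS probe sets with a
    mean score in the hemimethylated band [0.3, 0.7], and (iii) a
    sliding-window (300 bp) median score profile against distance to
    the nearest TSS, which should dip near the TSS.
    """
    df = matrix.values_frame if isinstance(matrix, MethylationMatrix) else matrix
    notes: list[str] = []
    stat, p = _bimodality_gmm(df.to_numpy(dtype=float).ravel(), seed=seed)

    hemi_frac = float("nan")
    if sex is not None:
        females = [s for s in df.columns if str(sex.get(s, "")).upper().startswith("F")]
        x_sets = probesets[probesets["chrom"].astype(str).str.upper().isin(["X", "CHRX"])]
        ids = [i for i in x_sets.index if i in df.index]
        if tss_positions is not None and ids:
            near = []
            tssx = tss_positions[tss_positions["chrom"].astype(str).str.upper().isin(["X", "CHRX"])]
            for i in ids:
                row = probesets.loc[i]
                d = np.abs(tssx["tss"].to_numpy() - 0.5 * (row["start"] + row["end"]))
                if d.size and d.min() <= max_tss_dist:
                    near.append(i)
            ids = near
        if females and ids:
            means = df.loc[ids, females].mean(axis=1)
            hemi_frac = float(((means >= 0.3) & (means <= 0.7)).mean())
        else:
            notes.append("no female samples or X probe sets: hemimethylation check skipped")

    profile = pd.DataFrame(columns=["distance", "median_score"])
    if tss_positions is not None:
        dists, scores = [], []
        for i in df.index:
            if i not in probesets.index:
                continue
            row = probesets.loc[i]
            sub = tss_positions[tss_positions["chrom"] == row["chrom"]]
            if not len(sub):
                continue
            mid = 0.5 * (row["start"] + row["end"])
            dists.append(float(np.min(np.abs(sub["tss"].to_numpy() - mid))))
            scores.append(float(df.loc[i].mean()))
        dists = np.asarray(dists)
        scores = np.asarray(scores)
        if dists.size:
            centers = np.arange(0, dists.max() + window_bp, window_bp / 2.0)
            rows = []
            for c in centers:
                mask = np.abs(dists - c) <= window_bp / 2.0
                if mask.any():
                    rows.append({"distance": c, "median_score": float(np.median(scores[mask]))})
            profile = pd.DataFrame(rows)

    return QCReport(stat, p, hemi_frac, profile, notes)
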