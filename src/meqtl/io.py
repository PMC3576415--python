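"""Readers and writers for the pipeline's plain-text formats.

Dosage matrices, probe/probe-set BED, long-format chip intensities,
phenotype tables and association results all travel as tab-separated
text; BED I/O converts between the package's 1-based inclusive internal
coordinates and BED's 0-based half-open convention.  VCF dosages (DS
field) are read through pysam.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import Chip, IntensityExperiment, MethylationMatrix
from .scan import GenotypePanel

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "write_probesets_bed",
    "read_probesets_bed",
    "write_intensities_tsv",
    "read_intensities_tsv",
    "write_methylation_tsv",
    "read_methylation_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
]

_META_COLS = ["chrom", "pos", "ref", "alt", "info"]


def write_genotypes_tsv(panel: GenotypePanel, path) -> None:
    """snp, chrom, pos, ref, alt, info, then one dosage column per sample."""
    out = panel.snps[_META_COLS].copy()
    out = out.join(panel.dosages.T)
    out.to_csv(path, sep="\t", index_label="snp")


def read_genotypes_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col="snp", dtype={"chrom": str})
    snps = df[_META_COLS].copy()
    dosages = df.drop(columns=_META_COLS).T.astype(float)
    dosages.index.name = "sample"
    return GenotypePanel(snps, dosages)


def read_genotypes_vcf(path) -> GenotypePanel:
    """Dosage panel from a VCF carrying per-sample DS (dosage) values."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    meta, cols = [], {}
    for rec in vf:
        sid = rec.id or f"{rec.chrom}:{rec.pos}"
        meta.append(
            {
                "snp": sid,
                "chrom": str(rec.chrom),
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
                "info": float(rec.info.get("INFO", 1.0)),
            }
        )
        cols[sid] = [float(rec.samples[s]["DS"]) for s in samples]
    snps = pd.DataFrame(meta).set_index("snp")
    dosages = pd.DataFrame(cols, index=samples)
    return GenotypePanel(snps, dosages)


def write_probesets_bed(probesets: pd.DataFrame, path) -> None:
    """BED (0-based half-open) from 1-based inclusive intervals."""
    bed = pd.DataFrame(
        {
            "chrom": probesets["chrom"],
            "start": probesets["start"].astype(int) - 1,
            "end": probesets["end"].astype(int),
            "name": probesets.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_probesets_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"],
                      dtype={"chrom": str})
    return pd.DataFrame(
        {
            "chrom": bed["chrom"].to_numpy(),
            "start": bed["start"].to_numpy() + 1,
            "end": bed["end"].to_numpy(),
        },
        index=pd.Index(bed["name"].to_numpy(), name="id"),
    )


def write_intensities_tsv(experiment: IntensityExperiment, path) -> None:
    """Long format: chip, sample, calibration, replicate, batch, probe, intensity.

    Control probes are written with probe ids ``ctrl<k>`` and
    is_control = 1.
    """
    frames = []
    for chip in experiment.chips:
        base = {
            "chip": chip.chip_id,
            "sample": chip.sample_id if chip.sample_id is not None else "",
            "calibration": chip.calibration or "",
            "replicate": chip.replicate,
            "batch": chip.batch,
        }
        f = pd.DataFrame(
            {
                "probe": chip.probe_intensities.index,
                "intensity": chip.probe_intensities.to_numpy(),
                "is_control": 0,
            }
        )
        g = pd.DataFrame(
            {
                "probe": [f"ctrl{k + 1:02d}" for k in range(len(chip.control_intensities))],
                "intensity": chip.control_intensities,
                "is_control": 1,
            }
        )
        both = pd.concat([f, g], ignore_index=True)
        for k, v in base.items():
            both[k] = v
        frames.append(both)
    cols = ["chip", "sample", "calibration", "replicate", "batch", "probe", "intensity", "is_control"]
    pd.concat(frames, ignore_index=True)[cols].to_csv(path, sep="\t", index=False)


def read_intensities_tsv(path) -> IntensityExperiment:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    chips = []
    for chip_id, grp in df.groupby("chip", sort=False):
        probes = grp[grp["is_control"] == 0]
        ctrls = grp[grp["is_control"] == 1]
        first = grp.iloc[0]
        chips.append(
            Chip(
                chip_id=str(chip_id),
                sample_id=str(first["sample"]) or None,
                replicate=int(first["replicate"]),
                batch=str(first["batch"]),
                probe_intensities=pd.Series(
                    probes["intensity"].to_numpy(), index=probes["probe"].to_numpy()
                ),
                control_intensities=ctrls["intensity"].to_numpy(),
                calibration=str(first["calibration"]) or None,
            )
        )
    return IntensityExperiment(chips)


def write_methylation_tsv(matrix: MethylationMatrix, path) -> None:
    matrix.values_frame.to_csv(path, sep="\t", index_label="probeset")


def read_methylation_tsv(path, stage: str = "normalized") -> MethylationMatrix:
    return MethylationMatrix(pd.read_csv(path, sep="\t", index_col="probeset"), stage=stage)


def write_truth_tsv(truth, path) -> None:
    rows = [{"probeset": ps, "snp": snp, "beta": beta} for ps, (snp, beta) in truth.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path):
    from .simulate import PlantedTruth

    df = pd.read_csv(path, sep="\t")
    return PlantedTruth({r.probeset: (r.snp, float(r.beta)) for r in df.itertuples()})
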