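"""DMH preprocessing: averaging, scoring, calibration, normalisation, SNP filter."""

import numpy as np
import pandas as pd
import pytest

from meqtl.preprocess import (
    Chip,
    IntensityExperiment,
    MethylationMatrix,
    average_replicates,
    calibrate_scores,
    filter_probesets_by_snp,
    methylation_score,
    qc_patterns,
    quantile_normalize,
    score_experiment,
)


def _chip(chip_id, sample, rep, intensities, ctrl=(8.0,), calibration=None):
    return Chip(
        chip_id=chip_id,
        sample_id=sample,
        replicate=rep,
        batch="B1",
        probe_intensities=pd.Series(intensities),
        control_intensities=np.asarray(ctrl),
        calibration=calibration,
    )


class TestAverageReplicates:
    def test_arithmetic_mean_of_duplicates(self):
        exp = IntensityExperiment(
            [
                _chip("c1", "s1", 1, {"p1": 100.0}),
                _chip("c2", "s1", 2, {"p1": 300.0}),
            ]
        )
        out = average_replicates(exp)
        assert out.sample_chips()["s1"][0].probe_intensities["p1"] == 200.0

    def test_identical_replicates_idempotent(self):
        vals = {"p1": 12.0, "p2": 7.5}
        exp = IntensityExperiment(
            [_chip("c1", "s1", 1, vals), _chip("c2", "s1", 2, vals)]
        )
        out = average_replicates(exp)
        assert out.sample_chips()["s1"][0].probe_intensities.to_dict() == vals

    def test_mean_preserved_under_averaging(self, rng):
        chips = []
        for s in range(4):
            for r in (1, 2):
                chips.append(
                    _chip(f"c{s}{r}", f"s{s}", r, dict(zip("abcde", rng.uniform(10, 100, 5))))
                )
        exp = IntensityExperiment(chips)
        out = average_replicates(exp)
        raw_mean = np.mean([c.probe_intensities.to_numpy() for c in exp.chips])
        avg_mean = np.mean(
            [c.probe_intensities.to_numpy() for reps in out.sample_chips().values() for c in reps]
        )
        assert avg_mean == pytest.approx(raw_mean)

    def test_odd_replicate_count_names_sample(self):
        exp = IntensityExperiment([_chip("c1", "bad_sample", 1, {"p1": 1.0})])
        with pytest.raises(ValueError, match="bad_sample"):
            average_replicates(exp)


class TestMethylationScore:
    @pytest.mark.parametrize(
        "probes,controls,expected",
        [
            ([8, 8, 8], [8], 0.0),
            ([16, 16], [4, 4], 2.0),
        ],
    )
    def test_log_median_differences(self, probes, controls, expected):
        assert methylation_score(probes, controls) == pytest.approx(expected)

    def test_matches_brute_force_median_log_oracle(self):
        probes, controls = [3, 5, 7, 11], [2, 6]
        expected = np.median(np.log2(probes)) - np.median(np.log2(controls))
        assert methylation_score(probes, controls) == pytest.approx(expected)

    def test_invariant_to_chipwide_rescaling(self, rng):
        probes = rng.uniform(5, 50, 7)
        controls = rng.uniform(5, 50, 4)
        s0 = methylation_score(probes, controls)
        assert methylation_score(probes * 13.7, controls * 13.7) == pytest.approx(s0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            methylation_score([1.0, 0.0], [2.0])


class TestCalibration:
    @staticmethod
    def _raw(values):
        return MethylationMatrix(pd.DataFrame(values), stage="raw")

    def test_anchor_points_map_to_zero_and_one(self):
        raw = self._raw({"s1": [0.3], "s2": [1.9]})
        m0 = pd.Series({0: 0.3})
        m100 = pd.Series({0: 1.9})
        cal, dropped = calibrate_scores(raw, m0, m100)
        assert cal.values_frame.loc[0, "s1"] == pytest.approx(0.0)
        assert cal.values_frame.loc[0, "s2"] == pytest.approx(1.0)
        assert dropped == []

    def test_midpoint_maps_to_half(self):
        raw = self._raw({"s1": [1.1]})
        cal, _ = calibrate_scores(raw, pd.Series({0: 0.3}), pd.Series({0: 1.9}))
        assert cal.values_frame.iloc[0, 0] == pytest.approx(0.5)

    def test_affine_round_trip(self, rng):
        m0 = pd.Series(rng.normal(-0.3, 0.1, 10))
        m100 = m0 + rng.uniform(0.5, 2.0, 10)
        s = pd.DataFrame(rng.normal(0.5, 1.0, (10, 6)))
        cal, _ = calibrate_scores(MethylationMatrix(s, stage="raw"), m0, m100)
        recovered = cal.values_frame.mul(m100 - m0, axis=0).add(m0, axis=0)
        assert np.allclose(recovered.to_numpy(), s.to_numpy())

    def test_identical_anchors_dropped_with_warning(self):
        raw = self._raw({"s1": [0.5, 0.7]})
        m0 = pd.Series({0: 0.2, 1: 1.0})
        m100 = pd.Series({0: 1.2, 1: 1.0})
        with pytest.warns(UserWarning, match="uncalibratable"):
            cal, dropped = calibrate_scores(raw, m0, m100)
        assert dropped == [1]
        assert list(cal.values_frame.index) == [0]


class TestQuantileNormalize:
    def test_identical_samples_fixed_point(self):
        df = pd.DataFrame({"a": [0.1, 0.5, 0.9], "b": [0.1, 0.5, 0.9]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_two_sample_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert list(out["a"]) == [2.5, 3.5, 4.5]
        assert list(out["b"]) == [2.5, 3.5, 4.5]

    def test_distributions_identical_after(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        out = quantile_normalize(df)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcde":
            assert np.allclose(np.sort(out[c].to_numpy()), ref)

    def test_rank_order_preserved_and_ties_averaged(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = quantile_normalize(df)
        # tie in column a receives the mean of the two lowest reference quantiles
        assert out.loc[0, "a"] == out.loc[1, "a"]
        assert out.loc[0, "a"] < out.loc[2, "a"]
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out.loc[0, "a"] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_stage_advances_on_wrapper(self):
        m = MethylationMatrix(
            pd.DataFrame({"a": [0.1, 0.9], "b": [0.2, 0.8]}), stage="calibrated"
        )
        assert quantile_normalize(m).stage == "normalized"


def _probeset_fixture(rng, n_sets=100, n_snps=500, chrom_len=1_000_000):
    rows, probe_rows = [], []
    for i in range(n_sets):
        start = int(rng.integers(1, chrom_len - 300))
        end = start + 200
        ps = f"PS{i:03d}"
        rows.append({"id": ps, "chrom": "1", "start": start, "end": end})
        for k, pos in enumerate(sorted(rng.integers(start, end - 50, size=4))):
            probe_rows.append({"probe": f"{ps}_p{k}", "probeset": ps, "chrom": "1", "pos": int(pos)})
    probesets = pd.DataFrame(rows).set_index("id")
    probes = pd.DataFrame(probe_rows).set_index("probe")
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": rng.integers(1, chrom_len, size=n_snps),
            "maf": rng.uniform(0, 0.5, size=n_snps),
        },
        index=pd.Index([f"rs{i}" for i in range(n_snps)], name="snp"),
    )
    return probesets, probes, snps


class TestSnpFilter:
    def test_empty_panel_keeps_everything(self, rng):
        probesets, probes, _ = _probeset_fixture(rng, n_sets=10)
        empty = pd.DataFrame(columns=["chrom", "pos", "maf"])
        kept, report = filter_probesets_by_snp(probesets, probes, empty)
        assert len(kept) == 10 and len(report) == 0

    def test_threshold_semantics(self):
        probesets = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [300]}, index=["PS0"])
        probes = pd.DataFrame(
            {"probeset": ["PS0"], "chrom": ["1"], "pos": [150]}, index=["PS0_p0"]
        )
        for maf, excluded in [(0.10, True), (0.04, False)]:
            snps = pd.DataFrame({"chrom": ["1"], "pos": [160], "maf": [maf]}, index=["rs1"])
            kept, report = filter_probesets_by_snp(probesets, probes, snps)
            assert ("PS0" not in kept.index) == excluded

    def test_matches_quadratic_oracle(self, rng):
        probesets, probes, snps = _probeset_fixture(rng)
        kept, _ = filter_probesets_by_snp(probesets, probes, snps, 0.05, probe_length=50)
        excluded_oracle = set()
        for probe in probes.itertuples():
            for snp in snps.itertuples():
                if snp.maf > 0.05 and probe.pos <= snp.pos <= probe.pos + 49:
                    excluded_oracle.add(probe.probeset)
        assert set(probesets.index) - set(kept.index) == excluded_oracle

    def test_partition_and_monotonicity(self, rng):
        probesets, probes, snps = _probeset_fixture(rng)
        kept_hi, rep_hi = filter_probesets_by_snp(probesets, probes, snps, 0.25)
        kept_lo, rep_lo = filter_probesets_by_snp(probesets, probes, snps, 0.05)
        excl_hi = set(probesets.index) - set(kept_hi.index)
        excl_lo = set(probesets.index) - set(kept_lo.index)
        assert excl_hi <= excl_lo  # lower threshold excludes a superset
        assert set(kept_lo.index) | excl_lo == set(probesets.index)

    def test_chromosome_mismatch_reported(self, rng):
        probesets, probes, snps = _probeset_fixture(rng, n_sets=5)
        snps["chrom"] = "chr1"
        with pytest.raises(ValueError, match="1"):
            filter_probesets_by_snp(probesets, probes, snps)


class TestQcPatterns:
    def test_constant_half_matrix_is_fully_hemimethylated(self):
        probesets = pd.DataFrame(
            {"chrom": ["X", "X"], "start": [100, 500], "end": [200, 600]}, index=["a", "b"]
        )
        df = pd.DataFrame(0.5, index=["a", "b"], columns=["s1", "s2"])
        sex = pd.Series({"s1": "F", "s2": "M"})
        rep = qc_patterns(df, probesets, sex=sex)
        assert rep.hemimethylated_fraction_female_x == 1.0

    def test_constant_matrix_profile_flat(self):
        probesets = pd.DataFrame(
            {"chrom": ["1"] * 4, "start": [100, 1100, 2100, 3100], "end": [200, 1200, 2200, 3200]},
            index=list("abcd"),
        )
        df = pd.DataFrame(0.4, index=list("abcd"), columns=["s1", "s2"])
        tss = pd.DataFrame({"chrom": ["1"], "tss": [150]})
        rep = qc_patterns(df, probesets, tss_positions=tss)
        assert rep.tss_profile["median_score"].nunique() == 1

    def test_bimodal_mixture_detected(self, rng):
        vals = np.concatenate([rng.normal(0.1, 0.03, 600), rng.normal(0.9, 0.03, 600)])
        df = pd.DataFrame(vals.reshape(-1, 4))
        probesets = pd.DataFrame(
            {"chrom": "1", "start": 1, "end": 2}, index=df.index
        )
        rep = qc_patterns(df, probesets, seed=1)
        assert rep.bimodality_p < 0.05
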