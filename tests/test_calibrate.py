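import math

import numpy as np
import pandas as pd
import pytest

from kasphi.calibrate import (
    calibrate_panel,
    centroid_angles,
    compute_centroids,
    exclude_outliers,
    flag_mismatches,
)
from kasphi.data_model import CalibrationError, PopulationDesign
from kasphi.simulate import SimConfig, simulate_experiment
from kasphi.pipeline import run_calibration


def _signals(points, snp="snp01"):
    """points: {sample_id: (fam, hex)} -> averaged-signal frame."""
    return pd.DataFrame(
        [
            dict(sample_id=s, snp_id=snp, dataset="swab", fam_mean=f, hex_mean=h,
                 n_replicates=4)
            for s, (f, h) in points.items()
        ]
    )


class TestCentroids:
    def test_componentwise_median_odd_and_even(self):
        pts = {"a": (1, 3), "b": (2, 4), "c": (3, 5)}
        expected = {s: "AB" for s in pts}
        # single-class SNP would fail the three-class check; use all classes
        pts.update({"x1": (0.1, 3.0), "x2": (0.3, 2.8), "y1": (3.0, 0.1), "y2": (2.8, 0.3)})
        expected.update({"x1": "A", "x2": "A", "y1": "B", "y2": "B"})
        cents = compute_centroids(_signals(pts), expected)
        ab = cents[cents["genotype"] == "AB"].iloc[0]
        assert (ab["fam"], ab["hex"]) == (2, 4)  # odd n: middle point per axis
        a = cents[cents["genotype"] == "A"].iloc[0]
        assert (a["fam"], a["hex"]) == (0.2, 2.9)  # even n: midpoint per axis
        assert a["n_points"] == 2

    def test_missing_class_raises(self):
        pts = {"a": (0.1, 3.0), "b": (3.0, 0.1)}
        with pytest.raises(CalibrationError, match="AB"):
            compute_centroids(_signals(pts), {"a": "A", "b": "B"})


def _three_cluster_setup():
    """Well-separated A/AB/B clusters plus their centroid frame."""
    pts = {
        "a1": (0.2, 3.0), "a2": (0.3, 2.9), "a3": (0.25, 3.1),
        "h1": (2.0, 2.1), "h2": (2.1, 2.0), "h3": (1.9, 2.0),
        "b1": (3.0, 0.3), "b2": (2.9, 0.2), "b3": (3.1, 0.25),
    }
    expected = {s: ("A" if s[0] == "a" else "AB" if s[0] == "h" else "B") for s in pts}
    cents = compute_centroids(_signals(pts), expected)
    return pts, expected, cents


class TestMismatches:
    def test_zero_distance_to_expected_not_flagged(self):
        _, expected, cents = _three_cluster_setup()
        sig = _signals({"h1": (2.0, 2.0)})
        res = flag_mismatches(sig, {"h1": "AB"}, cents)
        assert res.mismatches.empty

    def test_point_at_wrong_centroid_flagged_and_edna_propagated(self):
        _, expected, cents = _three_cluster_setup()
        b_cent = cents[(cents["genotype"] == "B")].iloc[0]
        sig = _signals({"a1": (b_cent["fam"], b_cent["hex"])})
        designs = [
            PopulationDesign("P1", [("a1", "A", 10.0), ("z9", "AB", 10.0)], 30.0,
                             "low_conc", 0.25),
            PopulationDesign("P1", [("a1", "A", 10.0), ("z9", "AB", 10.0)], 6.0,
                             "high_conc", 0.25),
        ]
        res = flag_mismatches(sig, {"a1": "A"}, cents, designs)
        assert len(res.mismatches) == 1
        row = res.mismatches.iloc[0]
        assert row["assigned_genotype"] == "A" and row["nearest_genotype"] == "B"
        assert ("P1", "snp01") in res.excluded_edna_calls
        # flagged at its only typed SNP -> the animal and its container go too
        assert res.excluded_animals == {"a1"}
        assert res.excluded_populations == {"P1"}

    def test_animal_mismatched_at_all_snps_fully_excluded(self):
        # mislabelled animal: expected A but heterozygous-looking at every SNP
        frames, expected = [], {}
        for i in range(1, 10):
            pts, exp, _ = _three_cluster_setup()
            pts["m12"] = (2.0, 2.05)  # near the AB cluster
            frames.append(_signals(pts, snp=f"snp{i:02d}"))
            expected.update(exp)
        expected["m12"] = "A"
        sig = pd.concat(frames, ignore_index=True)
        cents = compute_centroids(sig, expected)
        designs = [
            PopulationDesign("P3", [("m12", "A", 10.0), ("a1", "A", 10.0)], 30.0,
                             "low_conc", 0.0)
        ]
        res = flag_mismatches(sig, expected, cents, designs)
        assert "m12" in res.excluded_animals
        assert "P3" in res.excluded_populations
        assert sum(s == "m12" for s, _ in res.excluded_swab_calls) == 9

    def test_distance_tie_is_ambiguous_mismatch(self):
        cents = pd.DataFrame(
            [
                dict(snp_id="snp01", genotype="A", fam=0.0, hex=2.0, n_points=3),
                dict(snp_id="snp01", genotype="AB", fam=1.0, hex=1.0, n_points=3),
                dict(snp_id="snp01", genotype="B", fam=2.0, hex=0.0, n_points=3),
            ]
        )
        sig = _signals({"t1": (0.5, 1.5)})  # equidistant from A and AB
        res = flag_mismatches(sig, {"t1": "AB"}, cents)
        assert len(res.mismatches) == 1 and res.mismatches.iloc[0]["ambiguous"]


class TestOutliers:
    def _cluster_with_distances(self, dists):
        """Points on the FAM axis at given distances from centroid (5, 0)."""
        cents = pd.DataFrame(
            [
                dict(snp_id="s", genotype="A", fam=5.0, hex=0.0, n_points=len(dists)),
                dict(snp_id="s", genotype="AB", fam=0.0, hex=0.0, n_points=1),
                dict(snp_id="s", genotype="B", fam=0.0, hex=5.0, n_points=1),
            ]
        )
        sig = _signals(
            {f"p{i}": (5.0 + d, 0.0) for i, d in enumerate(dists)}, snp="s"
        )
        expected = {f"p{i}": "A" for i in range(len(dists))}
        return sig, cents, expected

    def test_mad_threshold_hand_computed(self):
        # d = {0.1,0.2,0.3,0.4,2.0}: median 0.3, MAD = 1.4826*0.1,
        # threshold = 0.3 + 3*0.14826 = 0.74478 -> only d=2.0 excluded
        sig, cents, expected = self._cluster_with_distances([0.1, 0.2, 0.3, 0.4, 2.0])
        retained, outliers = exclude_outliers(sig, cents, expected)
        assert list(outliers["sample_id"]) == ["p4"]
        assert outliers.iloc[0]["threshold"] == pytest.approx(0.74478)
        assert len(retained) == 4

    def test_all_equal_distances_excludes_none(self):
        sig, cents, expected = self._cluster_with_distances([0.5, 0.5, 0.5, 0.5])
        retained, outliers = exclude_outliers(sig, cents, expected)
        assert outliers.empty and len(retained) == 4

    def test_zero_mad_excludes_only_strictly_above_median(self):
        sig, cents, expected = self._cluster_with_distances([0.0, 0.0, 0.0, 5.0])
        with pytest.warns(UserWarning, match="zero MAD"):
            retained, outliers = exclude_outliers(sig, cents, expected)
        assert list(outliers["sample_id"]) == ["p3"]
        assert len(retained) == 3

    def test_singleton_cluster_warns_and_keeps(self):
        sig, cents, expected = self._cluster_with_distances([1.0])
        with pytest.warns(UserWarning, match="single point"):
            retained, outliers = exclude_outliers(sig, cents, expected)
        assert outliers.empty and len(retained) == 1


class TestAngles:
    @pytest.mark.parametrize(
        "fam,hex_,angle", [(1, 0, 0.0), (0, 1, 90.0), (1, 1, 45.0)]
    )
    def test_axis_and_diagonal_angles(self, fam, hex_, angle):
        cents = pd.DataFrame(
            [
                dict(snp_id="s", genotype="A", fam=0.1, hex=3.0, n_points=1),
                dict(snp_id="s", genotype="AB", fam=fam, hex=hex_, n_points=1),
                dict(snp_id="s", genotype="B", fam=3.0, hex=0.1, n_points=1),
            ]
        )
        if angle in (0.0, 90.0):
            # AB at an axis breaks the ordering -> calibration error
            with pytest.raises(CalibrationError):
                centroid_angles(cents)
        else:
            assert centroid_angles(cents)["s"].alpha_ab == pytest.approx(angle)

    def test_ordering_violation_is_calibration_error(self):
        cents = pd.DataFrame(
            [
                dict(snp_id="s", genotype="A", fam=3.0, hex=0.1, n_points=1),
                dict(snp_id="s", genotype="AB", fam=1.0, hex=1.0, n_points=1),
                dict(snp_id="s", genotype="B", fam=0.1, hex=3.0, n_points=1),
            ]
        )
        with pytest.raises(CalibrationError, match="ordering"):
            centroid_angles(cents)

    def test_angles_invariant_under_uniform_scaling(self):
        base = pd.DataFrame(
            [
                dict(snp_id="s", genotype="A", fam=0.4, hex=2.9, n_points=1),
                dict(snp_id="s", genotype="AB", fam=1.8, hex=2.1, n_points=1),
                dict(snp_id="s", genotype="B", fam=3.0, hex=0.6, n_points=1),
            ]
        )
        scaled = base.assign(fam=base["fam"] * 7.3, hex=base["hex"] * 7.3)
        a, b = centroid_angles(base)["s"], centroid_angles(scaled)["s"]
        for attr in ("alpha_a", "alpha_ab", "alpha_b"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-12)


class TestFullCalibration:
    def test_clean_simulation_yields_no_mismatches(self):
        cfg = SimConfig(dropout_rate=0.0, false_het_rate=0.0, low_signal_rate=0.0,
                        swab_angle_sd=0.5)
        exp = simulate_experiment(cfg, seed=21)
        cal, _ = run_calibration(exp.fluorescence, exp.design)
        assert cal.mismatch.mismatches.empty

    def test_angle_recovery_improves_with_less_noise(self):
        errs = {}
        for sd in (4.0, 0.2):
            cfg = SimConfig(dropout_rate=0.0, false_het_rate=0.0,
                            low_signal_rate=0.0, swab_angle_sd=sd)
            exp = simulate_experiment(cfg, seed=22)
            cal, _ = run_calibration(exp.fluorescence, exp.design)
            errs[sd] = max(
                abs(cal.calibrations[s].alpha_ab - exp.panel[s].alpha_ab)
                for s in exp.panel
            )
        assert errs[0.2] < errs[4.0]
        assert errs[0.2] < 0.2

    def test_idempotent_with_zero_outliers(self):
        cfg = SimConfig(dropout_rate=0.0, false_het_rate=0.0, low_signal_rate=0.0,
                        swab_angle_sd=0.0, radius_log_sd=0.0)
        exp = simulate_experiment(cfg, seed=23)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-noise clusters have zero MAD
            cal, _ = run_calibration(exp.fluorescence, exp.design)
        assert cal.outliers.empty
        pd.testing.assert_frame_equal(
            cal.raw_centroids.sort_values(["snp_id", "genotype"]).reset_index(drop=True),
            cal.final_centroids.sort_values(["snp_id", "genotype"]).reset_index(drop=True),
        )
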