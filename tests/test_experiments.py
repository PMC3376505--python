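"""Calibration fixed point, scans, threshold bisection and the ROS report."""

import numpy as np
import pandas as pd
import pytest

from mitodyn.experiments import (ScanResult, calibrate_reference_state,
                                 find_half_nadh_inhibition, ros_site_report,
                                 scan_load, scan_inhibition,
                                 solve_steady_state)


class TestCalibration:
    def test_fixture_is_calibration_fixed_point(self, fixture_config):
        """The bundled parameter set already satisfies the share and redox
        targets, so calibration (capacity stage skipped for speed) returns
        it unchanged after a single verification pass."""
        cfg2, report, y_ref = calibrate_reference_state(
            fixture_config, with_capacity=False)
        assert report.converged
        assert report.iterations == 1
        assert cfg2.transporters.kappa_c4 == \
            fixture_config.transporters.kappa_c4
        cal = fixture_config.calibration
        assert report.achieved["share_leak"] == pytest.approx(
            cal.share_leak, abs=cal.share_tolerance)
        assert report.achieved["share_atp"] == pytest.approx(
            cal.share_atp, abs=cal.share_tolerance)

    def test_summary_lists_targets(self, fixture_config):
        _, report, _ = calibrate_reference_state(fixture_config,
                                                 with_capacity=False)
        text = report.summary()
        assert "share_leak" in text and "nadh_ratio" in text


class TestScans:
    @pytest.fixture(scope="class")
    def small_load_scan(self, reference_system, reference_state):
        return scan_load(reference_system, np.array([0.8, 1.0, 1.3]),
                         reference_state)

    def test_grid_must_be_monotone(self):
        with pytest.raises(ValueError, match="monotone"):
            ScanResult("x", np.array([1.0, 0.5, 2.0]), [{}, {}, {}])

    def test_single_point_scan_normalizes_to_one(self, reference_system,
                                                 reference_state):
        scan = scan_load(reference_system, np.array([1.0]), reference_state)
        frame = scan.to_frame()
        assert len(frame) == 1
        for col in ("nadh_norm", "atp_production_norm",
                    "o2_consumption_norm"):
            assert frame[col].iloc[0] == pytest.approx(1.0, rel=1e-6)

    def test_load_scan_monotone_responses(self, small_load_scan):
        frame = small_load_scan.to_frame()
        assert frame["converged"].all()
        # NADH falls and oxygen consumption rises with energetic demand
        assert np.all(np.diff(frame["nadh"]) < 0)
        assert np.all(np.diff(frame["o2_consumption"]) > 0)

    def test_inhibition_scan_reference_row(self, reference_system,
                                           reference_state):
        scan = scan_inhibition(reference_system, "KGDHC",
                               np.array([0.0, 0.3]), 1.0,
                               reference_state, with_capacity=False)
        frame = scan.to_frame()
        # zero inhibition reproduces the uninhibited reference
        assert frame["nadh_norm"].iloc[0] == pytest.approx(1.0, rel=1e-6)
        assert frame["akg"].iloc[1] > frame["akg"].iloc[0]

    def test_inhibition_scan_rejects_unknown_enzyme(self, reference_system):
        with pytest.raises(ValueError):
            scan_inhibition(reference_system, "CS", np.array([0.1]))


class TestHalfNadhBisection:
    def test_enzyme_without_nadh_control_reports_unattained(
            self, reference_system, reference_state):
        """Fumarase carries a large capacity excess, so inhibition across
        the probed range leaves the NADH level essentially unchanged and
        the half-reduction target is never bracketed."""
        frac, attained = find_half_nadh_inhibition(
            reference_system, "FUM", reference_state=reference_state,
            hi=0.6)
        assert not attained
        assert np.isnan(frac)


class TestRosReport:
    def test_reference_point_normalizes_to_one(self, reference_system,
                                               reference_state):
        scan = scan_inhibition(reference_system, "KGDHC",
                               np.array([0.0, 0.4]), 1.0,
                               reference_state, with_capacity=False)
        report = ros_site_report(scan)
        assert isinstance(report, pd.DataFrame)
        row0 = report.iloc[0]
        for site in ("occ_flavin_reduced_norm", "occ_CIII_SQp_norm",
                     "occ_CI_SQ_norm"):
            assert row0[site] == pytest.approx(1.0, rel=1e-6)

    def test_inhibition_lowers_flavin_and_sqp_occupancy(self,
                                                        reference_system,
                                                        reference_state):
        """KGDHC inhibition at fixed load oxidizes the chain: the fully
        reduced flavin and the p-site semiquinone occupancies fall, while
        the complex I bound-SQ occupancy barely moves."""
        scan = scan_inhibition(reference_system, "KGDHC",
                               np.array([0.0, 0.4]), 1.0,
                               reference_state, with_capacity=False)
        report = ros_site_report(scan)
        last = report.iloc[-1]
        assert last["occ_flavin_reduced_norm"] < 0.8
        assert last["occ_CIII_SQp_norm"] < 1.0
        assert abs(last["occ_CI_SQ_norm"] - 1.0) < 0.05
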