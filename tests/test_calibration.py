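"""Bead line, quantile bridge and FSC gate derivation."""

import numpy as np
import pytest

import rgcflow as rf
from rgcflow.calibration import DegenerateFitError, GateInterval
from conftest import PRINTED_DA, PRINTED_DV, PRINTED_Q


def _normal_equations(x, y):
    """Least-squares line via the normal equations (independent oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy, syy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return slope, intercept, r


class TestFitLine:
    def test_printed_pairs_slope_and_r(self):
        cal = rf.fit_line(PRINTED_DA, PRINTED_DV, role="bridge")
        assert round(cal.slope, 2) == 1.61
        assert round(cal.r, 4) == 0.9718

    def test_identity_line(self):
        cal = rf.fit_line([0, 1, 2, 3], [0, 1, 2, 3])
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = rng.integers(3, 40)
            x = rng.normal(50, 20, n)
            y = rng.normal(0, 1, n) + rng.uniform(-2, 2) * x
            cal = rf.fit_line(x, y)
            slope, intercept, r = _normal_equations(x, y)
            assert cal.slope == pytest.approx(slope, abs=1e-10)
            assert cal.intercept == pytest.approx(intercept, abs=1e-10)
            assert cal.r == pytest.approx(r, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateFitError):
            rf.fit_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateFitError):
            rf.fit_line([1.0], [1.0])


class TestBeadCalibration:
    def test_noiseless_beads_recover_planted_line(self):
        samples = rf.generate_bead_sample(cv=0.0, n=500, seed=1)
        cal = rf.fit_bead_calibration(samples)
        assert cal.slope == pytest.approx(0.027, abs=1e-4)
        assert cal.intercept == pytest.approx(2.16, abs=1e-4)
        assert cal.role == "bead"

    def test_noisy_beads_recover_slope_within_two_percent(self):
        samples = rf.generate_bead_sample(cv=0.03, n=10_000, seed=2)
        cal = rf.fit_bead_calibration(samples)
        assert cal.slope == pytest.approx(0.027, rel=0.02)

    def test_two_sizes_exact_interpolating_line(self):
        samples = rf.generate_bead_sample(diameters_um=(6.0, 20.0), cv=0.0,
                                          n=100, seed=3)
        cal = rf.fit_bead_calibration(samples)
        assert cal.r == pytest.approx(1.0)
        assert float(cal.predict((6.0 - 2.16) / 0.027)) == pytest.approx(6.0)

    def test_replicate_means_used(self):
        samples = rf.generate_bead_sample(cv=0.03, n=2000, seed=4, replicates=3)
        assert all(len(reps) == 3 for reps in samples.values())
        cal = rf.fit_bead_calibration(samples)
        assert cal.slope == pytest.approx(0.027, rel=0.05)

    def test_single_bead_size_degenerate(self):
        samples = rf.generate_bead_sample(diameters_um=(10.0,), cv=0.0, n=10)
        with pytest.raises(DegenerateFitError):
            rf.fit_bead_calibration(samples)


class TestFscDiameterConversion:
    def test_intercept_at_zero_fsc(self):
        assert rf.fsc_to_diameter(0.0, rf.PAPER_2012_BEAD) == pytest.approx(2.16)

    def test_published_small_medium_gate(self):
        fsc = rf.diameter_to_fsc(13.26, rf.PAPER_2012_BEAD)
        assert round(fsc) == 411

    def test_round_trip_identity(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(2, 25, 100)
        back = rf.fsc_to_diameter(rf.diameter_to_fsc(d, rf.PAPER_2012_BEAD),
                                  rf.PAPER_2012_BEAD)
        np.testing.assert_allclose(back, d, rtol=1e-12)

    def test_role_enforced(self):
        with pytest.raises(ValueError):
            rf.fsc_to_diameter(100.0, rf.PAPER_2012_BRIDGE)


class TestQuantilePairs:
    def test_published_difference_column(self, printed_pairs):
        assert printed_pairs.difference_pct[0] == pytest.approx(-7.97, abs=5e-3)
        assert printed_pairs.difference_pct[4] == pytest.approx(61.63, abs=5e-3)

    def test_identical_distributions_zero_difference(self):
        rng = np.random.default_rng(21)
        areas = rng.lognormal(3.2, 0.5, 5000)
        # FSC events whose bead-line diameters equal the area diameters
        fsc = rf.diameter_to_fsc(rf.area_to_diameter(areas), rf.PAPER_2012_BEAD)
        pairs = rf.build_quantile_pairs(areas, fsc, PRINTED_Q, rf.PAPER_2012_BEAD)
        # interpolation between ranks happens in area space on one side and
        # FSC space on the other, so agreement is near-exact, not bitwise
        np.testing.assert_allclose(pairs.difference_pct, 0.0, atol=1e-4)

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            rf.QuantilePairSet.from_printed([5, 20], [5.0, 4.0], [6.0, 7.0])

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            rf.build_quantile_pairs([], [100.0], [50.0], rf.PAPER_2012_BEAD)


class TestBridge:
    def test_printed_pairs(self, printed_pairs):
        cal = rf.fit_bridge(printed_pairs)
        assert round(cal.slope, 2) == 1.61
        assert round(cal.r, 4) == 0.9718
        assert cal.role == "bridge"

    def test_exact_line_r_one(self):
        pairs = rf.QuantilePairSet.from_printed(
            [5, 50, 95], [4.0, 8.0, 12.0], [1.61 * d - 1.94 for d in (4.0, 8.0, 12.0)])
        assert rf.fit_bridge(pairs).r == pytest.approx(1.0)


class TestDeriveGates:
    def test_published_gate_chain(self, paper_gates):
        assert paper_gates.medium.fsc[0] == 411
        assert paper_gates.large.fsc[0] == 601
        assert paper_gates.small.d_v_um[1] == pytest.approx(13.26)
        assert paper_gates.medium.d_a_um == (9.44, 12.62)

    def test_truncation_convention_reproduces_lowest_bound(self):
        gates = rf.derive_fsc_gates([15, 70, 125], rf.PAPER_2012_BRIDGE,
                                    rf.PAPER_2012_BEAD, round_intermediates=True,
                                    fsc_rounding="truncate")
        assert gates.small.fsc[0] == 108

    def test_identity_calibrations_pass_through_diameters(self):
        identity_bridge = rf.LinearCalibration(1.0, 0.0, 1.0, "bridge")
        identity_bead = rf.LinearCalibration(1.0, 0.0, 1.0, "bead")
        gates = rf.derive_fsc_gates([15, 70, 125], identity_bridge, identity_bead)
        for cls, bound in (("small", 15.0), ("medium", 70.0), ("large", 125.0)):
            gate: GateInterval = getattr(gates, cls)
            assert gate.fsc[0] == round(rf.area_to_diameter(bound))

    def test_gate_json_round_trip(self, paper_gates, tmp_path):
        p = tmp_path / "gates.json"
        paper_gates.save(p)
        assert rf.SizeGateScheme.load(p) == paper_gates

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            rf.derive_fsc_gates([70, 15, 125], rf.PAPER_2012_BRIDGE,
                                rf.PAPER_2012_BEAD)


class TestEndToEndRecovery:
    def test_planted_bridge_recovered_from_synthetic_chain(self):
        """Areas pushed through circle-equation -> bridge -> bead line with
        measurement noise; the refitted bridge recovers the planted line."""
        rng = np.random.default_rng(33)
        n = 10_000
        areas = rng.lognormal(np.log(30.0), 0.5, n)
        d_a = rf.area_to_diameter(areas)
        d_v = rf.PAPER_2012_BRIDGE.predict(d_a)
        fsc = rf.diameter_to_fsc(d_v, rf.PAPER_2012_BEAD)
        fsc = np.maximum(fsc * (1 + rng.normal(0, 0.03, n)), 0.0)
        pairs = rf.build_quantile_pairs(areas, fsc, PRINTED_Q, rf.PAPER_2012_BEAD)
        cal = rf.fit_bridge(pairs)
        assert cal.slope == pytest.approx(1.61, rel=0.05)
        assert cal.intercept == pytest.approx(-1.94, rel=0.05)
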