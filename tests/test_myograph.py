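"""Organ-bath analysis: plateaus, ring calibration, anchored relaxation,
bronchodilation fits and onset timing."""

import numpy as np
import pytest

from ionscreen.dose_response import ec_fraction, hill_model
from ionscreen.myograph_analysis import (Event, EventKind,
                                         RingDisqualifiedError, TensionTrace,
                                         bronchodilation_ec50, calibrate_ring,
                                         onset_time, percent_relaxation,
                                         plateau_tension, read_tension_csv,
                                         write_tension_csv)
from ionscreen.synthetic_data import (gen_calibration_ring,
                                      gen_precontracted_ring)


def simple_trace(tension, events, dt=1.0):
    tension = np.asarray(tension, dtype=float)
    return TensionTrace("r1", np.arange(tension.size) * dt, tension, events)


class TestPlateau:
    def test_constant_segment(self):
        y = np.concatenate([np.full(60, 5.0), np.full(240, 10.0)])
        tr = simple_trace(y, [Event(59.5, EventKind.DOSE_CONTRACTANT, 1.0)])
        res = plateau_tension(tr, 0)
        assert res.value_mN == pytest.approx(10.0) and res.plateaued

    def test_ramp_flagged_not_plateaued(self):
        t = np.arange(300.0)
        y = 5.0 + 0.02 * t
        tr = simple_trace(y, [Event(0.5, EventKind.DOSE_CONTRACTANT, 1.0)])
        res = plateau_tension(tr, 0)
        assert not res.plateaued

    def test_exponential_approach_converges(self):
        t = np.arange(600.0)
        y = 10.0 * (1.0 - np.exp(-t / 60.0))
        tr = simple_trace(y, [Event(0.5, EventKind.DOSE_CONTRACTANT, 1.0)])
        res = plateau_tension(tr, 0)
        assert res.value_mN == pytest.approx(10.0, abs=0.01)


class TestCalibration:
    def test_recovers_generated_ring(self):
        trace, truth = gen_calibration_ring(seed=2)
        cal = calibrate_ring(trace)
        assert cal.ec50 == pytest.approx(truth["cch_ec50_uM"], rel=0.05)
        assert cal.ec25 < cal.ec50 < cal.ec75 < cal.ec95

    def test_ec75_matches_algebra(self):
        trace, _ = gen_calibration_ring(seed=2)
        cal = calibrate_ring(trace)
        assert cal.ec75 == pytest.approx(
            ec_fraction(cal.ec50, cal.contraction_fit.hill_slope, 75), rel=1e-9)

    def test_self_consistency_dosing_at_own_ecf(self):
        # a fresh ring dosed at the calibrated EC75 contracts to ~75% of span
        trace, truth = gen_calibration_ring(seed=3)
        cal = calibrate_ring(trace)
        ring = gen_precontracted_ring(
            "r2", precontract_conc_uM=cal.ec75,
            cch_ec50_uM=truth["cch_ec50_uM"], seed=3)
        idx = ring.events_of_kind(EventKind.DOSE_CONTRACTANT)[0][0]
        plateau = plateau_tension(ring, idx).value_mN
        span = cal.contraction_fit.bottom - cal.contraction_fit.top
        expected = cal.baseline_mN + 0.75 * span
        assert plateau == pytest.approx(expected, rel=0.01)

    def test_flat_ring_disqualified(self):
        events = [Event(60.0 + 100.0 * k, EventKind.DOSE_CONTRACTANT,
                        10.0 ** (k - 2)) for k in range(5)]
        tr = simple_trace(np.full(600, 5.0), events)
        with pytest.raises(RingDisqualifiedError, match="span"):
            calibrate_ring(tr)

    def test_non_monotone_ring_disqualified(self):
        y = np.concatenate([np.full(60, 5.0), np.full(100, 8.0),
                            np.full(100, 14.0), np.full(100, 9.0),
                            np.full(100, 15.0), np.full(140, 15.0)])
        events = [Event(60.0 + 100.0 * k, EventKind.DOSE_CONTRACTANT,
                        10.0 ** (k - 2)) for k in range(5)]
        tr = simple_trace(y, events)
        with pytest.raises(RingDisqualifiedError, match="non-monotone"):
            calibrate_ring(tr)


class TestPercentRelaxation:
    def test_anchors_exact(self):
        assert percent_relaxation(10.0, 2.0, 10.0) == pytest.approx(0.0)
        assert percent_relaxation(10.0, 2.0, 2.0) == pytest.approx(100.0)

    def test_linear_between_anchors(self):
        assert percent_relaxation(10.0, 2.0, 6.0) == pytest.approx(50.0)

    def test_beyond_floor_exceeds_100_unclamped(self):
        assert percent_relaxation(10.0, 2.0, 1.0) > 100.0

    def test_invalid_ring(self):
        with pytest.raises(ValueError, match="exceed"):
            percent_relaxation(2.0, 5.0, 3.0)


class TestBronchodilationFit:
    def test_noiseless_round_trip(self):
        c = 10.0 ** np.arange(-3.0, 1.1, 0.5)
        rel = hill_model(c, 0.38, 1.5, 0.0, 100.0)
        fit = bronchodilation_ec50(list(zip(c, rel)))
        assert fit.converged
        assert fit.midpoint == pytest.approx(0.38, rel=1e-3)
        assert fit.hill_slope == pytest.approx(1.5, rel=1e-3)

    def test_partial_relaxer_censored(self):
        c = 10.0 ** np.arange(-3.0, 1.1, 0.5)
        rel = hill_model(c, 0.1, 1.0, 0.0, 40.0)  # tops out at 40%
        fit = bronchodilation_ec50(list(zip(c, rel)))
        assert not fit.converged
        assert fit.censored_at == pytest.approx(c.max())

    def test_short_waits_right_shift_apparent_ec50(self):
        # slow-equilibrating relaxant scored with 10-min vs 60-min doses:
        # truncated equilibration at low doses compresses the curve rightward
        mids = {}
        for wait in (600.0, 3600.0):
            ring = gen_precontracted_ring(
                "r", precontract_conc_uM=0.9, relax_ec50_uM=0.05,
                tau_s=900.0, segment_s=wait, noise_sd_mN=0.001, seed=6)
            test = ring.events_of_kind(EventKind.DOSE_TEST)
            pre = ring.events_of_kind(EventKind.DOSE_CONTRACTANT)[0][0]
            theo = ring.events_of_kind(EventKind.DOSE_THEOPHYLLINE)[0][0]
            tc = plateau_tension(ring, pre).value_mN
            tf = plateau_tension(ring, theo).value_mN
            pts = [(e.conc_uM, percent_relaxation(
                tc, tf, plateau_tension(ring, i).value_mN)) for i, e in test]
            mids[wait] = bronchodilation_ec50(pts).midpoint
        assert mids[600.0] > mids[3600.0]


class TestPartialVsFullContrast:
    def test_max_relaxation_pattern_across_contraction_levels(self):
        maxima = {}
        for mech in ("proportional", "capacity"):
            vals = []
            for frac in (25, 50, 75, 95):
                conc = ec_fraction(0.3, 1.0, frac)
                ring = gen_precontracted_ring(
                    "r", precontract_conc_uM=conc, mechanism=mech, seed=11)
                pre = ring.events_of_kind(EventKind.DOSE_CONTRACTANT)[0][0]
                theo = ring.events_of_kind(EventKind.DOSE_THEOPHYLLINE)[0][0]
                tc = plateau_tension(ring, pre).value_mN
                tf = plateau_tension(ring, theo).value_mN
                rel = [percent_relaxation(tc, tf,
                                          plateau_tension(ring, i).value_mN)
                       for i, _ in ring.events_of_kind(EventKind.DOSE_TEST)]
                vals.append(max(rel))
            maxima[mech] = vals
        # the channel-blocker-like agent relaxes ~fully at every level
        assert all(v > 90.0 for v in maxima["proportional"])
        # the capacity-limited agent loses efficacy as contraction rises
        cap = maxima["capacity"]
        assert cap[0] > 95.0 and cap[-1] < 60.0
        assert all(a >= b - 1.0 for a, b in zip(cap, cap[1:]))


class TestOnset:
    @staticmethod
    def relaxation_trace(tau=60.0, duration=1200.0):
        t = np.arange(duration)
        y = np.where(t < 60.0, 10.0, 2.0 + 8.0 * np.exp(-(t - 60.0) / tau))
        return simple_trace(y, [Event(59.5, EventKind.DOSE_TEST, 1.0)])

    def test_instant_step_is_zero(self):
        y = np.concatenate([np.full(60, 10.0), np.full(600, 2.0)])
        tr = simple_trace(y, [Event(59.5, EventKind.DOSE_TEST, 1.0)])
        res = onset_time(tr, 0)
        assert res.time_s == pytest.approx(0.0) and not res.censored

    def test_first_order_three_tau(self):
        res = onset_time(self.relaxation_trace(tau=60.0), 0, fraction=0.95)
        assert not res.censored
        assert res.time_s == pytest.approx(180.0, abs=5.0)

    def test_non_plateauing_drift_censored(self):
        t = np.arange(400.0)
        y = 10.0 - 0.01 * t
        tr = simple_trace(y, [Event(0.5, EventKind.DOSE_TEST, 1.0)])
        assert onset_time(tr, 0).censored


def test_tension_csv_round_trip(tmp_path):
    trace, _ = gen_calibration_ring(seed=5)
    write_tension_csv([trace], tmp_path / "t.csv", tmp_path / "e.csv")
    back = read_tension_csv(tmp_path / "t.csv", tmp_path / "e.csv")
    assert len(back) == 1
    np.testing.assert_allclose(back[0].tension, trace.tension)
    cal_a, cal_b = calibrate_ring(trace), calibrate_ring(back[0])
    assert cal_b.ec50 == pytest.approx(cal_a.ec50, rel=1e-9)
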