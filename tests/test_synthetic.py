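"""Synthetic-data generators: determinism, closed-form limits, truth joins."""

import numpy as np
import pytest

from ionscreen.assay_core import WellRole, score_trace_max_min_max
from ionscreen.plate_normalization import ControlSummary, normalize_poc, poc_to_poi
from ionscreen.synthetic_data import (CompoundClass, CompoundTruth,
                                      ScreenScenario, gen_ca_flux,
                                      gen_compound_truths, gen_ephys_cells,
                                      gen_screen, gen_screen_plates,
                                      time_to_fraction_block_min,
                                      DEFAULT_KON_SLOW)
from ionscreen.ephys_analysis import normalize_cell
from ionscreen.pipeline import score_plates, poc_table


def small_scenario(**kw):
    defaults = dict(n_compounds=352, seed=9)
    defaults.update(kw)
    return ScreenScenario(**defaults)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        p1, t1 = gen_screen(small_scenario())
        p2, t2 = gen_screen(small_scenario())
        assert t1 == t2
        for a, b in zip(p1, p2):
            for name in a.wells:
                np.testing.assert_array_equal(a.wells[name].trace.values,
                                              b.wells[name].trace.values)

    def test_different_seed_differs(self):
        p1, _ = gen_screen(small_scenario(seed=9))
        p2, _ = gen_screen(small_scenario(seed=10))
        a = p1[0].wells["A1"].trace.values
        b = p2[0].wells["A1"].trace.values
        assert not np.array_equal(a, b)


class TestScreenGenerator:
    def test_no_actives_no_signal(self):
        sc = small_scenario(
            mixture={"INACTIVE": 1.0, "FULL_BLOCKER": 0.0, "PARTIAL_BLOCKER": 0.0,
                     "FLUORESCENT_ARTIFACT": 0.0, "CA_INTERFERER": 0.0},
            read_cv=1e-9)
        plates, _ = gen_screen(sc)
        scored = score_plates(plates, "decrease")
        poc, _, _ = poc_table(scored)
        assert np.abs(poc["poi"]).max() < 0.5

    def test_full_blocker_poi_approaches_100(self):
        sc = small_scenario(read_cv=1e-9)
        truth = CompoundTruth("B1", CompoundClass.FULL_BLOCKER, ic50_uM=0.001)
        rng = np.random.default_rng(0)
        plates = gen_screen_plates([truth], sc, rng)
        scored = score_plates(plates, "decrease")
        poc, _, _ = poc_table(scored)
        assert poc["poi"].iloc[0] == pytest.approx(100.0, abs=0.5)

    def test_plate_layout_controls_in_cols_23_24(self):
        plates, _ = gen_screen(small_scenario())
        plate = plates[0]
        assert len(plate.wells_by_role(WellRole.NEUTRAL_CONTROL)) == 16
        assert len(plate.wells_by_role(WellRole.INHIBITOR_CONTROL)) == 16
        assert all(w.endswith("23") for w in
                   plate.wells_by_role(WellRole.NEUTRAL_CONTROL))
        plate.require_normalizable()

    def test_artifact_raises_baseline_and_dilutes_quench(self):
        sc = small_scenario(read_cv=1e-9)
        art = CompoundTruth("A1", CompoundClass.FLUORESCENT_ARTIFACT,
                            fi_offset_frac=3.0)
        rng = np.random.default_rng(0)
        plates = gen_screen_plates([art], sc, rng)
        scored = score_plates(plates, "decrease")
        test = scored[scored.role == "TEST"].iloc[0]
        neutral_fi = scored[scored.role == "NEUTRAL_CONTROL"]["baseline_fi"]
        assert test["baseline_fi"] > 2.5 * neutral_fi.median()
        # offset makes an inactive compound look like an inhibitor
        assert test["response"] < sc.neutral_quench * 0.5

    def test_truth_mixture_proportions(self):
        sc = ScreenScenario(n_compounds=20_000, seed=1)
        truths = gen_compound_truths(sc, np.random.default_rng(sc.seed))
        frac_inactive = np.mean([t.cls is CompoundClass.INACTIVE for t in truths])
        assert frac_inactive == pytest.approx(0.97, abs=0.01)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ScreenScenario(mixture={"INACTIVE": 0.5, "FULL_BLOCKER": 0.1,
                                    "PARTIAL_BLOCKER": 0.1,
                                    "FLUORESCENT_ARTIFACT": 0.1,
                                    "CA_INTERFERER": 0.1})


class TestCaFluxGenerator:
    def test_interferer_suppresses_flux_signal(self):
        sc = small_scenario(read_cv=1e-9)
        rng = np.random.default_rng(0)
        interferer = CompoundTruth("X1", CompoundClass.CA_INTERFERER, ic50_uM=1.0)
        clean = CompoundTruth("X2", CompoundClass.FULL_BLOCKER, ic50_uM=0.1)
        plates = gen_ca_flux([interferer, clean], sc, rng, np.array([10.0]))
        scored = score_plates(plates, "increase")
        by_cid = scored.set_index("compound_id")
        # closed form: C = 1/(1+10) of the full calcium response
        blank = scored[scored.role == "BLANK"]["response"].mean()
        neutral = scored[scored.role == "NEUTRAL_CONTROL"]["response"].mean()
        controls = ControlSummary.from_responses(
            scored[scored.role == "NEUTRAL_CONTROL"]["response"],
            scored[scored.role == "BLANK"]["response"])
        poc_interferer = normalize_poc(by_cid.loc["X1", "response"], controls)
        poc_clean = normalize_poc(by_cid.loc["X2", "response"], controls)
        assert poc_clean == pytest.approx(100.0, abs=1.0)
        assert poc_interferer < 30.0
        assert blank == pytest.approx(0.0, abs=1e-6)
        assert neutral > 0.5

    def test_blank_wells_flat(self):
        sc = small_scenario(read_cv=1e-9)
        plates = gen_ca_flux([CompoundTruth("X", CompoundClass.INACTIVE)], sc,
                             np.random.default_rng(0), np.array([1.0]))
        blanks = plates[0].wells_by_role(WellRole.BLANK)
        for w in blanks.values():
            assert np.ptp(w.trace.values) < 1e-3 * w.trace.values.mean()


class TestEphysGenerator:
    def test_instant_equilibrium_matches_hill_block(self):
        truth = CompoundTruth("F", CompoundClass.FULL_BLOCKER, ic50_uM=0.7)
        cells = gen_ephys_cells(truth, n_cells=1, noise_cv=0.0, seed=0)
        for conc, resp in normalize_cell(cells[0]).values():
            if conc is not None:
                expected = 1.0 - conc / (conc + 0.7)
                assert resp == pytest.approx(expected, rel=1e-9)

    def test_slow_binder_equilibration_time_preset(self):
        # niclosamide-like preset: ~10 min to steady state at 1.11 μM,
        # ~4 min at 3.3 μM
        assert time_to_fraction_block_min(DEFAULT_KON_SLOW, 1.11) == \
            pytest.approx(10.0, rel=0.05)
        assert time_to_fraction_block_min(DEFAULT_KON_SLOW, 3.3) == \
            pytest.approx(4.0, rel=0.2)

    def test_rundown_only_monotone_decay(self):
        truth = CompoundTruth("I", CompoundClass.INACTIVE)
        cells = gen_ephys_cells(truth, rundown_tau_s=1000.0, noise_cv=0.0,
                                n_cells=1, seed=0)
        responses = [resp for _, (_, resp) in
                     sorted(normalize_cell(cells[0]).items())]
        assert all(a > b for a, b in zip(responses, responses[1:]))
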