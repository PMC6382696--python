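"""Hit-funnel stages: thresholds, strict boundaries, full accounting."""

import numpy as np
import pytest

from ionscreen.dose_response import ConcResponseFit
from ionscreen.hit_triage import (Reason, ScreenDataset, TriageConfig,
                                  call_primary_hits, confirm_hits,
                                  counterscreen_filter, fluorescence_filter,
                                  potency_filter, primary_hit_threshold,
                                  run_funnel)


def poi_population(median, iqr, n=101):
    """n sorted values with exact median and IQR under linear interpolation."""
    lo, hi = median - iqr / 2, median + iqr / 2
    knots_x = [0, (n - 1) * 0.25, (n - 1) * 0.5, (n - 1) * 0.75, n - 1]
    knots_y = [lo - iqr, lo, median, hi, hi + iqr]
    return np.interp(np.arange(n), knots_x, knots_y)


def fit(ic50, converged=True, censored_at=None):
    return ConcResponseFit(midpoint=ic50, hill_slope=1.0, top=100.0, bottom=0.0,
                           converged=converged, censored_at=censored_at)


class TestPrimaryThreshold:
    def test_median_iqr_margin_formula(self):
        poi = poi_population(median=2.0, iqr=1.8)
        cfg = TriageConfig()
        assert primary_hit_threshold(poi, cfg) == pytest.approx(27.4)

    def test_margin_only_for_silent_population(self):
        cfg = TriageConfig()
        assert primary_hit_threshold(np.zeros(200), cfg) == pytest.approx(20.0)

    def test_requires_enough_wells(self):
        with pytest.raises(ValueError, match="test wells"):
            primary_hit_threshold(np.zeros(50), TriageConfig())


class TestPrimaryHits:
    def test_strict_inequality_at_boundary(self):
        hits, missing = call_primary_hits(
            {"a": 10.0, "b": 28.0, "c": 50.0, "d": 27.4}, 27.4)
        assert hits == {"b", "c"} and not missing

    def test_empty_input(self):
        assert call_primary_hits({}, 27.4) == (set(), set())

    def test_missing_poi_logged_not_dropped(self):
        hits, missing = call_primary_hits({"a": None, "b": 90.0}, 27.4)
        assert hits == {"b"} and missing == {"a"}


class TestConfirmation:
    def test_median_decides(self):
        cfg = TriageConfig()
        confirmed, retest = confirm_hits(
            {"yes": [30.0, 35.0, 10.0], "no": [10.0, 12.0, 40.0]}, 27.4, cfg)
        assert confirmed == {"yes"} and not retest

    def test_boundary_is_not_confirmed(self):
        confirmed, _ = confirm_hits({"edge": [27.4, 27.4, 27.4]}, 27.4,
                                    TriageConfig())
        assert not confirmed

    def test_short_replicates_go_to_retest(self):
        confirmed, retest = confirm_hits({"few": [90.0, 95.0]}, 27.4,
                                         TriageConfig())
        assert retest == {"few"} and not confirmed


class TestFluorescenceFilter:
    neutral = [95.0, 100.0, 105.0]  # median 100, sample SD 5

    def test_retained_and_artifact_split(self):
        clean, artifacts = fluorescence_filter(
            {"dim": 120.0, "bright": 200.0, "at_median": 100.0},
            self.neutral, TriageConfig())
        assert clean == {"dim", "at_median"} and artifacts == {"bright"}

    def test_boundary_is_artifact(self):
        _, artifacts = fluorescence_filter({"edge": 150.0}, self.neutral,
                                           TriageConfig())
        assert artifacts == {"edge"}

    def test_requires_neutral_controls(self):
        with pytest.raises(ValueError, match="neutral-control"):
            fluorescence_filter({"a": 1.0}, [100.0], TriageConfig())


class TestCounterscreenAndPotency:
    def test_counterscreen_strict_cutoff(self):
        cfg = TriageConfig()
        specific, interferers = counterscreen_filter(
            {"bad": fit(2.0), "edge": fit(10.0),
             "censored": fit(50.0, converged=False, censored_at=30.0)}, cfg)
        assert interferers == {"bad"}
        assert specific == {"edge", "censored"}

    def test_potency_thresholds_and_no_fit(self):
        cfg = TriageConfig()
        hits, eliminated = potency_filter(
            {"potent": fit(0.132), "weak": fit(8.0),
             "nofit": fit(100.0, converged=False, censored_at=55.6)}, cfg)
        assert hits == {"potent"}
        assert eliminated == {"weak": Reason.LOW_POTENCY, "nofit": Reason.NO_FIT}


class TestRunFunnel:
    @staticmethod
    def dataset():
        background = {f"bg{i}": abs(float(v)) for i, v in enumerate(
            np.random.default_rng(0).normal(1.0, 1.0, 200))}
        poi = dict(background)
        poi.update({"active": 80.0, "fluor": 70.0, "ca": 75.0,
                    "weak": 60.0, "flaky": 65.0})
        reps = {"active": [78.0, 82.0, 79.0], "fluor": [68.0, 71.0, 72.0],
                "ca": [74.0, 76.0, 73.0], "weak": [61.0, 59.0, 60.0],
                "flaky": [5.0, 4.0, 70.0]}
        fi = {c: 100.0 for c in poi}
        fi["fluor"] = 400.0
        return ScreenDataset(
            primary_poi=poi, replicate_poi=reps, baseline_fi=fi,
            neutral_fi=[95.0, 100.0, 105.0, 98.0, 102.0],
            ca_flux_fits={"active": fit(40.0, False, 30.0), "ca": fit(1.0),
                          "weak": fit(40.0, False, 30.0)},
            eyfp_fits={"active": fit(0.2), "weak": fit(9.0)},
        )

    def test_full_accounting_and_monotone_stages(self):
        report = run_funnel(self.dataset(), TriageConfig())
        n_total = len(self.dataset().primary_poi)
        assert len(report.survivors) + len(report.eliminations) == n_total
        for name, n_in, n_out in report.stages:
            assert n_out <= n_in
        assert report.survivors == ["active"]
        assert report.eliminations["fluor"] == Reason.AUTO_FLUORESCENT
        assert report.eliminations["ca"] == Reason.CA_FLUX_INTERFERENCE
        assert report.eliminations["weak"] == Reason.LOW_POTENCY
        assert report.eliminations["flaky"] == Reason.NOT_CONFIRMED

    def test_stage_skipping(self):
        cfg = TriageConfig(skip_counterscreen=True, skip_potency=True)
        report = run_funnel(self.dataset(), cfg)
        assert {n for n, _, _ in report.stages} == {"primary", "confirmation",
                                                    "fluorescence"}
        assert "ca" in report.survivors

    def test_deterministic(self):
        a = run_funnel(self.dataset(), TriageConfig())
        b = run_funnel(self.dataset(), TriageConfig())
        assert a.to_json() == b.to_json()

    def test_json_round_trip(self, tmp_path):
        import json
        report = run_funnel(self.dataset(), TriageConfig())
        report.to_json(tmp_path / "funnel.json")
        payload = json.loads((tmp_path / "funnel.json").read_text())
        assert payload["survivors"] == ["active"]
        assert payload["poc_cutoff"] == pytest.approx(100 - report.poi_cutoff)
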