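"""Peak integration, calibration, validation statistics, profile ANOVA."""

import dataclasses

import numpy as np
import pytest

from oxidha.quantify import (
    CalibrationModel,
    PrepVolumes,
    confirm_analyte,
    estimate_noise,
    fit_calibration,
    fit_calibration_batch,
    integrate_peak,
    lod_from_blank,
    precision_accuracy,
    profile_stats,
    quantify_sample,
    recovery,
)
from oxidha.simulate import (
    ChromatogramTrace,
    SamplePlan,
    calibration_series,
    recovery_scenario,
    simulate_sample,
    simulate_trace,
)


def wide_model(analyte, slope=1.0):
    return CalibrationModel(analyte, slope, 0.0, 1.0, (1e-6, 1e3), None, None)


def make_trace(method, plan, analyte, role="quantitative"):
    return simulate_trace(plan, method.transition(analyte, role))


class TestIntegration:
    def test_noise_free_area_recovered(self, hdohe_method, noise_free_plan):
        plan = dataclasses.replace(
            noise_free_plan, analyte_concentrations={"17-HDoHE": 0.5}
        )
        trace = make_trace(hdohe_method, plan, "17-HDoHE")
        peak = integrate_peak(trace, 6.46)
        expected = plan.response_factor("17-HDoHE") * 0.5
        assert peak is not None
        assert peak.area == pytest.approx(expected, rel=5e-3)
        assert peak.snr == np.inf

    def test_all_zero_trace_gives_none(self, hdohe_method, noise_free_plan):
        trace = make_trace(hdohe_method, noise_free_plan, "17-HDoHE")
        assert integrate_peak(trace, 6.46) is None

    def test_coeluting_pair_integrated_from_own_traces(
        self, hpdohe_method, noise_free_plan
    ):
        """10- and 11-HpDoHE share RT 7.39; quantification separates them by
        transition, never by retention time."""
        plan = dataclasses.replace(
            noise_free_plan,
            analyte_concentrations={"10-HpDoHE": 1.0, "11-HpDoHE": 2.0},
        )
        p10 = integrate_peak(make_trace(hpdohe_method, plan, "10-HpDoHE"), 7.39)
        p11 = integrate_peak(make_trace(hpdohe_method, plan, "11-HpDoHE"), 7.39)
        assert p11.area / p10.area == pytest.approx(2.0, rel=1e-2)

    def test_empty_trace_rejected(self, hdohe_method):
        t = hdohe_method.transition("17-HDoHE", "quantitative")
        trace = ChromatogramTrace(t, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            integrate_peak(trace, 6.46)


class TestNoiseEstimation:
    def test_zero_noise_trace(self, hdohe_method, noise_free_plan):
        trace = make_trace(hdohe_method, noise_free_plan, "17-HDoHE")
        assert estimate_noise(trace) == 0.0

    def test_injected_sigma_recovered(self, hdohe_method):
        plan = SamplePlan(
            analyte_concentrations={}, baseline_level=40.0, noise_sigma=4.0,
            seed=9,
        )
        trace = make_trace(hdohe_method, plan, "17-HDoHE")
        # 0-2.5 min at 0.005 spacing: 500 baseline points
        est = estimate_noise(trace, baseline_region=(0.0, 2.5))
        assert est == pytest.approx(4.0, rel=0.15)

    def test_region_overlapping_peak_rejected(self, hdohe_method, noise_free_plan):
        trace = make_trace(hdohe_method, noise_free_plan, "17-HDoHE")
        with pytest.raises(ValueError, match="overlaps"):
            estimate_noise(trace, (6.0, 7.0), expected_rts=[6.46])

    def test_short_region_rejected(self, hdohe_method, noise_free_plan):
        trace = make_trace(hdohe_method, noise_free_plan, "17-HDoHE")
        with pytest.raises(ValueError, match="20 points"):
            estimate_noise(trace, (0.0, 0.05))


class TestConfirmation:
    def test_rules(self):
        from oxidha.quantify import Peak

        peak = Peak(6.46, 6.4, 6.5, 100.0, 10.0, 50.0)
        shifted = Peak(6.96, 6.9, 7.0, 80.0, 8.0, 40.0)
        assert confirm_analyte(peak, peak)
        assert not confirm_analyte(peak, None)
        assert not confirm_analyte(None, peak)
        assert not confirm_analyte(peak, shifted, rt_tolerance=0.1)


class TestCalibration:
    def test_perfect_line(self):
        points = [(c, 2.0 * c + 0.1) for c in (0.1, 0.5, 1.0, 2.0)]
        model = fit_calibration(points, "x")
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.1)
        assert model.r_squared == pytest.approx(1.0)
        assert model.invert(2.0 * 0.5 + 0.1) == pytest.approx(0.5)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 1.0), (1.0, 1.1), (1.0, 0.9)])

    def test_lod_from_snr_points(self):
        points = [(c, c) for c in (0.5, 1.0, 2.0)]
        snr = [(c, 100.0 * c) for c in (0.5, 1.0, 2.0)]  # S/N = 3 at 0.03
        model = fit_calibration(points, "x", snr_points=snr)
        # 0.03 ng/uL x 10 uL injected = 300 pg on column
        assert model.lod_pg == pytest.approx(300.0, rel=1e-6)
        assert model.loq_pg == pytest.approx(1000.0, rel=1e-6)

    def test_weighted_fit_available(self):
        points = [(c, 2.0 * c) for c in (0.1, 0.5, 1.0, 2.0)]
        model = fit_calibration(points, "x", weighting="1/x")
        assert model.slope == pytest.approx(2.0)

    def test_lod_from_blank_path(self):
        assert lod_from_blank(5.0, height_per_conc=1000.0) == pytest.approx(
            0.015 * 1e4
        )

    def test_lod_monotone_in_noise(self, hdohe_method):
        """More baseline noise can only raise the limit of detection."""
        lods = []
        for noise in (2.0, 8.0, 32.0):
            plan = SamplePlan(
                analyte_concentrations={}, baseline_level=10 * noise,
                noise_sigma=noise, area_cv=0.0, seed=21,
            )
            samples = calibration_series(
                hdohe_method, levels=[0.05, 0.2, 1.0], replicates=2,
                template=plan, seed=21,
            )
            models = fit_calibration_batch(samples, hdohe_method)
            lods.append(models["17-HDoHE"].lod_pg)
        assert lods[0] < lods[1] < lods[2]


class TestQuantifySample:
    def quantify_noise_free(self, method, concentrations, models, plan):
        sample = simulate_sample(plan, method, "s", rng=1)
        return quantify_sample(sample.traces, method, models)

    def test_round_trip_noise_free(self, hdohe_method, noise_free_plan):
        conc = {"17-HDoHE": 0.4, "14-HDoHE": 0.05}
        plan = dataclasses.replace(
            noise_free_plan, analyte_concentrations=conc
        )
        cal = calibration_series(
            hdohe_method, levels=[1.0, 0.5, 0.1, 0.01],
            replicates=1, template=noise_free_plan, seed=2,
        )
        models = fit_calibration_batch(cal, hdohe_method)
        results = {
            r.analyte_id: r
            for r in self.quantify_noise_free(hdohe_method, conc, models, plan)
        }
        for analyte, expected in conc.items():
            r = results[analyte]
            assert r.confirmed
            assert r.concentration == pytest.approx(expected, rel=0.01)
        # absent analytes are unconfirmed, not zero-quantified
        assert not results["5-HDoHE"].confirmed
        assert results["5-HDoHE"].concentration is None

    def test_decoy_in_single_trace_never_quantified(
        self, hdohe_method, noise_free_plan
    ):
        """Dual-transition rule: a peak present only in the quantitative
        trace is rejected."""
        plan = dataclasses.replace(
            noise_free_plan,
            analyte_concentrations={"17-HDoHE": 0.5},
            qual_to_quant_ratio=0.0,  # suppress the qualitative transition
        )
        sample = simulate_sample(plan, hdohe_method, "s", rng=3)
        models = {a: wide_model(a) for a in hdohe_method.analytes}
        results = {
            r.analyte_id: r
            for r in quantify_sample(sample.traces, hdohe_method, models)
        }
        r = results["17-HDoHE"]
        assert r.quant_area > 0
        assert not r.confirmed
        assert r.concentration is None
        assert "qualitative missing" in r.flags

    def test_missing_is_trace_fatal(self, hdohe_method, noise_free_plan):
        plan = dataclasses.replace(
            noise_free_plan, analyte_concentrations={"17-HDoHE": 0.5}
        )
        sample = simulate_sample(plan, hdohe_method, "s", rng=4)
        traces = {
            k: v
            for k, v in sample.traces.items()
            if k != ("5(S)-HETE-d8", "internal_standard")
        }
        models = {a: wide_model(a) for a in hdohe_method.analytes}
        with pytest.raises(ValueError, match="internal-standard"):
            quantify_sample(traces, hdohe_method, models)

    def test_out_of_range_flagged(self, hdohe_method, noise_free_plan):
        plan = dataclasses.replace(
            noise_free_plan, analyte_concentrations={"17-HDoHE": 0.5}
        )
        sample = simulate_sample(plan, hdohe_method, "s", rng=5)
        models = {a: wide_model(a) for a in hdohe_method.analytes}
        models["17-HDoHE"] = CalibrationModel(
            "17-HDoHE", 1.0, 0.0, 1.0, (1e-6, 1e-4), None, None
        )
        results = {
            r.analyte_id: r
            for r in quantify_sample(sample.traces, hdohe_method, models)
        }
        assert "outside calibrated range" in results["17-HDoHE"].flags

    def test_calibration_inversion_on_own_standard(
        self, hdohe_method, noise_free_plan
    ):
        """Quantifying a calibration standard returns its own level."""
        level = 0.1
        cal = calibration_series(
            hdohe_method, levels=[1.0, 0.5, level, 0.01], replicates=1,
            template=noise_free_plan, seed=6,
        )
        models = fit_calibration_batch(cal, hdohe_method)
        standard = next(s for s in cal if s.metadata["level"] == level)
        results = quantify_sample(standard.traces, hdohe_method, models)
        for r in results:
            assert r.concentration == pytest.approx(level, rel=1e-3)


class TestRecoveryPrecisionAccuracy:
    def test_recovery_identity_and_loss(self, hdohe_method, noise_free_plan):
        models = {a: wide_model(a) for a in hdohe_method.analytes}
        for loss, expected in ((1.0, 100.0), (0.9, 90.0)):
            before, after = recovery_scenario(
                noise_free_plan, hdohe_method, 1.0, loss, seed=8
            )
            rb = quantify_sample(before.traces, hdohe_method, models)
            ra = quantify_sample(after.traces, hdohe_method, models)
            for b, a in zip(rb, ra):
                assert recovery(b, a) == pytest.approx(expected, abs=0.2)

    def test_recovery_requires_matching_analyte(self):
        from oxidha.quantify import QuantResult

        r1 = QuantResult("A", True, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        r2 = QuantResult("B", True, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            recovery(r1, r2)

    def test_zero_noise_batches(self):
        m = np.full((3, 3), 2.0)
        pa = precision_accuracy(m, expected=2.0)
        assert pa.intra_day_rsd == 0.0
        assert pa.inter_day_rsd == 0.0
        assert pa.accuracy == 100.0

    def test_bias_reflected_in_accuracy(self):
        m = np.full((3, 3), 1.9)
        pa = precision_accuracy(m, expected=2.0)
        assert pa.accuracy == pytest.approx(95.0)

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            precision_accuracy(np.ones((1, 3)), 1.0)


class TestProfileStats:
    def test_identical_groups_share_a_letter(self):
        data = [1.0, 1.1, 0.9, 1.05]
        stats = profile_stats({"a": data, "b": data, "c": data})
        assert len({letters for letters in stats.letters.values()}) == 1

    def test_dominant_group_isolated(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": 1.0 + 0.01 * rng.normal(size=5) for i in range(4)}
        groups["big"] = 10.0 + 0.01 * rng.normal(size=5)
        stats = profile_stats(groups)
        big_letters = set(stats.letters["big"])
        for name, letters in stats.letters.items():
            if name != "big":
                assert not big_letters & set(letters)
        assert stats.p_value < 1e-6

    def test_minimum_group_sizes_enforced(self):
        with pytest.raises(ValueError):
            profile_stats({"a": [1.0, 1.1], "b": [2.0]})
        with pytest.raises(ValueError):
            profile_stats({"a": [1.0, 1.1]})
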