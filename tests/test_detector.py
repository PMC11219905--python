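"""UKF disturbance estimation, cross-covariance trigger, scoring."""

import numpy as np
import pytest

from faidsim.detector import (DetectorTuning, MealDetector, cross_covariance,
                              is_night, score_detections)
from faidsim.patient import (MealEvent, PatientParams, VariabilityConfig,
                             VirtualPatient)
from faidsim.loop import ClosedLoop, NoBolusPolicy


def clean_meal_scenario(days, cho=60.0):
    times = ((7, "breakfast"), (13, "lunch"), (20, "dinner"))
    return [[MealEvent(h * 60.0, cho, label=lab) for h, lab in times]
            for _ in range(days)]


class TestCrossCovariance:
    def test_constant_sequences_give_zero(self):
        assert cross_covariance([5.0] * 10, [2.0] * 10) == 0.0

    def test_proportional_sequences_formula(self, rng):
        gs = rng.uniform(100.0, 200.0, size=12)
        a = 0.7
        dd = a * (gs - gs.mean())
        got = cross_covariance(gs, dd, max_lag=0)
        expected = a * np.sum((gs - gs.mean()) ** 2) / gs.size
        assert got == pytest.approx(expected)

    def test_independent_white_noise_near_zero(self, rng):
        vals = [cross_covariance(rng.normal(size=20), rng.normal(size=20))
                for _ in range(400)]
        assert abs(np.mean(vals)) < 0.05

    def test_max_over_lags_catches_shifted_signal(self, rng):
        dd = rng.normal(size=30)
        gs = np.roll(dd, 4) * 3.0  # Gs lags the disturbance by 4 samples
        at_zero = cross_covariance(gs, dd, max_lag=0)
        with_lags = cross_covariance(gs, dd, max_lag=6)
        assert with_lags > at_zero

    def test_short_buffer_rejected(self):
        with pytest.raises(ValueError):
            cross_covariance([1.0, 2.0], [1.0, 2.0])


class TestNightWindow:
    @pytest.mark.parametrize("clock,expected", [
        (23 * 60.0, True), (2 * 60.0, True), (5 * 60 + 59.0, True),
        (6 * 60.0, False), (12 * 60.0, False), (22 * 60 + 59.0, False),
    ])
    def test_inclusive_exclusive_bounds(self, clock, expected):
        assert is_night(clock) is expected


class TestUkf:
    def test_quiescent_disturbance_stays_small(self, params):
        """Steady basal input: D̂ stays within 3σ of its process noise."""
        det = MealDetector(params)
        gs0 = params.g_s * params.Gbl
        for _ in range(100):
            det.ukf_step(gs0, params.ubl)
        sigma_d = np.sqrt(det.state.Q[6, 6])
        assert abs(det.disturbance) < 3.0 * sigma_d

    def test_meal_raises_disturbance_estimate(self, params, quiet_var):
        """A real meal drives D̂ up with positive forward differences."""
        vp = VirtualPatient(params, quiet_var)
        det = MealDetector(params)
        for _ in range(20):
            vp.step(params.ubl)
            det.ukf_step(vp.state.Gs, params.ubl)
        vp.ingest_meal(60.0)
        d_before = det.disturbance
        ddiffs = []
        for _ in range(12):
            vp.step(params.ubl)
            det.ukf_step(vp.state.Gs, params.ubl)
            ddiffs.append(det.state.ddiff_buffer[-1])
        assert det.disturbance > d_before + 50.0
        assert max(ddiffs) > 0.0

    def test_tracks_true_flux_scale(self, params, quiet_var):
        """Peak D̂ approximates the true peak appearance flux."""
        vp = VirtualPatient(params, quiet_var)
        det = MealDetector(params)
        for _ in range(20):
            vp.step(params.ubl)
            det.ukf_step(vp.state.Gs, params.ubl)
        vp.ingest_meal(60.0)
        est_peak, true_peak = 0.0, 0.0
        for _ in range(36):
            true_peak = max(true_peak, vp.state.M2 / params.tmax_meal)
            vp.step(params.ubl)
            det.ukf_step(vp.state.Gs, params.ubl)
            est_peak = max(est_peak, det.disturbance)
        assert est_peak == pytest.approx(true_peak, rel=0.35)


class TestMealFlag:
    @staticmethod
    def _warm_detector(params, rising=True):
        """Buffers engineered so cc >= trade-off threshold with the
        Ddiff and 15-min CGM rise conditions satisfied (or violated)."""
        det = MealDetector(params)
        st, m = det.state, det.tuning.window_len
        gs = np.linspace(120, 150, m) if rising else np.linspace(150, 120, m)
        st.gs_buffer.extend(gs)
        st.ddiff_buffer.extend(2.0 * (gs - gs.mean()))
        st.consecutive_hits = 2   # this sample makes the third hit
        return det

    def test_night_suppression_overrides_signal(self, params):
        day = self._warm_detector(params)
        night = self._warm_detector(params)
        assert day.meal_flag(12 * 60.0) is True
        assert night.meal_flag(2 * 60.0) is False

    def test_falling_glucose_vetoes(self, params):
        """cc above threshold but glucose falling over 15 min: no flag."""
        det = self._warm_detector(params, rising=False)
        assert det.meal_flag(12 * 60.0) is False

    def test_refractory_holdoff(self, params):
        det = self._warm_detector(params)
        assert det.meal_flag(12 * 60.0) is True
        det.state.consecutive_hits = 2
        assert det.meal_flag(12 * 60.0 + 30.0) is False   # within 2 h
        det.state.consecutive_hits = 2
        assert det.meal_flag(12 * 60.0 + 150.0) is True   # past hold-off


@pytest.fixture(scope="module")
def clean_run():
    params = PatientParams()
    var = VariabilityConfig(si_amplitude=0.0, absorption_cv=0.0,
                            cgm_noise_sd=2.0, seed=0)
    loop = ClosedLoop(params, clean_meal_scenario(5), mode="faid",
                      policy=NoBolusPolicy(), variability=var,
                      detector_tuning=DetectorTuning.preset("trade_off"),
                      seed=11)
    loop.run(5)
    return loop.trace


class TestEndToEndDetection:
    def test_sensitivity_and_latency_band(self, clean_run):
        """Trade-off tuning detects clean 60 g meals promptly."""
        sc = score_detections(clean_run)
        assert sc.sensitivity >= 90.0
        assert 30.0 <= sc.median_latency <= 40.0

    def test_no_night_flags(self, clean_run):
        flagged = clean_run.loc[clean_run["meal_detected"] > 0, "time_min"]
        clock = flagged.to_numpy() % 1440.0
        assert not np.any((clock >= 23 * 60.0) | (clock < 6 * 60.0))

    def test_threshold_monotonicity(self):
        """Lowering the threshold never reduces the flag count."""
        params = PatientParams()
        var = VariabilityConfig(si_amplitude=0.0, absorption_cv=0.0,
                                cgm_noise_sd=2.0, seed=0)
        counts = []
        for threshold in (250.0, 110.0, 40.0):
            loop = ClosedLoop(params, clean_meal_scenario(3), mode="faid",
                              policy=NoBolusPolicy(), variability=var,
                              detector_tuning=DetectorTuning(
                                  threshold=threshold), seed=11)
            loop.run(3)
            counts.append(int(loop.trace["meal_detected"].sum()))
        assert counts[0] <= counts[1] <= counts[2]


class TestScoring:
    def test_perfect_detector(self):
        meals = [420.0, 780.0, 1200.0]
        flags = [t + 35.0 for t in meals]
        sc = score_detections((meals, flags))
        assert sc.sensitivity == 100.0 and sc.fp == 0
        assert sc.median_latency == 35.0

    def test_no_flags(self):
        sc = score_detections(([420.0, 780.0], []))
        assert sc.sensitivity == 0.0 and sc.fn == 2

    def test_spurious_flag_is_fp(self):
        sc = score_detections(([420.0], [180.0, 450.0]))
        assert sc.tp == 1 and sc.fp == 1

    def test_window_boundary(self):
        sc = score_detections(([420.0], [545.0]), association_window=120.0)
        assert sc.fp == 1 and sc.fn == 1
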