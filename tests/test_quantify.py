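import numpy as np
import pytest
from scipy.integrate import quad

from warmpet import errors, io_pet, quantify
from warmpet.io_pet import TimeActivityCurve

from conftest import make_exponential_tac


class TestFindPeak:
    def test_unique_maximum_in_window(self, schedule):
        mid = schedule.mid_times
        activity = 120.0 * np.exp(-0.5 * np.abs(mid - 4.5))
        split = quantify.find_peak(TimeActivityCurve(schedule, activity))
        assert split.peak_value == pytest.approx(120.0)
        assert split.time_to_peak == pytest.approx(4.5)

    def test_flat_curve_ties_break_to_earliest_frame(self, schedule):
        split = quantify.find_peak(
            TimeActivityCurve(schedule, np.full(len(schedule), 50.0)))
        in_window = schedule.mid_times[(schedule.mid_times >= 2)
                                       & (schedule.mid_times <= 10)]
        assert split.time_to_peak == pytest.approx(in_window[0])

    def test_no_frame_in_window_raises(self):
        short = io_pet.FrameSchedule(np.array([0.0, 0.5]), np.array([0.5, 0.5]))
        tac = TimeActivityCurve(short, np.array([1.0, 2.0]))
        with pytest.raises(errors.WindowError):
            quantify.find_peak(tac)

    def test_nonpositive_signal_in_window_raises(self, schedule):
        with pytest.raises(errors.DegenerateSignalError):
            quantify.find_peak(
                TimeActivityCurve(schedule, np.zeros(len(schedule))))


class TestWarmBpnd:
    def test_target_identical_to_reference_gives_zero(self, exp_tac_factory):
        tac = exp_tac_factory(100.0, 0.05)
        assert quantify.warm_bpnd(tac, tac) == 0.0

    def test_mono_exponential_closed_form(self, exp_tac_factory):
        # slower target washout with equal deposits: binding potential equals
        # the washout-rate ratio minus one
        target = exp_tac_factory(100.0, 0.025)
        reference = exp_tac_factory(100.0, 0.05)
        assert quantify.warm_bpnd(target, reference) == pytest.approx(1.0, abs=1e-10)

    def test_deposit_scaling_closed_form(self, exp_tac_factory):
        # equal washout rates, 1.5x deposit: the peak scaling alone drives it
        target = exp_tac_factory(150.0, 0.05)
        reference = exp_tac_factory(100.0, 0.05)
        assert quantify.warm_bpnd(target, reference) == pytest.approx(0.5, abs=1e-10)

    def test_slower_target_washout_increases_bpnd(self, exp_tac_factory):
        reference = exp_tac_factory(100.0, 0.05)
        estimates = [quantify.warm_bpnd(exp_tac_factory(100.0, k), reference)
                     for k in (0.05, 0.04, 0.03, 0.02)]
        assert np.all(np.diff(estimates) > 0)

    def test_independent_of_upper_limit_for_aligned_exponentials(
            self, exp_tac_factory):
        target = exp_tac_factory(120.0, 0.03)
        reference = exp_tac_factory(100.0, 0.06)
        values = [quantify.warm_bpnd(target, reference, T=T)
                  for T in (30.0, 45.0, 60.0)]
        assert np.ptp(values) < 1e-10

    def test_misaligned_peaks_integrate_from_each_curves_own_peak(
            self, schedule, exp_tac_factory):
        # target peaks later; each washout integral starts at its own peak
        target = make_exponential_tac(schedule, 100.0, 0.025, peak_mid_time=4.5)
        reference = exp_tac_factory(100.0, 0.05, 2.5)
        mid = schedule.mid_times
        t_end = mid[mid <= 60][-1]
        num = 100.0 * (-0.05 * (t_end - 2.5) ** 2 / 2)
        den = 100.0 * (-0.025 * (t_end - 4.5) ** 2 / 2)
        assert quantify.warm_bpnd(target, reference) == pytest.approx(
            num / den - 1.0, abs=1e-10)

    def test_non_decaying_target_raises(self, schedule, exp_tac_factory):
        rising = TimeActivityCurve(schedule, np.linspace(1, 100, len(schedule)))
        with pytest.raises(errors.NonWashoutError):
            quantify.warm_bpnd(rising, exp_tac_factory(100.0, 0.05))

    def test_schedule_mismatch_raises(self, schedule, exp_tac_factory):
        other = io_pet.FrameSchedule(schedule.start_times[:-1],
                                     schedule.durations[:-1])
        target = TimeActivityCurve(other, exp_tac_factory(100.0, 0.05).activity[:-1])
        with pytest.raises(errors.ScheduleError):
            quantify.warm_bpnd(target, exp_tac_factory(100.0, 0.05))

    def test_scale_invariance(self, exp_tac_factory):
        target = exp_tac_factory(130.0, 0.03)
        reference = exp_tac_factory(100.0, 0.05)
        base = quantify.warm_bpnd(target, reference)
        scaled = quantify.warm_bpnd(target.scaled(7.3), reference.scaled(7.3))
        assert scaled == pytest.approx(base, abs=1e-12)


class TestEarlyPhaseMeasures:
    def test_r1_is_peak_ratio(self):
        assert quantify.relative_uptake_r1(90.0, 120.0) == pytest.approx(0.75)
        assert quantify.relative_uptake_r1(120.0, 120.0) == pytest.approx(1.0)

    def test_r1_degenerate_reference(self):
        with pytest.raises(errors.DegenerateSignalError):
            quantify.relative_uptake_r1(90.0, 0.0)

    def test_scbf_slope_and_calibration(self):
        assert quantify.surrogate_cbf(100.0, 5.0) == pytest.approx(20.0)
        assert quantify.surrogate_cbf(100.0, 5.0, 2.5) == pytest.approx(50.0)
        assert quantify.surrogate_cbf(200.0, 5.0) == pytest.approx(40.0)

    def test_scale_factor_targets_cohort_mean(self):
        factor = quantify.calibrate_scale_factor([10.0, 30.0], 40.0)
        assert factor == pytest.approx(2.0)
        assert quantify.calibrate_scale_factor([25.0, 35.0], 30.0) == pytest.approx(1.0)
        with pytest.raises(errors.CalibrationError):
            quantify.calibrate_scale_factor([0.0, 0.0], 40.0)


class TestSuvr:
    def test_reference_against_itself_is_one(self, exp_tac_factory):
        tac = exp_tac_factory(100.0, 0.04)
        assert quantify.suvr(tac, tac).suvr == 1.0

    def test_constant_curves_exact_ratio(self, schedule):
        target = TimeActivityCurve(schedule, np.full(len(schedule), 60.0))
        reference = TimeActivityCurve(schedule, np.full(len(schedule), 30.0))
        assert quantify.suvr(target, reference).suvr == pytest.approx(2.0)

    def test_exponential_curves_match_quadrature_oracle(self, schedule,
                                                        exp_tac_factory):
        k_t, k_r = 0.02, 0.05
        target = exp_tac_factory(120.0, k_t)
        reference = exp_tac_factory(100.0, k_r)
        mid = schedule.mid_times
        t0 = mid[mid >= 40][0]
        t1 = mid[mid <= 60][-1]
        num, _ = quad(lambda t: 120.0 * np.exp(-k_t * (t - 2.5)), t0, t1)
        den, _ = quad(lambda t: 100.0 * np.exp(-k_r * (t - 2.5)), t0, t1)
        # trapezoid on 6-min frames carries a curvature error bounded by
        # h^2 k^2 / 12 ~ 0.75% per integral at k = 0.05/min
        assert quantify.suvr(target, reference).suvr == pytest.approx(
            num / den, rel=1e-2)

    def test_window_not_covered_raises(self):
        short = io_pet.FrameSchedule(np.arange(10.0), np.ones(10))
        tac = TimeActivityCurve(short, np.ones(10))
        with pytest.raises(errors.WindowError):
            quantify.suvr(tac, tac)


class TestTrapezoidAgainstQuadrature:
    def test_fine_schedule_integrals_match_adaptive_quadrature(self):
        # dense 0.5-min frames: trapezoid vs adaptive quadrature on an
        # analytic log-linear integrand
        starts = np.arange(0.0, 70.0, 0.5)
        schedule = io_pet.FrameSchedule(starts, np.full(len(starts), 0.5))
        mid = schedule.mid_times
        k, m0, tp = 0.04, 100.0, 2.25
        activity = np.where(mid < tp, m0 * (0.5 + 0.4 * mid / tp),
                            m0 * np.exp(-k * (mid - tp)))
        tac = TimeActivityCurve(schedule, activity)
        split = quantify.find_peak(tac)
        integral, _, _ = quantify._washout_log_integral(
            tac.activity, mid, split.peak_frame_index, split.peak_value, 60.0)
        t_end = mid[mid <= 60.0][-1]
        oracle, _ = quad(lambda t: -k * (t - tp), tp, t_end)
        assert integral == pytest.approx(oracle, abs=1e-9)


class TestParametricMaps:
    @pytest.fixture()
    def phantom(self, schedule, exp_tac_factory):
        ref = exp_tac_factory(100.0, 0.05)
        slow = exp_tac_factory(100.0, 0.025)  # true BP_ND 1 vs this reference
        voxels = np.zeros((4, 2, 1, len(schedule)))
        voxels[:2, :, 0] = ref.activity
        voxels[2:, :, 0] = slow.activity
        labels = np.zeros((4, 2, 1), dtype=np.int32)
        labels[:2] = 1
        labels[2:] = 2
        image = io_pet.DynamicImage(voxels, schedule)
        mask = io_pet.RegionMask(labels, {1: "CERB", 2: "FL"})
        return image, mask

    def test_identity_voxels_give_null_maps(self, schedule, exp_tac_factory):
        ref = exp_tac_factory(100.0, 0.05)
        voxels = np.tile(ref.activity, (3, 3, 1, 1))
        labels = np.ones((3, 3, 1), dtype=np.int32)
        image = io_pet.DynamicImage(voxels, schedule)
        mask = io_pet.RegionMask(labels, {1: "CERB"})
        maps, qc = quantify.parametric_maps(image, mask)
        assert np.allclose(maps["bpnd"][labels > 0], 0.0)
        assert np.allclose(maps["r1"][labels > 0], 1.0)
        assert np.allclose(maps["suvr"][labels > 0], 1.0)
        assert qc["n_sentinel_bpnd"] == 0

    def test_two_region_phantom_recovers_region_values(self, phantom):
        image, mask = phantom
        maps, _ = quantify.parametric_maps(image, mask)
        assert np.allclose(maps["bpnd"][mask.labels == 1], 0.0, atol=1e-10)
        assert np.allclose(maps["bpnd"][mask.labels == 2], 1.0, atol=1e-10)

    def test_dead_voxel_gets_sentinel_and_qc_count(self, phantom):
        image, mask = phantom
        image.voxels[3, 1, 0, :] = 0.0
        maps, qc = quantify.parametric_maps(image, mask)
        assert np.isnan(maps["bpnd"][3, 1, 0])
        assert np.isnan(maps["r1"][3, 1, 0])
        assert qc["nonpositive_peak"] == 1
        assert qc["n_sentinel_bpnd"] == 1

    def test_background_is_nan(self, phantom):
        image, mask = phantom
        mask.labels[0, 0, 0] = 0
        maps, _ = quantify.parametric_maps(image, mask)
        assert np.isnan(maps["bpnd"][0, 0, 0])

    def test_regional_summary_matches_tac_level_estimates(self, phantom):
        image, mask = phantom
        df = quantify.regional_summary(image, mask).set_index("region")
        ref = io_pet.extract_tac(image, mask, "CERB")
        fl = io_pet.extract_tac(image, mask, "FL")
        assert df.loc["FL", "bpnd"] == pytest.approx(
            quantify.warm_bpnd(fl, ref), abs=1e-12)
        assert df.loc["FL", "suvr"] == pytest.approx(
            quantify.suvr(fl, ref).suvr, abs=1e-12)
        assert df.loc["CERB", "bpnd"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc["FL", "n_voxels"] == 4
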