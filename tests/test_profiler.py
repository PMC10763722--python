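"""Peak fitting, sarcomere grammar, QC rule, and intensity normalization."""

import dataclasses

import numpy as np
import pytest

from titinsted.geometry import genotype_defaults
from titinsted.profiler import (
    AssignConfig,
    FitConfig,
    FittedPeak,
    ProfileError,
    assign_sarcomeres,
    detect_and_fit_peaks,
    extract_line_profile,
    intensity_ratio_contrast,
    measure_profile,
    normalize_a170_intensity,
    qc_filter,
)
from titinsted.simulate import StedSimParams, profile_to_image, simulate_profile

from conftest import make_profile


def peak(channel, center, height=100.0, fwhm=45.0):
    return FittedPeak(channel=channel, center_nm=center, height=height,
                      fwhm_nm=fwhm, center_se_nm=0.5, baseline=0.0)


def slack_layout_peaks(n_sarcomeres=3, sl=1800.0, mir_h=100.0, a170_h=100.0):
    """Peak lists placed exactly on the TTNtv- slack layout."""
    mir, a170 = [], []
    for k in range(n_sarcomeres):
        m = sl / 2 + k * sl
        mir += [peak("mir", m - 700.0, mir_h), peak("mir", m + 700.0, mir_h)]
        a170 += [peak("a170", m - 70.0, a170_h), peak("a170", m + 70.0, a170_h)]
    return mir, a170


class TestPeakFitting:
    def test_noiseless_single_gaussian_self_fit(self):
        profile = make_profile({"mir": [(500.0, 100.0, 40.0)]}, span_nm=1000.0)
        peaks = detect_and_fit_peaks(profile, "mir")
        assert len(peaks) == 1
        assert peaks[0].center_nm == pytest.approx(500.0, abs=1.0)
        assert peaks[0].fwhm_nm == pytest.approx(40.0, abs=1.0)
        assert peaks[0].height == pytest.approx(100.0, rel=0.02)

    def test_doublet_140nm_apart_resolved(self):
        profile = make_profile(
            {"a170": [(430.0, 100.0, 40.0), (570.0, 100.0, 40.0)]}, span_nm=1000.0
        )
        peaks = detect_and_fit_peaks(profile, "a170")
        assert len(peaks) == 2
        assert peaks[1].center_nm - peaks[0].center_nm == pytest.approx(140.0, abs=2.0)

    def test_30nm_pair_below_resolving_criterion(self):
        # oracle: the summed curve of two 40 nm FWHM Gaussians 30 nm apart has
        # a single maximum, so a single (broad) peak must be returned
        from conftest import gaussian

        x = np.arange(0.0, 1000.0, 10.0)
        y = gaussian(x, 485.0, 100.0, 40.0) + gaussian(x, 515.0, 100.0, 40.0)
        assert (np.diff(np.sign(np.diff(y))) < 0).sum() == 1
        profile = make_profile(
            {"a170": [(485.0, 100.0, 40.0), (515.0, 100.0, 40.0)]}, span_nm=1000.0
        )
        config = FitConfig(unresolved_fwhm_factor=1.25)
        peaks = detect_and_fit_peaks(profile, "a170", config)
        assert len(peaks) == 1
        assert "unresolved" in peaks[0].flags

    def test_shoulder_split_accepted_by_f_test(self):
        # a pair close enough to form a single maximum; with a lowered
        # broadness trigger the two-component refit runs and the residual
        # F-criterion accepts the split
        profile = make_profile(
            {"mir": [(484.0, 100.0, 40.0), (516.0, 100.0, 40.0)]}, span_nm=1000.0
        )
        x = profile.positions
        y = profile.channels["mir"]
        sel = (x > 380) & (x < 650)
        assert (np.diff(np.sign(np.diff(y[sel]))) < 0).sum() == 1  # truly one maximum
        config = FitConfig(shoulder_fwhm_factor=1.05)
        peaks = detect_and_fit_peaks(profile, "mir", config)
        assert len(peaks) == 2
        assert all("shoulder_split" in p.flags for p in peaks)
        assert peaks[1].center_nm - peaks[0].center_nm == pytest.approx(32.0, abs=6.0)

    def test_missing_channel_rejected(self):
        profile = make_profile({"mir": [(500.0, 100.0, 40.0)]})
        with pytest.raises(ProfileError, match="a170"):
            detect_and_fit_peaks(profile, "a170")


class TestAssignment:
    def test_three_sarcomeres_dtk_70(self):
        mir, a170 = slack_layout_peaks(3)
        measurements = assign_sarcomeres(mir, a170)
        assert len(measurements) == 3
        for m in measurements:
            assert m.dtk_nm == pytest.approx(70.0)
            assert m.a170_separation_nm == pytest.approx(140.0)
            assert m.aband_titin_len_nm == pytest.approx(1400.0)
            assert m.sl_nm == pytest.approx(1800.0)

    def test_dtk_is_half_separation_by_construction(self):
        mir, a170 = slack_layout_peaks(3)
        for m in assign_sarcomeres(mir, a170):
            assert m.dtk_nm == m.a170_separation_nm / 2

    def test_spurious_mir_between_pair_does_not_change_count(self):
        mir, a170 = slack_layout_peaks(3)
        mir.append(peak("mir", 900 - 650.0))  # inside the first sarcomere span
        measurements = assign_sarcomeres(sorted(mir, key=lambda p: p.center_nm), a170)
        assert len(measurements) == 3

    def test_empty_a170_list_gives_no_measurements(self):
        mir, _ = slack_layout_peaks(3)
        assert assign_sarcomeres(mir, []) == []

    def test_single_match_insufficient_for_sl(self):
        mir, a170 = slack_layout_peaks(1)
        assert assign_sarcomeres(mir, a170) == []

    def test_translation_invariance(self):
        mir, a170 = slack_layout_peaks(3)
        offset = 123.4
        mir2 = [dataclasses.replace(p, center_nm=p.center_nm + offset) for p in mir]
        a2 = [dataclasses.replace(p, center_nm=p.center_nm + offset) for p in a170]
        m1 = assign_sarcomeres(mir, a170)
        m2 = assign_sarcomeres(mir2, a2)
        for a, b in zip(m1, m2):
            assert b.dtk_nm == pytest.approx(a.dtk_nm)
            assert b.aband_titin_len_nm == pytest.approx(a.aband_titin_len_nm)
            assert b.sl_nm == pytest.approx(a.sl_nm)
            assert b.m_position_nm - a.m_position_nm == pytest.approx(offset)


class TestQC:
    def test_mir_fluctuation_above_threshold_fails(self):
        mir, a170 = slack_layout_peaks(2)
        measurements = assign_sarcomeres(mir, a170)
        m = measurements[0]
        m.peaks["mir_left"] = dataclasses.replace(m.peaks["mir_left"], height=100.0)
        m.peaks["mir_right"] = dataclasses.replace(m.peaks["mir_right"], height=130.0)
        passed, reasons = qc_filter(m)
        # |100-130| / 115 = 0.2609 > 0.20
        assert not passed
        assert reasons == ("MIR",)

    def test_equal_heights_pass(self):
        mir, a170 = slack_layout_peaks(2)
        m = assign_sarcomeres(mir, a170)[0]
        passed, reasons = qc_filter(m)
        assert passed and reasons == ()

    def test_a170_only_failure_named(self):
        mir, a170 = slack_layout_peaks(2)
        m = assign_sarcomeres(mir, a170)[0]
        m.peaks["a170_left"] = dataclasses.replace(m.peaks["a170_left"], height=50.0)
        passed, reasons = qc_filter(m)
        assert not passed
        assert reasons == ("A170",)

    def test_threshold_zero_rejects_any_asymmetry(self):
        mir, a170 = slack_layout_peaks(2)
        m = assign_sarcomeres(mir, a170)[0]
        m.peaks["mir_left"] = dataclasses.replace(m.peaks["mir_left"], height=100.001)
        passed, _ = qc_filter(m, threshold=0.0)
        assert not passed

    def test_boundary_fluctuation_exactly_at_threshold_passes(self):
        mir, a170 = slack_layout_peaks(2)
        m = assign_sarcomeres(mir, a170)[0]
        # fluctuation = |90 - 110| / 100 = 0.20, not > 0.20
        m.peaks["a170_left"] = dataclasses.replace(m.peaks["a170_left"], height=90.0)
        m.peaks["a170_right"] = dataclasses.replace(m.peaks["a170_right"], height=110.0)
        passed, _ = qc_filter(m)
        assert passed


class TestIntensity:
    def test_equal_heights_give_unit_ratio(self):
        mir, a170 = slack_layout_peaks(2)
        m = assign_sarcomeres(mir, a170)[0]
        assert normalize_a170_intensity(m) == pytest.approx(1.0)

    def test_printed_group_means_give_0667_and_33pct(self):
        ratio, reduction = intensity_ratio_contrast(0.1765, 0.2646)
        assert round(ratio, 3) == 0.667
        assert round(reduction) == 33

    def test_profiler_ratio_halves_when_heights_track_counts(self):
        """Labeled-molecule-count oracle: with registration jitter off and no
        truncated-MIR shift, band heights are proportional to molecule counts,
        so the mean A170/MIR height ratio at trunc_fraction 0.5 is 0.5."""
        pos = genotype_defaults(
            "TTNTV_POS", trunc_mir_shift_slack_nm=0.0, trunc_shift_relax_nm_per_um=0.0
        )
        ratios = []
        for seed in range(12):
            profile, _ = simulate_profile(
                StedSimParams(genotype=pos, registration_jitter_sd_nm=0.0, seed=seed)
            )
            for m in measure_profile(profile):
                if m.qc_pass:
                    ratios.append(m.a170_over_mir_intensity)
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - 0.5) < max(2 * se, 0.02)


class TestPipelineOnSimulations:
    def test_noiseless_jitterfree_metrics_exact(self, noiseless_sim):
        profile, truth = noiseless_sim
        measurements = measure_profile(profile)
        assert len(measurements) == len(truth.layouts)
        for m, layout in zip(measurements, truth.layouts):
            assert m.dtk_nm == pytest.approx(layout.dtk_nm, abs=1.0)
            assert m.aband_titin_len_nm == pytest.approx(layout.aband_titin_len_nm, abs=1.0)
            assert m.sl_nm == pytest.approx(layout.sl_nm, abs=1.0)
            assert m.a170_over_mir_intensity == pytest.approx(1.0, rel=0.01)
            assert m.qc_pass

    def test_mir_width_excess_in_pos_decreases_with_stretch(self):
        """The truncated-MIR shift broadens the MIR band at slack and relaxes
        with stretch, so the TTNtv+ minus TTNtv- FWHM excess shrinks."""
        def mean_fwhm(genotype, sl, seed):
            vals = []
            for s in range(10):
                p, _ = simulate_profile(StedSimParams(genotype=genotype, sl_um=sl, seed=seed + s))
                vals += [m.mir_fwhm_nm for m in measure_profile(p)]
            return np.mean(vals)

        excess_slack = mean_fwhm("TTNTV_POS", 1.8, 0) - mean_fwhm("TTNTV_NEG", 1.8, 100)
        excess_stretched = mean_fwhm("TTNTV_POS", 2.6, 200) - mean_fwhm("TTNTV_NEG", 2.6, 300)
        assert excess_slack > 0
        assert excess_stretched < excess_slack


class TestLineExtraction:
    def test_constant_image_gives_flat_profile(self):
        img = {"mir": np.full((40, 60), 7.0), "a170": np.full((40, 60), 7.0)}
        profile = extract_line_profile(img, 10.0, (20, 2), (20, 57), width_px=5)
        np.testing.assert_allclose(profile.channels["mir"], 7.0)

    def test_round_trip_through_2d_rendering(self):
        params = StedSimParams(registration_jitter_sd_nm=0.0, poisson_noise=False, seed=0)
        profile, truth = simulate_profile(params)
        img = profile_to_image(profile, truth, n_rows=21, seed=1)
        n_cols = img["mir"].shape[1]
        extracted = extract_line_profile(img, params.pixel_nm, (10, 0), (10, n_cols - 1),
                                         width_px=5)
        # thick-line average over Poisson rows recovers the noiseless trace
        resid = extracted.channels["mir"] - truth.noiseless["mir"][:n_cols]
        scale = truth.noiseless["mir"].max()
        assert np.abs(resid).max() < 0.15 * scale

    def test_wide_average_reduces_noise(self):
        params = StedSimParams(registration_jitter_sd_nm=0.0, poisson_noise=False, seed=0)
        profile, truth = simulate_profile(params)
        sds = {}
        for width in (1, 21):
            resids = []
            for seed in range(8):
                img = profile_to_image(profile, truth, n_rows=21, seed=seed)
                n_cols = img["mir"].shape[1]
                ex = extract_line_profile(img, params.pixel_nm, (10, 0), (10, n_cols - 1),
                                          width_px=width)
                resids.append(ex.channels["mir"] - truth.noiseless["mir"][:n_cols])
            sds[width] = np.std(np.concatenate(resids))
        assert sds[21] < sds[1]

    def test_line_outside_image_rejected(self):
        img = {"mir": np.zeros((20, 20))}
        with pytest.raises(ProfileError, match="outside"):
            extract_line_profile(img, 10.0, (5, 0), (5, 25))
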