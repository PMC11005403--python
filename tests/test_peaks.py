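"""oriC peak detection, area integration, and initiation-mode estimation."""

import numpy as np
import pytest

from mfakit import (MFAProfile, detect_ori_peak, estimate_ori_fraction,
                    gaussian_smooth, normalize_profile, peak_area,
                    simulate_population, timecourse_summary)
from mfakit.genome import circular_distance
from mfakit.peaks import PeakCall

from conftest import make_params, noiseless_profile


def triangular_profile(genome, apex_value, half_width, bin_size=1000):
    """Flat baseline 1.0 with a triangular peak of given apex at oriC."""
    starts = np.arange(genome.length // bin_size) * bin_size
    d = circular_distance(starts, genome.ori_position, genome.length)
    vals = 1.0 + (apex_value - 1.0) * np.clip(1.0 - d / half_width, 0, None)
    return MFAProfile(genome=genome, bin_size=bin_size, values=vals, sigma=1.0)


def trapezoid_oracle(values, baseline, indices, bin_size):
    """Brute-force per-bin trapezoid summation over a circular index path."""
    y = [max(values[i] - baseline, 0.0) for i in indices]
    total = 0.0
    for a, b in zip(y[:-1], y[1:]):
        total += 0.5 * (a + b) * bin_size
    return total


class TestDetect:
    def test_flat_profile_not_detected(self, tbar):
        prof = MFAProfile(genome=tbar, bin_size=1000,
                          values=np.ones(2010), sigma=1.0)
        peak = detect_ori_peak(prof)
        assert peak.height == pytest.approx(0.0)
        assert not peak.detected

    def test_triangular_peak_at_annotated_ori(self, tbar):
        """Apex lands on the annotated origin coordinate, height is apex
        minus the far-field baseline of 1.0."""
        prof = triangular_profile(tbar, apex_value=1.6, half_width=200_000)
        peak = detect_ori_peak(prof)
        assert abs(peak.apex_position - 1_671_000) <= prof.bin_size
        assert peak.height == pytest.approx(0.6, abs=1e-9)
        assert peak.detected

    def test_window_validation(self, tbar):
        prof = triangular_profile(tbar, 1.5, 100_000)
        with pytest.raises(ValueError):
            detect_ori_peak(prof, window=tbar.length)

    def test_unsmoothed_profile_warns(self, tbar):
        prof = MFAProfile(genome=tbar, bin_size=1000,
                          values=np.ones(2010), sigma=0.0)
        with pytest.warns(UserWarning, match="unsmoothed"):
            detect_ori_peak(prof)

    def test_pure_rdr_profile_has_no_detectable_peak(self, tbar):
        """Dispersed (recombination-driven) initiation leaves the profile
        flat: no origin peak should be called."""
        hits = 0
        for seed in range(5):
            sim = simulate_population(make_params(tbar, f=0.0, r=0.6,
                                                  n=2000, depth=10.0,
                                                  seed=seed))
            prof = gaussian_smooth(normalize_profile(sim.coverage), 10)
            hits += detect_ori_peak(prof, min_height=0.05).detected
        assert hits == 0


class TestArea:
    def test_whole_genome_triangle_closed_form(self, tbar):
        """A triangle of height h spanning the genome (bounds at the
        antipode) integrates to h * L / 2."""
        h, L = 0.5, tbar.length
        starts = np.arange(2010) * 1000
        d = circular_distance(starts, tbar.ori_position, L)
        vals = 1.0 + h * (1.0 - 2.0 * d / L)
        prof = MFAProfile(genome=tbar, bin_size=1000, values=vals, sigma=1.0)
        peak = PeakCall(apex_position=tbar.ori_position,
                        apex_value=1.0 + h, baseline=1.0, height=h, area=0.0,
                        left_bound=tbar.antipode, right_bound=tbar.antipode,
                        detected=True, far_min=1.0)
        assert peak_area(prof, peak) == pytest.approx(h * L / 2, rel=1e-9)

    def test_detected_area_matches_trapezoid_oracle(self, tbar):
        prof = triangular_profile(tbar, 1.5, 300_000)
        peak = detect_ori_peak(prof)
        apex = peak.apex_position // 1000
        left = peak.left_bound // 1000
        right = peak.right_bound // 1000
        n = prof.n_bins
        path = [(left + j) % n for j in range(((right - left) % n) + 1)]
        oracle = trapezoid_oracle(prof.values, peak.baseline, path, 1000)
        assert peak.area == pytest.approx(oracle, abs=1e-9)
        assert peak_area(prof, peak) == pytest.approx(oracle, abs=1e-9)

    def test_flat_profile_zero_area(self, tbar):
        prof = MFAProfile(genome=tbar, bin_size=1000,
                          values=np.ones(2010), sigma=1.0)
        peak = detect_ori_peak(prof)
        assert peak_area(prof, peak) == 0.0

    def test_area_linear_in_excess_height(self, tbar):
        prof1 = triangular_profile(tbar, 1.4, 250_000)
        prof2 = triangular_profile(tbar, 1.8, 250_000)  # doubled excess
        p1 = detect_ori_peak(prof1)
        p2 = detect_ori_peak(prof2)
        assert p2.area == pytest.approx(2 * p1.area, rel=1e-6)


class TestOriFraction:
    def test_exact_inversion_full_ori_use(self, tbar):
        prof = noiseless_profile(tbar, f=1.0, r=0.8)
        peak = detect_ori_peak(prof)
        assert estimate_ori_fraction(peak, 0.8) == pytest.approx(1.0, abs=1e-9)

    def test_zero_contrast_gives_zero(self):
        peak = PeakCall(apex_position=0, apex_value=1.0, baseline=1.0,
                        height=0.0, area=0.0, left_bound=0, right_bound=0,
                        detected=False, far_min=1.0)
        assert estimate_ori_fraction(peak, 0.5) == 0.0

    def test_exact_inversion_mixed_mode(self, tbar):
        prof = noiseless_profile(tbar, f=0.5, r=0.6)
        peak = detect_ori_peak(prof)
        assert estimate_ori_fraction(peak, 0.6) == pytest.approx(0.5, abs=1e-6)

    def test_r_zero_rejected(self, tbar):
        peak = detect_ori_peak(noiseless_profile(tbar, 0.5, 0.6))
        with pytest.raises(ValueError):
            estimate_ori_fraction(peak, 0.0)

    def test_f_r_not_jointly_identifiable(self, tbar):
        """Two (f, r) pairs with the same peak-to-trough contrast k produce
        bin-wise identical normalized profiles, so r must be supplied."""
        f1, r1 = 0.5, 0.6
        k = f1 * r1 / (1 + r1 * (1 - f1) / 2)
        r2 = 1.0
        f2 = k * (1 + r2 / 2) / (r2 * (1 + k / 2))  # same k at r2
        a = noiseless_profile(tbar, f1, r1).values
        b = noiseless_profile(tbar, f2, r2).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_recovery_from_simulated_data(self, tbar):
        """f-hat within 0.05 RMSE of truth at study conditions (subset of
        the full grid; the acceptance suite runs the complete sweep)."""
        r = 0.6
        for f in (0.25, 0.75):
            errs = []
            for seed in range(5):
                sim = simulate_population(make_params(tbar, f=f, r=r, n=2000,
                                                      depth=10.0,
                                                      seed=100 + seed))
                prof = gaussian_smooth(normalize_profile(sim.coverage), 10)
                peak = detect_ori_peak(prof)
                errs.append(estimate_ori_fraction(peak, r) - f)
            assert np.sqrt(np.mean(np.square(errs))) < 0.05


class TestTimecourse:
    def test_single_flat_sample(self, tbar):
        prof = MFAProfile(genome=tbar, bin_size=1000,
                          values=np.ones(2010), sigma=1.0)
        table = timecourse_summary([("t0", 0.0, prof)])
        assert len(table) == 1
        assert table.loc[0, "height"] == 0.0
        assert not table.loc[0, "detected"]

    def test_heights_increase_with_ori_fraction(self, tbar):
        samples = []
        for i, f in enumerate([0.2, 0.5, 0.9]):
            sim = simulate_population(make_params(tbar, f=f, r=0.6, n=2000,
                                                  depth=10.0, seed=33))
            prof = gaussian_smooth(normalize_profile(sim.coverage), 10)
            samples.append((f"f{f}", float(i), prof))
        table = timecourse_summary(samples)
        assert np.all(np.diff(table["height"].to_numpy()) > 0)

    def test_sorted_by_hours(self, tbar):
        prof = triangular_profile(tbar, 1.4, 200_000)
        table = timecourse_summary([("late", 9.0, prof), ("early", 1.0, prof)])
        assert list(table["label"]) == ["early", "late"]

    def test_empty_and_duplicate_labels_rejected(self, tbar):
        prof = triangular_profile(tbar, 1.4, 200_000)
        with pytest.raises(ValueError):
            timecourse_summary([])
        with pytest.raises(ValueError, match="duplicate"):
            timecourse_summary([("a", 0.0, prof), ("a", 1.0, prof)])
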