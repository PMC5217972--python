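"""Coverage profiles and packaging-model estimators."""

import numpy as np
import pytest

from pacwave.coverage import (CoverageProfile, binned_coverage,
                              detect_wave_period, directionality_test,
                              estimate_background, estimate_pac_position,
                              estimate_processivity, estimate_redundancy,
                              flank_extent, flank_series,
                              headful_window_means, near_att_fraction)
from pacwave.simulate import SimParams, simulate_experiment


def profile_from_depth(depth, frame="host", bin_size=1000):
    depth = np.asarray(depth, dtype=float)
    return CoverageProfile(frame, bin_size, depth, len(depth) * bin_size)


def truth_host_profile(molecules, host_length, bin_size=1000):
    starts, ends = [], []
    for m in molecules:
        for f, s, e, _ in m.segments:
            if f == "host":
                starts.append(s)
                ends.append(e)
    return binned_coverage(starts, ends, "host", host_length, bin_size)


class TestBinnedCoverage:
    def test_single_read_fractional_depth(self):
        prof = binned_coverage([100], [350], "host", 1000, bin_size=1000)
        assert prof.depth[0] == pytest.approx(0.25)

    def test_no_reads_all_zero(self):
        prof = binned_coverage([], [], "host", 5000, bin_size=1000)
        assert prof.n_bins == 5
        assert not prof.depth.any()

    def test_wrapping_interval_covers_both_ends(self):
        prof = binned_coverage([900], [1100 - 1000], "host", 1000, bin_size=100)
        # interval 900..1100 on a 1-kb circle: bins 9 and 0 fully covered
        assert prof.depth[9] == pytest.approx(1.0)
        assert prof.depth[0] == pytest.approx(1.0)
        assert prof.depth[5] == 0.0

    def test_uniform_background_recovers_mean_depth(self, study_frames):
        """A background-only simulation yields a flat profile at the
        expected mean coverage (the flat generalized-transduction floor)."""
        host, phage, att = study_frames
        p = SimParams(f_int=0.0, bg_rate=1.0, n_series=60, seed=20)
        mols, _, _ = simulate_experiment(p, host, phage, att)
        prof = truth_host_profile(mols, host.length)
        expect = 60 * p.headful / host.length
        assert prof.depth.mean() == pytest.approx(expect, rel=0.01)
        assert np.median(prof.depth) == pytest.approx(expect, rel=0.3)

    def test_invalid_bin_size(self):
        with pytest.raises(ValueError):
            binned_coverage([], [], "host", 1000, bin_size=0)


class TestNearAttFraction:
    def test_printed_ratio_arithmetic(self):
        """5,717 of 7,844 host reads inside the att-linked window -> 72.9%."""
        inside = np.full(5_717, 1_100_000)   # 100 kb left of attB
        outside = np.full(7_844 - 5_717, 200_000)
        frac, k, n = near_att_fraction(np.concatenate([inside, outside]),
                                       1_200_000, 2_000_000)
        assert (k, n) == (5_717, 7_844)
        assert round(100 * frac, 1) == 72.9

    def test_empty_window(self):
        frac, k, n = near_att_fraction(np.full(10, 500_000), 1_900_000, 2_000_000,
                                       window=(100_000, 10_000))
        assert frac == 0.0 and k == 0

    def test_window_larger_than_genome_rejected(self):
        with pytest.raises(ValueError):
            near_att_fraction([1], 0, 100_000, window=(90_000, 20_000))


class TestBackgroundAndExtent:
    def test_flat_background_recovered(self):
        prof = profile_from_depth(np.full(2000, 1.3))
        assert estimate_background(prof, 1_200_000) == pytest.approx(1.3)

    def test_enrichment_inside_exclusion_zone_ignored(self):
        depth = np.full(2000, 1.3)
        depth[1100:1200] = 80.0  # enrichment left of attB at 1.2 Mb
        prof = profile_from_depth(depth)
        assert estimate_background(prof, 1_200_000) == pytest.approx(1.3)

    def test_all_zero_profile(self):
        prof = profile_from_depth(np.zeros(2000))
        assert estimate_background(prof, 1_200_000) == 0.0

    def test_step_profile_extent(self):
        depth = np.full(2000, 1.0)
        att_bin = 1_800
        depth[att_bin - 750: att_bin] = 10.0  # 750 kb of 10X left of attB
        prof = profile_from_depth(depth)
        ext = flank_extent(prof, att_bin * 1000, "toward_attL", 1.0, 2.0, 3)
        assert ext == 750_000

    def test_flat_profile_extent_zero(self):
        prof = profile_from_depth(np.full(2000, 1.0))
        assert flank_extent(prof, 1_000_000, "toward_attL", 1.0, 2.0, 3) == 0

    def test_run_rule_bridges_isolated_dips(self):
        depth = np.full(1000, 1.0)
        depth[400:500] = 10.0
        depth[450] = 0.0  # a single low bin inside the enriched run
        prof = profile_from_depth(depth)
        ext = flank_extent(prof, 500_000, "toward_attL", 1.0, 2.0, run_rule=3)
        assert ext == 100_000

    def test_zero_background_uses_absolute_floor(self):
        depth = np.zeros(1000)
        depth[450:500] = 5.0
        prof = profile_from_depth(depth)
        ext = flank_extent(prof, 500_000, "toward_attL", 0.0, 2.0, 3)
        assert ext == 50_000


class TestWindowsAndProcessivity:
    def test_geometric_profile_recovers_ratios(self):
        H, delta = 71_664, 32_414
        nb = 900
        depth = np.zeros(nb)
        centers = np.arange(nb) * 1000 + 500
        j = np.where(centers < delta, 1, 2 + (centers - delta) // H)
        depth = 60.0 * (2 / 3) ** (j - 1)
        att_bin = 900
        prof = profile_from_depth(np.concatenate([depth[::-1], np.zeros(100)]))
        w = headful_window_means(prof, att_bin * 1000, "toward_attL", H,
                                 n_windows=8, first_offset=delta)
        np.testing.assert_allclose(w / w[0], (2 / 3) ** np.arange(8), rtol=0.02)
        assert estimate_processivity(w, 0.0) == pytest.approx(3.0, abs=0.15)

    def test_hand_computed_processivity(self):
        means = 60.0 * (2 / 3) ** np.arange(12)
        assert estimate_processivity(means, 0.0) == pytest.approx(
            sum((2 / 3) ** j for j in range(12)), rel=1e-12)
        assert estimate_processivity(means, 0.0) == pytest.approx(3.0, abs=0.05)

    def test_single_headful_series(self):
        assert estimate_processivity([50, 0, 0, 0], 0.0) == pytest.approx(1.0)

    def test_background_at_first_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_processivity([1.0, 0.5], background=1.5)

    def test_flat_profile_near_equal_windows(self):
        prof = profile_from_depth(np.full(1000, 2.0))
        w = headful_window_means(prof, 990_000, "toward_attL", 70_000,
                                 n_windows=5, first_offset=30_000)
        assert np.allclose(w, 2.0)


class TestWavePeriod:
    def test_synthetic_cosine_period_recovered(self):
        bins = np.arange(900)
        depth = 10 + 3 * np.cos(2 * np.pi * bins / 72.0)
        prof = profile_from_depth(np.concatenate([depth[::-1], [0]]))
        T = detect_wave_period(prof, 900_000, "toward_attL", span=850_000)
        assert T == pytest.approx(72_000, abs=500)

    def test_flat_profile_returns_none(self, rng):
        depth = rng.poisson(5.0, size=1000).astype(float)
        prof = profile_from_depth(depth)
        assert detect_wave_period(prof, 990_000, "toward_attL", span=900_000) is None

    def test_simulated_waves_match_headful(self, study_frames):
        """Truth-level flank coverage of an induction simulation shows the
        headful-sized wave to within ~1 kb."""
        host, phage, att = study_frames
        p = SimParams(f_int=1.0, bg_rate=0.0, n_series=5000,
                      pac_jitter_sd=2000.0, seed=21)
        mols, _, _ = simulate_experiment(p, host, phage, att)
        prof = truth_host_profile(mols, host.length)
        T = detect_wave_period(prof, att.attB_pos, "toward_attL")
        assert T is not None
        assert abs(T - p.headful) < 1500


class TestRedundancy:
    def test_study_values(self):
        assert estimate_redundancy(71_664, 65_149) == pytest.approx(0.100, abs=5e-4)
        assert estimate_redundancy(65_149, 65_149) == 0.0
        assert estimate_redundancy(72_000, 65_000) == pytest.approx(0.1077, abs=1e-4)

    @pytest.mark.parametrize("r", np.linspace(0.0, 0.3, 7))
    def test_identity_when_period_equals_headful(self, r):
        Lp = 65_149
        H = Lp * (1 + r)
        assert estimate_redundancy(H, Lp) == pytest.approx(r, abs=1e-12)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            estimate_redundancy(0, 65_149)


class TestPacPosition:
    def test_sawtooth_argmax(self):
        bins = np.arange(65, dtype=float)
        depth = np.where(bins <= 23, bins + 1, 0.1)
        prof = CoverageProfile("phage", 1000, depth, 65_000)
        est = estimate_pac_position(prof, smooth=2000)
        assert abs(est.pos_max - 23_000) <= 1500

    def test_flat_profile_flagged(self):
        prof = CoverageProfile("phage", 1000, np.full(65, 3.0), 65_000)
        est = estimate_pac_position(prof)
        assert est.pos_max is None and est.pos_edge is None

    def test_episomal_simulation_recovery(self, study_frames):
        """The rising edge of the phage coverage maximum recovers the pac
        position to well within 3 kb."""
        host, phage, att = study_frames
        p = SimParams(f_int=0.0, bg_rate=0.0, n_series=2000,
                      pac_jitter_sd=1000.0, seed=22)
        mols, _, _ = simulate_experiment(p, host, phage, att)
        starts, ends = [], []
        for m in mols:
            for f, s, e, _ in m.segments:
                starts.append(s)
                ends.append(e)
        prof = binned_coverage(starts, ends, "phage", phage.length, 1000)
        est = estimate_pac_position(prof)
        assert abs(est.pos_edge - p.pac_pos) <= 3000
        assert est.downslope == -1


class TestDirectionality:
    @pytest.mark.parametrize("left,right,expect_dir,expect_p", [
        (56, 0, "left", 2 * 0.5**56),
        (6, 0, "left", 0.03125),
        (5, 5, None, 1.0),
        (0, 8, "right", 2 * 0.5**8),
    ])
    def test_calls_and_exact_p(self, left, right, expect_dir, expect_p):
        direction, p = directionality_test(left, right)
        assert direction == expect_dir
        assert p == pytest.approx(expect_p, rel=1e-9)

    def test_no_hybrids_no_call(self):
        assert directionality_test(0, 0) == (None, None)


class TestRotationInvariance:
    def test_estimates_unchanged_under_coordinate_rotation(self, study_frames):
        """Rotating the circular host frame (and attB with it) must not
        change flank-based estimates."""
        host, phage, att = study_frames
        p = SimParams(f_int=1.0, bg_rate=0.0, n_series=800,
                      pac_jitter_sd=2000.0, seed=23)
        mols, _, _ = simulate_experiment(p, host, phage, att)
        prof = truth_host_profile(mols, host.length)
        shift_bins = 700
        rotated = CoverageProfile("host", 1000, np.roll(prof.depth, shift_bins),
                                  prof.length)
        attB_rot = att.attB_pos + shift_bins * 1000
        bg0 = estimate_background(prof, att.attB_pos)
        bg1 = estimate_background(rotated, attB_rot)
        assert bg0 == pytest.approx(bg1)
        e0 = flank_extent(prof, att.attB_pos, "toward_attL", bg0, 2.0, 3)
        e1 = flank_extent(rotated, attB_rot, "toward_attL", bg1, 2.0, 3)
        assert e0 == e1
        T0 = detect_wave_period(prof, att.attB_pos, "toward_attL")
        T1 = detect_wave_period(rotated, attB_rot, "toward_attL")
        assert T0 == pytest.approx(T1, abs=1.0)
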