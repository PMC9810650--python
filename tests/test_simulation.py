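"""Simulation framework: determinism, the noise model's closed forms,
crossing detection, and the replication analyses."""

import math

import numpy as np
import pytest

from rxcov import (
    ConfigError,
    DistributionSpec,
    DomainError,
    InsufficientDataError,
    Scenario,
    ValidationError,
    apply_noise,
    canonical_scenario,
    find_significance_crossing,
    find_zero_crossing,
    gamma_scan,
    generate_scenario,
    make_fixture_table,
    pvalue_two_group,
    replicate_study,
    replicate_sufficiency,
    simulate_aliquot_pair,
)


class TestScenario:
    def test_seed_determinism(self, small_scenario):
        d1 = generate_scenario(small_scenario)
        d2 = generate_scenario(small_scenario)
        np.testing.assert_array_equal(d1.s_x, d2.s_x)
        np.testing.assert_array_equal(d1.s_y, d2.s_y)
        np.testing.assert_array_equal(d1.noise_x(), d2.noise_x())

    def test_zero_scale_noise(self):
        sc = canonical_scenario(1, n_per_group=5, seed=0)
        sc = Scenario(
            n_per_group=5,
            dist_sx=sc.dist_sx,
            dist_sy=sc.dist_sy,
            dist_noise_x=DistributionSpec("normal", 0.0, 0.0),
            dist_noise_y=DistributionSpec("normal", 0.0, 0.0),
            seed=0,
        )
        draw = generate_scenario(sc)
        assert (draw.noise_x() == 0).all()

    def test_too_small_group(self):
        with pytest.raises(ConfigError):
            canonical_scenario(1, n_per_group=1)

    def test_unsupported_family(self):
        with pytest.raises(ConfigError):
            DistributionSpec("cauchy", 0, 1)

    def test_signals_are_nonnegative(self):
        sc = Scenario(
            n_per_group=200,
            dist_sx=DistributionSpec("normal", 0.1, 2.0),
            dist_sy=DistributionSpec("normal", 0.1, 2.0),
            dist_noise_x=DistributionSpec("normal", 0, 1),
            dist_noise_y=DistributionSpec("normal", 0, 1),
            seed=4,
        )
        draw = generate_scenario(sc)
        assert (draw.s_x >= 0).all() and (draw.s_y >= 0).all()
        assert draw.n_clipped > 0


class TestNoiseInjection:
    def test_additive_scaling(self):
        np.testing.assert_array_equal(
            apply_noise([10, 12], [1, -2], 2.0), [12.0, 8.0]
        )

    def test_gamma_zero_returns_signal(self):
        s = np.array([3.0, 4.0])
        np.testing.assert_array_equal(apply_noise(s, [5.0, -5.0], 0.0), s)

    def test_negative_gamma_rejected(self):
        with pytest.raises(DomainError):
            apply_noise([1.0], [1.0], -0.5)

    def test_aliquots_distinct_and_noise_free_identical(self, small_scenario):
        draw = generate_scenario(small_scenario)
        d, d2 = simulate_aliquot_pair(draw.s_x, 1.0, draw.noise_x, 1)
        assert not np.array_equal(d, d2)
        d, d2 = simulate_aliquot_pair(draw.s_x, 0.0, draw.noise_x, 1)
        np.testing.assert_array_equal(d, draw.s_x)
        np.testing.assert_array_equal(d2, draw.s_x)

    def test_replicate_averaging_shrinks_noise_variance(self):
        """Var(d - s) of an R-average is gamma^2 sigma_n^2 / R."""
        rng = np.random.default_rng(1)
        s = np.full(4000, 10.0)
        gamma, sigma_n, r = 1.5, 1.0, 400
        d, _ = simulate_aliquot_pair(
            s, gamma, lambda: rng.normal(0, sigma_n, s.size), r
        )
        observed = (d - s).var()
        assert observed == pytest.approx(gamma**2 * sigma_n**2 / r, rel=0.15)

    def test_zero_replicates_rejected(self, small_scenario):
        draw = generate_scenario(small_scenario)
        with pytest.raises(ConfigError):
            simulate_aliquot_pair(draw.s_x, 1.0, draw.noise_x, 0)

    def test_half_normal_closed_form(self):
        """gamma|n - n'| with n ~ Normal(0, sigma_n) has mean
        2 gamma sigma_n / sqrt(pi) and sd gamma sigma_n sqrt(2 - 4/pi)."""
        rng = np.random.default_rng(7)
        gamma, sigma_n, m = 1.7, 0.8, 200_000
        n_vals = gamma * np.abs(rng.normal(0, sigma_n, m) - rng.normal(0, sigma_n, m))
        assert n_vals.mean() == pytest.approx(
            2 * gamma * sigma_n / math.sqrt(math.pi), rel=0.01
        )
        assert n_vals.std(ddof=1) == pytest.approx(
            gamma * sigma_n * math.sqrt(2 - 4 / math.pi), rel=0.01
        )


class TestPvalue:
    def test_identical_groups(self):
        assert pvalue_two_group([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_well_separated_groups(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(20, 1, 20)
        assert pvalue_two_group(a, b) < 1e-6

    def test_insufficient_n(self):
        with pytest.raises(InsufficientDataError):
            pvalue_two_group([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("test", ["welch_t", "student_t", "mann_whitney"])
    def test_alternative_tests_run(self, rng, test):
        p = pvalue_two_group(rng.normal(0, 1, 10), rng.normal(1, 1, 10), test=test)
        assert 0 <= p <= 1


class TestCrossings:
    def test_exact_grid_point_zero(self):
        star, later = find_zero_crossing([0.25, 0.5, 0.75, 1.0], [1.0, 0.5, 0.0, -0.5])
        assert star == 0.75
        assert later == []

    def test_linear_interpolation(self):
        star, _ = find_zero_crossing([1.0, 2.0], [0.5, -0.5])
        assert star == pytest.approx(1.5)

    def test_no_crossing_absent(self):
        star, _ = find_zero_crossing([1, 2, 3], [0.5, 0.4, 0.3])
        assert star is None

    def test_later_recrossings_reported(self):
        star, later = find_zero_crossing([1, 2, 3, 4], [1.0, -1.0, 1.0, -1.0])
        assert star == pytest.approx(1.5)
        assert later == [pytest.approx(3.5)]

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            find_zero_crossing([1.0], [0.5])

    def test_significance_interpolation(self):
        g = find_significance_crossing([1.0, 2.0], [0.01, 0.10], alpha=0.05)
        assert g == pytest.approx(1 + 0.04 / 0.09)

    def test_always_significant_absent(self):
        assert find_significance_crossing([1, 2, 3], [0.01, 0.02, 0.03]) is None

    def test_alpha_validated(self):
        with pytest.raises(ValidationError):
            find_significance_crossing([1, 2], [0.1, 0.2], alpha=1.5)


class TestGammaScan:
    def test_seed_determinism_bit_identical(self, small_scenario):
        grid = np.linspace(0.2, 3.0, 8)
        s1 = gamma_scan(small_scenario, grid)
        s2 = gamma_scan(small_scenario, grid)
        np.testing.assert_array_equal(s1.rxcov_track, s2.rxcov_track)
        np.testing.assert_array_equal(s1.pvalue_track, s2.pvalue_track)
        assert s1.gamma_star == s2.gamma_star

    def test_tracks_finite_and_eventually_decreasing(self):
        sc = canonical_scenario(1, n_per_group=2000, seed=2)
        grid = np.linspace(0.25, 8.0, 16)
        scan = gamma_scan(sc, grid, k_smooth=2)
        assert np.isfinite(scan.rxcov_track).all()
        assert scan.rxcov_track[0] > scan.rxcov_track[-1]

    def test_gamma_zero_excluded(self, small_scenario):
        with pytest.raises(ValidationError):
            gamma_scan(small_scenario, [0.0, 1.0])

    def test_noise_free_scenario_all_points_degenerate(self):
        sc = Scenario(
            n_per_group=6,
            dist_sx=DistributionSpec("normal", 10, 2),
            dist_sy=DistributionSpec("normal", 12, 2),
            dist_noise_x=DistributionSpec("normal", 0, 0),
            dist_noise_y=DistributionSpec("normal", 0, 0),
            seed=0,
        )
        scan = gamma_scan(sc, [0.5, 1.0, 1.5])
        assert all(s == "noise_free" for s in scan.status)
        assert np.isnan(scan.rxcov_track).all()
        assert scan.gamma_star is None

    def test_fixed_draw_mode_is_smooth_near_gamma_star(self):
        sc = canonical_scenario(1, n_per_group=200, seed=6)
        grid = np.linspace(0.25, 10.0, 40)
        scan = gamma_scan(sc, grid, noise_draws="fixed")
        assert scan.gamma_star is not None
        assert scan.later_crossings == []

    def test_large_gamma_limit_matches_monte_carlo_oracle(self):
        """With a shared noise law, as gamma grows the signal becomes
        negligible and (after the ratio-scale clip at zero) d/gamma tends
        to max(n, 0): Z and N approach fixed laws whose rxCOV constant a
        brute-force Monte Carlo oracle computes directly; the scan's tail
        must agree within Monte-Carlo error, and the constant is negative
        because N is a worst-case max over both groups."""
        rng = np.random.default_rng(11)
        m = 400_000
        relu = lambda a: np.clip(a, 0.0, None)
        nx, ny = relu(rng.normal(0, 1, m)), relu(rng.normal(0, 1, m))
        nx2, ny2 = relu(rng.normal(0, 1, m)), relu(rng.normal(0, 1, m))
        z0 = np.abs(nx - ny)
        n0 = np.maximum(np.abs(nx - nx2), np.abs(ny - ny2))
        limit = np.log10(
            (z0.mean() * z0.std(ddof=1)) / (n0.mean() * n0.std(ddof=1))
        )
        assert limit < 0
        sc = canonical_scenario(1, n_per_group=4000, seed=3)
        scan = gamma_scan(sc, [200.0, 300.0], k_smooth=4)
        assert scan.rxcov_track.mean() == pytest.approx(limit, abs=0.05)


class TestReplication:
    def test_threshold_shifts_right_with_averaging(self):
        sc = canonical_scenario(1, n_per_group=1000, seed=9)
        grid = np.linspace(0.25, 12.0, 30)
        study = replicate_study(sc, grid, [1, 3], k_smooth=4)
        g1 = study.gamma_star_by_r[1]
        g3 = study.gamma_star_by_r[3]
        assert g1 is not None and g3 is not None
        assert g3 > g1
        assert "gamma*" in study.summary()

    def test_sufficiency_verdicts_match_scan_sign(self, small_scenario):
        study = replicate_study(small_scenario, np.linspace(0.5, 2.0, 4), [1])
        scan = study.scans[1]
        expected = scan.rxcov_track > 0
        np.testing.assert_array_equal(
            study.sufficiency["sufficient"].to_numpy(), expected
        )

    def test_unsorted_counts_rejected(self, small_scenario):
        with pytest.raises(ConfigError):
            replicate_study(small_scenario, [0.5, 1.0], [3, 1])


class TestReplicateSufficiency:
    def build_table(self, gamma, n_replicates, seed=21, n=60):
        sc = canonical_scenario(1, n_per_group=n, seed=seed)
        return make_fixture_table(
            sc, gamma=gamma, analytes=["A1"], n_replicates=n_replicates, seed=seed
        )

    def test_low_noise_sufficient_at_one(self):
        table = self.build_table(gamma=0.3, n_replicates=2)
        out = replicate_sufficiency(table, "G1", "G2")
        assert out.loc[0, "min_sufficient_r"] == 1
        assert out.loc[0, "verdict"] == "sufficient"

    def test_averaging_rescues_intermediate_noise(self):
        # pick gamma between the R=1 and R=3 thresholds: insufficient raw,
        # sufficient after averaging
        for seed in range(40):
            table = self.build_table(gamma=5.0, n_replicates=3, seed=seed)
            out = replicate_sufficiency(table, "G1", "G2")
            r = out.loc[0, "min_sufficient_r"]
            if r is not None and r > 1:
                assert out.loc[0, "verdict"] == "sufficient"
                return
        pytest.fail("no seed produced an intermediate-noise rescue")

    def test_hopeless_noise_reports_insufficient(self):
        table = self.build_table(gamma=500.0, n_replicates=2)
        out = replicate_sufficiency(table, "G1", "G2")
        assert out.loc[0, "min_sufficient_r"] is None
        assert out.loc[0, "verdict"].startswith("insufficient")

    def test_requires_replicate_column(self, fixture_table):
        with pytest.raises(ValidationError):
            replicate_sufficiency(fixture_table, "G1", "G2")
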