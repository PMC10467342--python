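"""NAT-zone detection, rate peaks and confinement statistics."""

import math

import numpy as np
import pytest

from natzone import (
    ConcentrationProfile,
    NATZone,
    NoTransitionZoneError,
    build_grid,
    confinement_index,
    confinement_pvalue,
    detect_nat_zone,
    rate_maximum_depth,
)


def _linear_profiles():
    """NO3- 25 -> 0 µM over 0..2 m; NH4+ 0 until 2.2 m then rising to 50."""
    z = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.2, 3.0, 4.0])
    no3 = np.maximum(0.0, 25.0 * (1 - z / 2.0))
    nh4 = np.where(z <= 2.2, 0.0, 50.0 * (z - 2.2) / 1.8)
    return (ConcentrationProfile(z, no3, "NO3"), ConcentrationProfile(z, nh4, "NH4"))


class TestDetectNATZone:
    def test_piecewise_linear_interpolation_oracle(self):
        no3, nh4 = _linear_profiles()
        zone = detect_nat_zone(no3, nh4, 1.0, 1.0)
        # down-crossing of 1 µM on the 25->0 ramp: z = 2*(1 - 1/25) = 1.92
        assert zone.z_top == pytest.approx(1.92, abs=1e-12)
        # up-crossing: NH4 reaches 1 µM at 2.2 + 1.8/50 = 2.236
        assert zone.z_bottom == pytest.approx(2.236, abs=1e-12)
        assert zone.mode == "gap"

    def test_constant_nitrate_is_unresolvable(self):
        z = np.linspace(0, 4, 9)
        no3 = ConcentrationProfile(z, np.full(9, 25.0), "NO3")
        nh4 = ConcentrationProfile(z, np.linspace(0, 50, 9), "NH4")
        with pytest.raises(NoTransitionZoneError):
            detect_nat_zone(no3, nh4, 1.0, 1.0)

    def test_no_ammonium_is_unresolvable(self):
        no3, _ = _linear_profiles()
        nh4 = ConcentrationProfile(no3.depths, np.zeros(no3.depths.size), "NH4")
        with pytest.raises(NoTransitionZoneError):
            detect_nat_zone(no3, nh4, 1.0, 1.0)

    def test_nitrate_absent_at_surface_is_unresolvable(self):
        z = np.linspace(0, 4, 5)
        no3 = ConcentrationProfile(z, np.array([0.5, 0.2, 0.1, 0.0, 0.0]), "NO3")
        nh4 = ConcentrationProfile(z, np.linspace(0, 50, 5), "NH4")
        with pytest.raises(NoTransitionZoneError):
            detect_nat_zone(no3, nh4, 1.0, 1.0)

    def test_coincident_crossings_give_zero_width_zone(self):
        z = np.array([0.0, 2.3, 4.0])
        no3 = ConcentrationProfile(z, np.array([25.0, 1.0, 0.0]), "NO3")
        nh4 = ConcentrationProfile(z, np.array([0.0, 1.0, 50.0]), "NH4")
        zone = detect_nat_zone(no3, nh4, 1.0, 1.0)
        assert zone.z_top == pytest.approx(2.3)
        assert zone.z_bottom == pytest.approx(2.3)
        assert zone.width == pytest.approx(0.0)

    def test_supersampling_invariance(self):
        no3, nh4 = _linear_profiles()
        zone = detect_nat_zone(no3, nh4, 1.0, 1.0)
        # add interpolated points: boundaries must not move
        zf = np.linspace(0, 4, 4001)
        no3f = ConcentrationProfile(zf, np.interp(zf, no3.depths, no3.values), "NO3")
        nh4f = ConcentrationProfile(zf, np.interp(zf, nh4.depths, nh4.values), "NH4")
        zone_f = detect_nat_zone(no3f, nh4f, 1.0, 1.0)
        assert zone_f.z_top == pytest.approx(zone.z_top, abs=1e-9)
        assert zone_f.z_bottom == pytest.approx(zone.z_bottom, abs=1e-9)

    def test_model_anammox_peak_falls_in_detected_zone(self, ref_results):
        """Desk-scale analogue of the rate peak sitting inside the gray band."""
        zone = ref_results.nat_zone(1.0, 1.0)
        peak = ref_results.anammox_peak_depth()
        assert zone.z_top <= peak <= zone.z_bottom


class TestRateMaximumDepth:
    def test_simple_argmax(self):
        g = build_grid(4.0, 4)
        assert rate_maximum_depth([0, 0, 5, 1], g) == pytest.approx(2.5)

    def test_tie_breaks_shallow(self):
        g = build_grid(3.0, 3)
        assert rate_maximum_depth([3.0, 3.0, 0.0], g) == pytest.approx(0.5)

    def test_discretized_gaussian_peak_near_mean(self):
        g = build_grid(4.0, 400)
        mu = 2.3
        r = np.exp(-((g.cell_centers - mu) ** 2) / (2 * 0.2**2))
        assert abs(rate_maximum_depth(r, g) - mu) <= g.cell_widths[0]

    def test_all_zero_rates_rejected(self):
        g = build_grid(1.0, 3)
        with pytest.raises(ValueError, match="no active zone"):
            rate_maximum_depth(np.zeros(3), g)


ZONE = NATZone(z_top=1.0, z_bottom=2.0, eps_no3=1.0, eps_nh4=1.0, mode="gap")


class TestConfinementIndex:
    def test_fully_inside_zone(self):
        depths = np.array([1.1, 1.5, 1.9])
        assert confinement_index([0.2, 0.5, 0.3], depths, ZONE) == 1.0

    def test_zone_without_samples(self):
        depths = np.array([0.1, 0.5, 2.5])
        assert confinement_index([0.2, 0.5, 0.3], depths, ZONE) == 0.0

    def test_partial_overlap_arithmetic(self):
        a = [0.0, 0.2, 0.5, 0.3, 0.0]
        inside3 = np.array([0.5, 1.2, 1.5, 1.8, 2.5])  # middle three inside
        assert confinement_index(a, inside3, ZONE) == pytest.approx(1.0)
        inside1 = np.array([0.5, 0.8, 1.5, 2.2, 2.5])  # only the middle one
        assert confinement_index(a, inside1, ZONE) == pytest.approx(0.5)

    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError, match="zero total abundance"):
            confinement_index([0.0, 0.0], np.array([1.1, 1.2]), ZONE)


class TestConfinementPvalue:
    def test_constant_abundance_gives_p_one(self):
        depths = np.linspace(0, 4, 6)
        r = confinement_pvalue(np.full(6, 0.2), depths, ZONE, n_permutations=999, seed=3)
        assert r.p_value == 1.0

    def test_exhaustive_enumeration_oracle(self):
        # 5 depths, all mass at the single in-zone depth: 4! of 5!
        # permutations keep it there -> p = (1+24)/(5!+1)
        depths = np.array([0.2, 0.6, 1.5, 2.4, 3.0])
        a = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        r = confinement_pvalue(a, depths, ZONE, method="exhaustive")
        assert r.exhaustive
        assert r.n_permutations == math.factorial(5)
        assert r.p_value == pytest.approx(25 / 121)

    def test_auto_uses_exhaustive_up_to_seven_depths(self):
        depths = np.linspace(0.5, 3.5, 7)
        a = np.array([0, 0, 0.5, 0.5, 0, 0, 0.0])
        r = confinement_pvalue(a, depths, ZONE, seed=1)
        assert r.exhaustive
        assert r.n_permutations == math.factorial(7)

    def test_monte_carlo_within_three_se_of_exhaustive(self):
        depths = np.array([0.3, 0.9, 1.2, 1.7, 2.2, 2.9, 3.6])
        a = np.array([0.01, 0.02, 0.30, 0.40, 0.05, 0.02, 0.01])
        exact = confinement_pvalue(a, depths, ZONE, method="exhaustive").p_value
        mc = confinement_pvalue(a, depths, ZONE, n_permutations=999, seed=11,
                                method="mc").p_value
        se = math.sqrt(exact * (1 - exact) / 999)
        assert abs(mc - exact) <= 3 * se + 2 / 999

    def test_p_value_floor(self):
        depths = np.linspace(0.5, 3.5, 12)
        a = np.zeros(12)
        a[4] = 1.0  # depth 1.59 in zone
        r = confinement_pvalue(a, depths, ZONE, n_permutations=99, seed=5)
        assert r.p_value >= 1 / 100

    def test_seed_reproducibility(self):
        depths = np.linspace(0, 4, 15)
        rng = np.random.default_rng(8)
        a = rng.random(15)
        r1 = confinement_pvalue(a, depths, ZONE, n_permutations=499, seed=42)
        r2 = confinement_pvalue(a, depths, ZONE, n_permutations=499, seed=42)
        assert r1.p_value == r2.p_value

    def test_degenerate_single_depth_rejected(self):
        with pytest.raises(ValueError):
            confinement_pvalue(np.array([1.0]), np.array([1.5]), ZONE, seed=0)

    def test_mc_without_seed_rejected(self):
        depths = np.linspace(0, 4, 9)
        with pytest.raises(ValueError, match="seed"):
            confinement_pvalue(np.ones(9), depths, ZONE, method="mc", seed=None)
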